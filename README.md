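# isrekit

Tools for asking whether two groups of interferon-stimulated genes (ISGs)
are driven by *different* interferon-stimulated response elements (ISREs).

After interferon-β, most ISGs are induced transiently by ISGF3
(IRF9 + tyrosine-phosphorylated STAT1/STAT2), while a subset stays on for
days, driven by the unphosphorylated complex U-ISGF3. The computational
signature of that split has two parts, and `isrekit` implements both as a
tested, reusable pipeline for anyone analyzing ISG expression and promoter
motifs:

1. **Gene-set classification** from expression data: quantile
   normalization, induction calls from duplicate arrays
   (p ≤ 0.05, treated signal > 25, fold > 2), and the set algebra
   `u_isgf3 = ifnb ∩ yf`, `isgf3_only = ifnb − u_isgf3 − ifng`
   (yf = genes induced by the phosphorylation-dead Y701F-STAT1).
2. **ISRE comparison**: promoter windows (TSS − 2500 to TSS + 500),
   log-odds PWM scanning on both strands, a CLOVER-style set-enrichment
   score with a shuffled-sequence null, per-group position frequency
   matrices from flank-extended best sites, and the symmetrized
   position-averaged Kullback–Leibler divergence

       D_i = ½ [ KL(p_i ‖ q_i) + KL(q_i ‖ p_i) ],   mean_d = (1/L) Σ_i D_i   (bits)

   with significance from label permutation:
   p = (1 + #{perm ≥ observed}) / (n_perm + 1).

A synthetic-data module generates expression matrices and 3-kb promoter
sets with planted truth (including a group with conserved ISRE flanks), so
the whole pipeline is verifiable without external downloads. A documented
synthetic stand-in for the canonical ISRE matrix ships in JASPAR format;
any JASPAR/TRANSFAC/MEME matrix can be substituted.

## Worked example

```python
import isrekit as ik

# two promoter groups; the "u_isgf3" group carries 90%-conserved 5-bp flanks
cfg = ik.PromoterSimConfig(seed=7)           # 2 x 30 promoters, 3 kb
groups, truth = ik.simulate_promoters(cfg)
res = ik.flank_divergence_test(groups["isgf3_only"], groups["u_isgf3"],
                               n_perm=999, seed=7)
print(f"mean symmetrized KL: {res.mean_d:.3f} bits")
print(f"permutation p-value: {res.p_value:.4g}  (null mean {res.perm_null['mean']:.3f})")
```

prints

```
mean symmetrized KL: 0.626 bits
permutation p-value: 0.001  (null mean 0.100)
```

The observed divergence between the two site populations (0.626 bits per
position, driven by the conserved flank columns) sits far above the
label-permutation null (mean 0.100 bits), so the test rejects at its
resolution limit: none of 999 permutations reached the observed value.

The classification side, on a simulated four-condition experiment:

```python
em, _ = ik.simulate_expression(ik.ExpressionSimConfig(seed=1))
em = ik.quantile_normalize(em)
sets = {c: ik.induced_set(ik.score_induction(em, c, "control"))
        for c in ("ifnb", "yf", "ifng")}
print(ik.partition_isgs(sets["ifnb"], sets["yf"], sets["ifng"]).summary())
```

```
{'ifnb_induced': 150, 'u_isgf3': 29, 'remaining_after_u_isgf3': 121,
 'ifng_induced': 73, 'ifng_overlap': 73, 'isgf3_only': 48}
```

150 genes come up after IFNβ; 29 of them are also induced by Y701F-STAT1
(the U-ISGF3 set); of the 121 remaining, 73 are IFNγ-inducible and are
excluded, leaving 48 ISGF3-only genes — the two groups whose ISREs the
motif stage then compares.

The same steps are available from the shell:

```
isrekit simulate promoters --seed 7 --out-a a.fasta --out-b b.fasta
isrekit collect-sites --fasta a.fasta --out sites_a.tsv
isrekit collect-sites --fasta b.fasta --out sites_b.tsv
isrekit diverge --sites-a sites_a.tsv --sites-b sites_b.tsv --seed 7 --out div.json
```

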