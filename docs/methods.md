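# Methods

## Scientific question

After a pulse of interferon-β, most interferon-stimulated genes (ISGs) are
induced transiently by ISGF3 (IRF9 plus tyrosine-phosphorylated STAT1/STAT2),
but a subset stays on for days, driven by the unphosphorylated form of the
complex (U-ISGF3). `isrekit` implements the computational side of that
observation as a reusable pipeline with two stages:

1. **Gene-set classification.** From a genes × samples intensity matrix with
   duplicate arrays per condition, call induction per contrast and form the
   sets: IFNβ-induced; the U-ISGF3 subset (also induced by Y701F-STAT1, a
   mutant that cannot be tyrosine-phosphorylated); and the ISGF3-only set
   (IFNβ-induced genes that are neither Y701F- nor IFNγ-inducible).
2. **ISRE comparison.** Extract promoter windows, scan them with an ISRE
   position-weight matrix, collect each gene's best site extended by flanking
   bases, and ask whether the two groups' site populations differ using a
   symmetrized position-averaged Kullback–Leibler divergence with a
   label-permutation significance test.

A synthetic-data module generates both kinds of input with planted truth so
every stage is verifiable end to end without downloads.

## Models and procedures

### Quantile normalization and induction calls

Quantile normalization forces every array column to share one empirical
distribution: the rank-r value of each column is replaced by the mean of the
rank-r sorted values across columns. Ties are broken by position (ordinal
ranks), which makes the post-condition exact: every column's sorted vector
equals the vector of per-rank means.

A gene is called induced in a treated-vs-control contrast when all three
gates pass:

* differential p ≤ 0.05 (inclusive), from a two-sample test on
  log2(intensity + 1) across replicates;
* mean treated signal > 25 (strict), on the linear scale;
* fold change > 2 (strict), with fold = mean(treated) / mean(control) on the
  linear scale.

The differential test behind the p-value is configurable: the default is a
pooled-variance two-sample t-test (reproducible at n = 2 duplicates without
vendor software), with Welch and a moderated ("shrunken", variance shrunk
toward the median with 4 prior degrees of freedom) alternative. No
multiple-testing correction is applied by default, matching the raw-p
filtering convention of the bead-array workflow; a BH flag is easy to add at
the call site since all p-values are returned. Genes with a control mean of
zero have no defined fold; they are flagged and never called induced.

Set algebra: `u_isgf3 = ifnb ∩ yf`, `isgf3_only = ifnb − u_isgf3 − ifng`.
Both relations hold for arbitrary inputs, including empty sets.

### Promoter windows

Windows span 2500 bp upstream to 500 bp downstream of the annotated TSS.
The TSS base is included, giving 3001 bp — the inclusive convention; both
offsets are parameters. Minus-strand windows are mirrored and
reverse-complemented so all sequences read 5′→3′ of the gene. Windows
clipped by a chromosome edge are flagged `truncated`. Internally coordinates
are 0-based half-open; BED output likewise; 1-based inclusive only in
user-facing text.

### PWM scanning and the set-enrichment score

A placement of a motif of length L at offset j scores
`Σ_i log2(p_i(b_i) / q(b_i))` bits, where `q` is the background model.
Both strands are scanned; minus-strand hits are reported at window-forward
offsets with the matched sequence in motif orientation. Placements touching
an N are skipped. For set-level statistics the default background is the
base composition of the analyzed window set; for single-window scans it is
uniform unless given.

The set over-representation score is CLOVER-style: per sequence, the
arithmetic mean over all placements (both strands) of the likelihood ratio
`Π_i p_i(b_i)/q(b_i)`; the set score is the mean over sequences of the
natural log of that per-sequence mean. Its null distribution is built by
independently shuffling each window's bases (composition-preserving), and
`p = (1 + #{null ≥ observed}) / (n_null + 1)`. This score is fixed by this
package so results are reproducible without the original CLOVER tool; it is
not claimed to be numerically identical to it.

Site collection takes, per gene, the maximum-score site above a bit
threshold (ties → smallest offset, then '+' strand), extends it by
`flank_width` bases on each side in motif orientation (default 5 bp), and
flags extensions clipped by the window edge; clipped sites are excluded from
alignment-based statistics. The default threshold of 5 bits sits well below
the score of essentially any site drawn from the packaged ISRE matrix and
well above the vast majority of background placements in promoter-like
composition.

### PFMs, information content, divergence

From n aligned sites, `p_i(b) = (count_i(b) + c) / (n + 4c)` with
pseudocount c = 0.5 (half-Laplace) by default — enough to keep every KL term
finite. Information content per position is `2 + Σ_b p log2 p − e(n)` bits
with the logo-standard small-sample correction `e(n) = 3/(2·ln2·n)`
(toggleable), clipped below at zero. Logo letter heights are
`p_i(b) × IC_i`, so each column's heights sum to its IC.

The divergence between group PFMs is the Jeffreys-type symmetrization,
per position:

    D_i = ½ [ Σ_b p_i(b) log2 (p_i(b)/q_i(b)) + Σ_b q_i(b) log2 (q_i(b)/p_i(b)) ]

averaged over positions to `mean_d` (bits throughout, matching logo units).
Significance comes from label permutation: pool the two site sets, shuffle
group labels preserving sizes, rebuild both PFMs (same pseudocount), and
recompute `mean_d`; `p = (1 + #{perm ≥ observed}) / (n_perm + 1)`, default
n_perm = 999. Permutation was chosen because it is assumption-free and exact
under exchangeability; no claim is made that it numerically matches whatever
procedure produced the original study's P<0.05. Sites are anchored on the
PWM match coordinates; no realignment is performed.

K-means clustering of sites ("unguided" similarity assessment) encodes each
site as a length-4L one-hot vector and runs Lloyd iterations to convergence,
best of 20 restarts by within-cluster sum of squares, reporting silhouette
and purity against group labels per k; the recommended k maximizes the
silhouette.

### Assay formulas

ΔΔCt: `fold = 2^−[(Ct_tt − Ct_rt) − (Ct_tc − Ct_rc)]`, efficiency 2 exact;
replicates reduce by mean with standard deviations propagated in quadrature
to a fold interval. Standard curve: least squares of Ct on log10 quantity,
`efficiency = 10^(−1/slope) − 1`; a non-negative slope is rejected. ChIP
enrichment is percent of the 2% input aliquot as measured (not rescaled to
total chromatin; a `rescale_total` flag gives the other convention). Plaque
titre is `count / (dilution × volume)`, with zero counts reported as below
the detection limit `1/(dilution × volume)`.

## The synthetic generator: what it emulates and what it does not

**Expression.** Four conditions (control, IFNβ, Y701F-STAT1, IFNγ), two
replicates each. Per-gene baselines are log-normal (log2 mean 7, sd 2);
replicate noise is additive Gaussian on log2 (sd 0.2), i.e. multiplicative
on intensities, the microarray convention. Planted memberships default to
the 48/29/73 structure (IFNβ-only / U-ISGF3 / IFNγ-overlap, totalling 150
IFNβ-induced genes) among 8000 genes, with per-gene folds log-uniform on
[4, 16]. Two choices matter and were made once, on realism grounds:

* *Planted fraction.* Quantile normalization mixes rank means across
  columns, so when a large fraction of genes is induced in one condition the
  planted folds are compressed — at ~15% planted the compression can push a
  4-fold gene below the 2-fold gate, and no noise setting rescues it. On the
  real array the induced fraction was <1%. The default 150/8000 ≈ 2% keeps
  the normalization near-neutral for planted genes, which is the regime the
  published filtering assumes.
* *Detectability floor.* Planted baselines are floored at log2 = 5 (≈32
  intensity units) because the study's induced genes are by construction
  detectably expressed; without the floor a "planted" gene can sit below the
  signal gate and the truth comparison would penalize a correctly working
  filter.

The generator does not model bead-level variance, probe effects, batch
structure, or between-array scale differences; passing recovery tests shows
the filters and set algebra are correct under idealized log-normal noise,
not that the pipeline is robust to array artefacts.

**Promoters.** Two groups of 30 sequences, 3000 bp, i.i.d. background with
human promoter-like composition A/C/G/T = 0.3/0.2/0.2/0.3 (a first-order
transition model is accepted as an alternative). Each promoter carries one
core drawn column-wise from the ISRE matrix (multiple-site mode behind
`sites_per_promoter`; 0 gives motif-free nulls); the `u_isgf3` group's 5-bp
flanks each match a fixed group consensus with probability
`flank_conservation` (default 0.9; 0 reduces both groups to the same
process, the exchangeable null). Minus-strand insertions (probability 0.5)
reverse-complement the whole flank+core+flank block. The recorded truth
(offsets, strands, core and flank sequences) is byte-checked against the
emitted FASTA in tests.

**The packaged ISRE matrix** is a synthetic stand-in (curated commercial
motif collections cannot be redistributed): 13 positions around the
consensus `NGAAANTGAAACT`, counts 94/2/2/2 at the ten consensus-fixed
positions, a 40/10/40/10 A/G-leaning first position, and a uniform N
position. The sharpness mirrors curated ISRE logos, whose GAAA repeats are
nearly invariant; it also gives planted cores a comfortable scoring margin
over background hits in A/T-rich sequence, which the site-recovery tests
rely on. Any JASPAR/TRANSFAC/MEME matrix can be substituted.

## Numerical choices and degenerate inputs

* Quantile normalization ties: ordinal (position-stable) rank assignment.
* Zero-variance genes in the t-test: p set to 0 when means differ, 1 when
  equal, instead of NaN.
* Matrices: probability columns must sum to 1 within 1e-9; zero cells are a
  numeric error whose remediation (raise the pseudocount) is named in the
  message; counts convert as `(count + pc)/(total + 4·pc)`.
* Scan ties: score descending, then offset ascending, '+' before '−'.
* p-value estimators always add one to numerator and denominator, so
  `p ∈ [1/(n+1), 1]` and a permutation p of zero is impossible.
* K-means: scikit-learn Lloyd with tol 1e-8, max 300 iterations, n_init
  restarts; silhouette is NaN (not an error) at k = 1 or k = n.
* Seeds: every stochastic routine takes an explicit seed; equal seeds give
  byte-identical artifacts.

## Problem sizes used in the checks

Calibration and power checks run at the sizes the design prescribes: the
type-I calibration of the divergence pipeline uses 1000 simulated datasets ×
199 permutations (rejection within the 95% binomial interval of 0.05);
power uses 100 seeded runs of the conservation-0.9 fixture (≥90 must reject
at α = 0.05); enrichment calibration uses 500 motif-free sets of 8 × 100-bp
windows with a 39-replicate shuffle null, a grid on which 0.05 is exactly
attainable. The expression emulation runs at 8000 genes. Oracle-equivalence
checks compare against exhaustive brute-force enumeration on 100 windows of
up to 100 bp at 1e-9 tolerance.

## Known limitations

* The CLOVER-style score and the permutation null are defined replacements
  for tools and tests the original analysis names but does not specify; they
  reproduce the *kind* of inference, not its exact numbers.
* The classifier assumes two or more replicates per condition and linear,
  non-negative intensities; no background correction or probe-to-gene
  collapsing beyond max-mean selection is provided.
* Flank divergence is tested at fixed width with anchored alignment; motifs
  differing by indels or offset shifts between groups are out of scope.
* With n = 2 duplicates the pooled t-test has 2 degrees of freedom; borderline
  folds near the gate can flip induction calls between seeds, which is a
  property of the published design, not of the implementation.
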