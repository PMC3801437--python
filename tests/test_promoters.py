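import numpy as np
import pytest

from conftest import brute_clover_score, brute_scan_scores, random_dna

from isrekit.matrices import PositionMatrix
from isrekit.promoters import (
    clover_set_score,
    collect_group_sites,
    enrichment_pvalue,
    extract_promoter_windows,
    reverse_complement,
    scan_pwm,
)
from isrekit.simulate import PromoterSimConfig, simulate_promoters


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def genome(tmp_path_factory):
    rng = np.random.default_rng(77)
    seq = random_dna(rng, 10000)
    path = tmp_path_factory.mktemp("genome") / "genome.fa"
    path.write_text(">chr1\n" + "\n".join(seq[i : i + 80] for i in range(0, len(seq), 80)) + "\n")
    return path, seq


def _tss_frame(rows):
    import pandas as pd

    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


class TestExtractWindows:
    def test_plus_strand_window_coordinates(self, genome):
        path, seq = genome
        (w,) = extract_promoter_windows(_tss_frame([("g", "chr1", 3000, "+")]), path)
        assert (w.start, w.end) == (499, 3500)  # 1-based 500..3500
        assert len(w) == 3001 and not w.truncated
        assert w.sequence == seq[499:3500]

    def test_minus_strand_window_mirrored_and_revcomped(self, genome):
        path, seq = genome
        (w,) = extract_promoter_windows(_tss_frame([("g", "chr1", 3000, "-")]), path)
        assert (w.start, w.end) == (2499, 5500)  # 1-based 2500..5500
        assert w.sequence == reverse_complement(seq[2499:5500])
        assert len(w) == 3001

    def test_chromosome_edge_clips_and_flags(self, genome):
        path, seq = genome
        (w,) = extract_promoter_windows(_tss_frame([("g", "chr1", 100, "+")]), path)
        assert (w.start, w.end) == (0, 600)  # 1-based 1..600
        assert w.truncated and len(w) == 600

    def test_unknown_chromosome_raises(self, genome):
        path, _ = genome
        with pytest.raises(KeyError):
            extract_promoter_windows(_tss_frame([("g", "chrX", 100, "+")]), path)

    def test_tss_outside_chromosome_raises(self, genome):
        path, _ = genome
        with pytest.raises(ValueError):
            extract_promoter_windows(_tss_frame([("g", "chr1", 20000, "+")]), path)

    def test_custom_window_size(self, genome):
        path, _ = genome
        (w,) = extract_promoter_windows(
            _tss_frame([("g", "chr1", 5000, "+")]), path, upstream=100, downstream=50
        )
        assert len(w) == 151 and not w.truncated


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _sharp_pwm(consensus: str, p_major=0.97) -> PositionMatrix:
    idx = {b: i for i, b in enumerate("ACGT")}
    probs = np.full((len(consensus), 4), (1 - p_major) / 3)
    for i, b in enumerate(consensus):
        probs[i, idx[b]] = p_major
    return PositionMatrix(probs, kind="probability", pseudocount=0.0)


class TestScanPwm:
    def test_degenerate_pwm_closed_form(self, uniform_bg):
        pwm = _sharp_pwm("ACGT", p_major=1.0 - 3e-12)  # effectively certain
        sites = scan_pwm(("g", "ACGT"), pwm, threshold=7.9, background=uniform_bg,
                         both_strands=False)
        assert len(sites) == 1
        assert sites[0].score == pytest.approx(4 * np.log2(4), abs=1e-7)

    def test_revcomp_window_flips_strands_and_mirrors_offsets(self, isre_pwm, uniform_bg):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 60)
        fwd = scan_pwm(("g", seq), isre_pwm, threshold=-1e9, background=uniform_bg)
        rev = scan_pwm(("g", reverse_complement(seq)), isre_pwm, threshold=-1e9,
                       background=uniform_bg)
        n = len(seq) - isre_pwm.length
        mapped = {
            (n - s.offset, "-" if s.strand == "+" else "+", round(s.score, 9))
            for s in rev
        }
        orig = {(s.offset, s.strand, round(s.score, 9)) for s in fwd}
        assert mapped == orig

    def test_scores_match_bruteforce_enumeration(self, isre_pwm, uniform_bg):
        rng = np.random.default_rng(11)
        for _ in range(10):
            seq = random_dna(rng, 50)
            sites = scan_pwm(("g", seq), isre_pwm, threshold=-1e9, background=uniform_bg)
            got = {(s.offset, s.strand): s.score for s in sites}
            expected = brute_scan_scores(seq, isre_pwm.probabilities(), uniform_bg)
            assert got.keys() == expected.keys()
            for k in expected:
                assert got[k] == pytest.approx(expected[k], abs=1e-9)

    def test_n_positions_skipped(self, isre_pwm, uniform_bg):
        seq = "A" * 20 + "N" + "A" * 20
        sites = scan_pwm(("g", seq), isre_pwm, threshold=-1e9, background=uniform_bg)
        L = isre_pwm.length
        for s in sites:
            assert "N" not in seq[s.offset : s.offset + L]

    def test_short_window_returns_empty(self, isre_pwm):
        assert scan_pwm(("g", "ACGT"), isre_pwm, threshold=0.0) == []

    def test_sites_sorted_by_score_then_offset(self, isre_pwm, uniform_bg):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 200)
        sites = scan_pwm(("g", seq), isre_pwm, threshold=-1e9, background=uniform_bg)
        keys = [(-s.score, s.offset) for s in sites]
        assert keys == sorted(keys)


# ---------------------------------------------------------------------------
# CLOVER-style set score and enrichment
# ---------------------------------------------------------------------------

class TestCloverScore:
    def test_single_placement_equals_log_lr(self, isre_pwm, uniform_bg):
        seq = isre_pwm.consensus()
        score = clover_set_score([("w", seq)], isre_pwm, background=uniform_bg,
                                 both_strands=False)
        (site,) = scan_pwm(("w", seq), isre_pwm, threshold=-1e9, both_strands=False,
                           background=uniform_bg)
        assert score == pytest.approx(np.log(2.0**site.score), abs=1e-12)

    def test_pwm_equal_to_background_scores_zero(self):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwm = PositionMatrix(np.tile(bg, (5, 1)), kind="probability", pseudocount=0.0)
        rng = np.random.default_rng(1)
        score = clover_set_score([("w", random_dna(rng, 30))], pwm, background=bg)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_enumeration(self, isre_pwm, uniform_bg):
        rng = np.random.default_rng(21)
        windows = [("w%d" % i, random_dna(rng, 40)) for i in range(10)]
        got = clover_set_score(windows, isre_pwm, background=uniform_bg)
        expected = brute_clover_score([s for _, s in windows],
                                      isre_pwm.probabilities(), uniform_bg)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_strand_symmetry_of_set_score(self, isre_pwm, uniform_bg):
        rng = np.random.default_rng(31)
        windows = [("w%d" % i, random_dna(rng, 40)) for i in range(6)]
        rc = [(g, reverse_complement(s)) for g, s in windows]
        a = clover_set_score(windows, isre_pwm, background=uniform_bg)
        b = clover_set_score(rc, isre_pwm, background=uniform_bg)
        assert a == pytest.approx(b, abs=1e-9)

    def test_empty_window_set_rejected(self, isre_pwm):
        with pytest.raises(ValueError):
            clover_set_score([], isre_pwm)


class TestEnrichment:
    def test_p_value_lower_bound_on_planted_fixture(self, isre_pwm):
        groups, _ = simulate_promoters(PromoterSimConfig(seed=5, length=300, n_per_group=30))
        res = enrichment_pvalue(groups["isgf3_only"], isre_pwm, n_null=999, seed=5)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_value_bounds_and_determinism(self, isre_pwm):
        rng = np.random.default_rng(9)
        windows = [("w%d" % i, random_dna(rng, 60)) for i in range(5)]
        r1 = enrichment_pvalue(windows, isre_pwm, n_null=49, seed=3)
        r2 = enrichment_pvalue(windows, isre_pwm, n_null=49, seed=3)
        assert r1 == r2
        assert 1 / 50 <= r1.p_value <= 1.0

    def test_small_n_null_rejected(self, isre_pwm):
        with pytest.raises(ValueError):
            enrichment_pvalue([("w", "A" * 30)], isre_pwm, n_null=5, seed=0)


# ---------------------------------------------------------------------------
# site collection
# ---------------------------------------------------------------------------

class TestCollectSites:
    def test_tie_resolves_to_smallest_offset(self, uniform_bg):
        pwm = _sharp_pwm("AAACC")
        core = "AAACC"  # revcomp GGTTT never occurs in the G background
        seq = "G" * 10 + core + "G" * 25 + core + "G" * 5
        (site,) = collect_group_sites([("g", seq)], pwm, threshold=5.0,
                                      flank_width=2, background=uniform_bg)
        assert site.offset == 10 and site.strand == "+"

    def test_extended_length_and_clipping(self, uniform_bg):
        pwm = _sharp_pwm("ACGTA")
        seq = "ACGTA" + "T" * 30  # best site flush with the window start
        (site,) = collect_group_sites([("g", seq)], pwm, threshold=5.0,
                                      flank_width=3, background=uniform_bg)
        assert site.clipped and len(site.extended) == 5 + 3  # left flank lost
        seq2 = "TTTT" + "ACGTA" + "T" * 30
        (site2,) = collect_group_sites([("g", seq2)], pwm, threshold=5.0,
                                       flank_width=3, background=uniform_bg)
        assert not site2.clipped and len(site2.extended) == 5 + 6

    def test_genes_without_sites_are_omitted(self, uniform_bg):
        pwm = _sharp_pwm("ACGTACGT")
        sites = collect_group_sites([("g", "T" * 40)], pwm, threshold=5.0,
                                    background=uniform_bg)
        assert sites == []

    def test_planted_offsets_recovered(self, isre_pwm):
        cfg = PromoterSimConfig(seed=7)
        groups, truth = simulate_promoters(cfg)
        sites = collect_group_sites(groups["u_isgf3"], isre_pwm, threshold=5.0,
                                    flank_width=cfg.flank_width)
        planted = {s.seq_id: (s.offset, s.strand) for s in truth.sites
                   if s.group == "u_isgf3"}
        recovered = {s.gene_id: (s.offset, s.strand) for s in sites}
        matches = sum(recovered.get(k) == v for k, v in planted.items())
        assert matches == len(planted)

    def test_minus_strand_extended_sequence_contains_flanks(self, isre_pwm):
        cfg = PromoterSimConfig(seed=13, strand_prob=1.0, flank_conservation=1.0)
        groups, truth = simulate_promoters(cfg)
        sites = collect_group_sites(groups["u_isgf3"], isre_pwm, threshold=5.0,
                                    flank_width=cfg.flank_width)
        by_id = {s.seq_id: s for s in truth.sites if s.group == "u_isgf3"}
        for s in sites:
            t = by_id[s.gene_id]
            if (s.offset, s.strand) == (t.offset, t.strand):
                assert s.extended == t.flank5 + t.core + t.flank3
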