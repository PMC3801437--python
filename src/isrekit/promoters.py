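"""Promoter windows and PWM scanning.

Promoter windows span 2500 bp upstream to 500 bp downstream of the
annotated TSS (3001 bp including the TSS base, the inclusive convention).
Scanning scores every placement of a PWM on both strands with the log2
likelihood ratio against a background model; set-level over-representation
uses a CLOVER-style score (per-sequence mean likelihood ratio, mean log
across sequences) with a composition-preserving shuffled-sequence null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .matrices import BASES, PositionMatrix, sequence_composition

__all__ = [
    "PromoterWindow",
    "MotifSite",
    "EnrichmentResult",
    "read_tss_table",
    "extract_promoter_windows",
    "scan_pwm",
    "clover_set_score",
    "enrichment_pvalue",
    "collect_group_sites",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# integer encoding: A=0 C=1 G=2 T=3, N (or any other letter) = 4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter sequence window, read 5'->3' relative to the gene.

    ``start``/``end`` are 0-based half-open genomic coordinates of the
    window on the reference; for minus-strand genes the stored sequence is
    the reverse complement of that interval.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifSite:
    """A scored PWM occurrence within a promoter window.

    ``offset`` is 0-based within the window (window forward orientation);
    ``strand`` is '+' when the motif matches the window as read, '-' when
    it matches the reverse complement.  ``core`` and ``extended`` are
    reported in motif orientation.
    """

    gene_id: str
    offset: int
    strand: str
    score: float
    core: str
    extended: str | None = None
    clipped: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    set_raw_score: float
    p_value: float
    n_null: int
    null_mean: float
    null_sd: float
    seed: int | None


# ---------------------------------------------------------------------------
# promoter window extraction
# ---------------------------------------------------------------------------

def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS table as BED6 (0-based start = TSS-1) or headered TSV.

    The TSV dialect has columns ``gene, chrom, tss, strand`` with ``tss``
    1-based.  Returns a frame with those four columns.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0].split("\t")
    if len(first) >= 6 and first[1].isdigit() and first[2].isdigit():
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = pd.DataFrame(
            {
                "gene": bed[3],
                "chrom": bed[0],
                "tss": bed[1].astype(int) + 1,
                "strand": bed[5],
            }
        )
    else:
        df = pd.read_csv(path, sep="\t")
        missing = {"gene", "chrom", "tss", "strand"} - set(df.columns)
        if missing:
            raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    return df[["gene", "chrom", "tss", "strand"]]


def extract_promoter_windows(
    tss_table: pd.DataFrame | str | Path,
    genome_fasta: str | Path,
    upstream: int = 2500,
    downstream: int = 500,
) -> list[PromoterWindow]:
    """Extract per-gene promoter windows from an indexed genome FASTA.

    Plus-strand windows cover 1-based ``[TSS - upstream, TSS + downstream]``
    (``upstream + downstream + 1`` bases, TSS included); minus-strand
    windows are mirrored and reverse-complemented so the output reads
    5'->3' of the gene.  Windows running off a chromosome end are clipped
    and flagged ``truncated``.
    """
    if not isinstance(tss_table, pd.DataFrame):
        tss_table = read_tss_table(tss_table)
    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    windows: list[PromoterWindow] = []
    for rec in tss_table.itertuples(index=False):
        if rec.chrom not in genome:
            raise KeyError(f"chromosome {rec.chrom!r} not in genome FASTA")
        chrom_len = len(genome[rec.chrom])
        tss = int(rec.tss)
        if not (1 <= tss <= chrom_len):
            raise ValueError(f"TSS {tss} outside chromosome {rec.chrom} for {rec.gene}")
        if rec.strand == "+":
            lo1, hi1 = tss - upstream, tss + downstream
        elif rec.strand == "-":
            lo1, hi1 = tss - downstream, tss + upstream
        else:
            raise ValueError(f"bad strand {rec.strand!r} for {rec.gene}")
        start = max(lo1 - 1, 0)
        end = min(hi1, chrom_len)
        truncated = (start != lo1 - 1) or (end != hi1)
        seq = genome[rec.chrom][start:end]
        if rec.strand == "-":
            seq = reverse_complement(seq)
        windows.append(
            PromoterWindow(
                gene_id=str(rec.gene),
                chrom=str(rec.chrom),
                strand=str(rec.strand),
                start=start,
                end=end,
                sequence=seq,
                truncated=truncated,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _as_id_seq(window) -> tuple[str, str]:
    """Accept PromoterWindow, Bio SeqRecord, (id, seq) pair, or str."""
    if isinstance(window, PromoterWindow):
        return window.gene_id, window.sequence
    if hasattr(window, "seq") and hasattr(window, "id"):
        return str(window.id), str(window.seq)
    if isinstance(window, tuple) and len(window) == 2:
        return str(window[0]), str(window[1])
    if isinstance(window, str):
        return "seq", window
    raise TypeError(f"cannot interpret {type(window).__name__} as a sequence window")


def _placement_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """LLR score at every placement; positions overlapping N score -inf."""
    L = lom.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    # lookup table with a -inf row for N
    table = np.vstack([lom.T, np.full((1, L), -np.inf)])  # (5, L)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    return table[win, np.arange(L)].sum(axis=1)


def scan_pwm(
    window,
    pwm: PositionMatrix,
    threshold: float = 0.0,
    both_strands: bool = True,
    background: np.ndarray | None = None,
) -> list[MotifSite]:
    """All PWM placements scoring at or above ``threshold`` bits.

    The score of a placement is ``sum_i log2(p_i(b_i) / q(b_i))``.
    Placements overlapping an N are skipped.  Sites are returned sorted by
    score descending, then offset ascending, '+' before '-'.  A window
    shorter than the motif yields an empty list with a warning.
    """
    gene_id, seq = _as_id_seq(window)
    L = pwm.length
    if len(seq) < L:
        logger.warning("window %s shorter than motif (%d < %d)", gene_id, len(seq), L)
        return []
    lom = pwm.log_odds(background)
    codes = encode(seq)
    sites: list[MotifSite] = []
    fwd = _placement_scores(codes, lom)
    for off in np.nonzero(fwd >= threshold)[0]:
        sites.append(
            MotifSite(gene_id, int(off), "+", float(fwd[off]), seq[off : off + L].upper())
        )
    if both_strands:
        rc = reverse_complement(seq)
        rev = _placement_scores(encode(rc), lom)
        n = len(seq) - L + 1
        for j in np.nonzero(rev >= threshold)[0]:
            off = n - 1 - int(j)  # offset in window-forward coordinates
            core = rc[j : j + L].upper()
            sites.append(MotifSite(gene_id, off, "-", float(rev[j]), core))
    sites.sort(key=lambda s: (-s.score, s.offset, s.strand != "+"))
    return sites


# ---------------------------------------------------------------------------
# CLOVER-style set enrichment
# ---------------------------------------------------------------------------

def _sequence_mean_lr(codes: np.ndarray, lom: np.ndarray, both_strands: bool) -> float:
    """Mean likelihood ratio over all valid placements of one sequence."""
    scores = _placement_scores(codes, lom)
    if both_strands:
        rev = codes[::-1]
        rc = np.where(rev == 4, 4, 3 - rev)  # complement; N stays N
        scores = np.concatenate([scores, _placement_scores(rc, lom)])
    valid = scores[np.isfinite(scores)]
    if valid.size == 0:
        raise ValueError("no N-free placement in a window")
    return float(np.mean(np.exp2(valid)))


def clover_set_score(
    windows: Sequence,
    pwm: PositionMatrix,
    background: np.ndarray | None = None,
    both_strands: bool = True,
) -> float:
    """CLOVER-style raw over-representation score for a window set.

    Per sequence: the arithmetic mean over all placements (both strands by
    default) of the likelihood ratio ``prod_i p_i(b_i)/q(b_i)``; the set
    score is the mean over sequences of the natural log of that mean.
    Background defaults to the base composition of the analyzed windows.
    """
    pairs = [_as_id_seq(w) for w in windows]
    if not pairs:
        raise ValueError("empty window set")
    if background is None:
        background = sequence_composition(seq for _, seq in pairs)
    lom = pwm.log_odds(background)
    L = pwm.length
    per_seq = []
    for gid, seq in pairs:
        if len(seq) < L:
            raise ValueError(f"window {gid} shorter than motif length {L}")
        per_seq.append(np.log(_sequence_mean_lr(encode(seq), lom, both_strands)))
    return float(np.mean(per_seq))


def enrichment_pvalue(
    windows: Sequence,
    pwm: PositionMatrix,
    n_null: int = 999,
    seed: int | None = None,
    background: np.ndarray | None = None,
    both_strands: bool = True,
) -> EnrichmentResult:
    """Permutation p-value for motif over-representation in a window set.

    Null replicates shuffle each window's bases independently
    (composition-preserving), and ``p = (1 + #{null >= observed}) /
    (n_null + 1)``.  Deterministic under a fixed seed.
    """
    if n_null < 19:
        raise ValueError("n_null must be >= 19 for a usable p-value grid")
    pairs = [_as_id_seq(w) for w in windows]
    if background is None:
        background = sequence_composition(seq for _, seq in pairs)
    observed = clover_set_score(pairs, pwm, background, both_strands)
    rng = np.random.default_rng(seed)
    lom = pwm.log_odds(background)
    coded = [encode(seq) for _, seq in pairs]
    null_scores = np.empty(n_null)
    for r in range(n_null):
        vals = [
            np.log(_sequence_mean_lr(rng.permutation(c), lom, both_strands))
            for c in coded
        ]
        null_scores[r] = np.mean(vals)
    hits = int(np.sum(null_scores >= observed))
    p = (1 + hits) / (n_null + 1)
    return EnrichmentResult(
        set_raw_score=observed,
        p_value=p,
        n_null=n_null,
        null_mean=float(null_scores.mean()),
        null_sd=float(null_scores.std(ddof=1)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# site collection for PFM building
# ---------------------------------------------------------------------------

def collect_group_sites(
    windows: Sequence,
    pwm: PositionMatrix,
    threshold: float,
    flank_width: int = 5,
    per_gene: str = "best",
    background: np.ndarray | None = None,
    both_strands: bool = True,
) -> list[MotifSite]:
    """Best (or all) above-threshold sites per gene, flank-extended.

    The selected site is extended by ``flank_width`` bases on each side in
    motif orientation, giving aligned sequences of length
    ``motif + 2 * flank_width`` for PFM building.  Extensions clipped by a
    window edge are flagged ``clipped`` (and are shorter).  Ties on score
    resolve to the smallest offset, then the '+' strand.  Genes with no
    site above threshold are omitted with a log message.
    """
    if per_gene not in ("best", "all"):
        raise ValueError("per_gene must be 'best' or 'all'")
    if background is None:
        background = sequence_composition(_as_id_seq(w)[1] for w in windows)
    out: list[MotifSite] = []
    L = pwm.length
    for w in windows:
        gid, seq = _as_id_seq(w)
        sites = scan_pwm((gid, seq), pwm, threshold, both_strands, background)
        if not sites:
            logger.info("gene %s: no site above threshold %.3g; omitted", gid, threshold)
            continue
        chosen = sites[:1] if per_gene == "best" else sites
        for s in chosen:
            lo = s.offset - flank_width
            hi = s.offset + L + flank_width
            clipped = lo < 0 or hi > len(seq)
            ext = seq[max(lo, 0) : min(hi, len(seq))].upper()
            if s.strand == "-":
                ext = reverse_complement(ext)
            out.append(replace(s, extended=ext, clipped=clipped))
    return out


def sites_to_frame(sites: Iterable[MotifSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene_id,
                "offset": s.offset,
                "strand": s.strand,
                "score_bits": s.score,
                "core": s.core,
                "extended": s.extended,
                "clipped": s.clipped,
            }
            for s in sites
        ]
    )
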