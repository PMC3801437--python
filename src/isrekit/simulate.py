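"""Synthetic expression matrices and promoter sets with planted truth.

The generator mirrors the study design the pipeline analyzes: duplicate
bead-array intensities for four conditions (untreated control, IFN-beta
6 h, Y701F-STAT1 overexpression, IFN-gamma 6 h) with planted induced gene
sets reproducing the 150 = 48 + 29 + 73 partition structure, and 3-kb
promoter sequences with an embedded ISRE core where one group
additionally carries conserved 5'/3' flanks.  Every planted fact is
recorded in a :class:`SyntheticTruth` so classification, scanning, site
collection and divergence can be verified end-to-end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .expression import ExpressionMatrix
from .matrices import BASES, PositionMatrix, canonical_isre_matrix
from .promoters import reverse_complement

__all__ = [
    "ExpressionSimConfig",
    "PromoterSimConfig",
    "PlantedSite",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_promoters",
    "write_promoter_fasta",
    "write_sites_bed",
]

CONDITIONS = ("control", "ifnb", "yf", "ifng")

#: human promoter-like i.i.d. base composition (A, C, G, T)
DEFAULT_COMPOSITION = (0.3, 0.2, 0.2, 0.3)


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the expression simulation.

    ``set_sizes`` gives the planted memberships in order
    ``(ifnb_only, u_isgf3, ifng_overlap)``: all three sets are
    IFN-beta-induced; the second is additionally induced by Y701F-STAT1
    and the third by IFN-gamma.  Intensities are log-normal: a per-gene
    baseline on the log2 scale plus additive Gaussian replicate noise
    (multiplicative on the linear scale, the microarray convention).

    ``n_genes`` defaults to 8000 so the planted fraction (~2%) is of the
    order seen on a whole-array experiment; quantile normalization is
    only distribution-preserving for induced genes when few genes change.
    Planted baselines are floored at ``planted_floor_log2`` because
    induced ISGs are, by construction of the study, detectably expressed.
    """

    n_genes: int = 8000
    set_sizes: tuple[int, int, int] = (48, 29, 73)
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    induced_fold_range: tuple[float, float] = (4.0, 16.0)
    replicate_count: int = 2
    noise_sd_log2: float = 0.2
    planted_floor_log2: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.set_sizes) != 3 or any(s < 0 for s in self.set_sizes):
            raise ValueError("set_sizes must be three non-negative counts")
        if sum(self.set_sizes) > self.n_genes:
            raise ValueError("planted set sizes exceed n_genes")
        lo, hi = self.induced_fold_range
        if not (1.0 < lo <= hi):
            raise ValueError("induced_fold_range lower bound must be > 1")
        if self.replicate_count < 2:
            raise ValueError("replicate_count must be >= 2")
        if self.noise_sd_log2 < 0 or self.baseline_log2_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class PromoterSimConfig:
    """Parameters of the promoter simulation.

    Two groups of ``n_per_group`` promoters each carry one ISRE core drawn
    from ``core_pwm``; in the ``u_isgf3`` group each flank base matches a
    fixed group-specific flank consensus with probability
    ``flank_conservation`` (0 reduces flanks to background, making the two
    groups exchangeable).  ``insert_position_range`` bounds the 0-based
    core start; ``background`` is either a length-4 base composition or a
    4x4 first-order transition matrix.
    """

    n_per_group: int = 30
    length: int = 3000
    background: tuple = DEFAULT_COMPOSITION
    core_pwm: PositionMatrix | None = None
    flank_width: int = 5
    flank_conservation: float = 0.9
    insert_position_range: tuple[int, int] | None = None
    strand_prob: float = 0.5
    sites_per_promoter: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_pwm is None:
            object.__setattr__(self, "core_pwm", canonical_isre_matrix())
        if not (0.0 <= self.flank_conservation <= 1.0):
            raise ValueError("flank_conservation must be in [0, 1]")
        if not (0.0 <= self.strand_prob <= 1.0):
            raise ValueError("strand_prob must be in [0, 1]")
        if self.flank_width < 0 or self.n_per_group < 1 or self.sites_per_promoter < 0:
            raise ValueError("counts must be non-negative (n_per_group >= 1)")
        L = self.core_pwm.length
        if L + 2 * self.flank_width > self.length:
            raise ValueError("core plus flanks longer than the promoter")
        if self.insert_position_range is None:
            object.__setattr__(
                self,
                "insert_position_range",
                (self.flank_width, self.length - L - self.flank_width),
            )
        lo, hi = self.insert_position_range
        if lo < self.flank_width or hi + L + self.flank_width > self.length or lo > hi:
            raise ValueError("insert window plus core plus flanks must fit within length")

    @property
    def core_length(self) -> int:
        return self.core_pwm.length


@dataclass(frozen=True)
class PlantedSite:
    """A planted ISRE insertion, recorded in motif orientation."""

    seq_id: str
    group: str
    offset: int  # 0-based core start in the emitted sequence (forward coords)
    strand: str
    core: str
    flank5: str
    flank3: str


@dataclass(frozen=True)
class SyntheticTruth:
    gene_sets: dict = field(default_factory=dict)
    sites: tuple = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_sets": {k: sorted(v) for k, v in self.gene_sets.items()},
            "sites": [asdict(s) for s in self.sites],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            gene_sets={k: frozenset(v) for k, v in payload["gene_sets"].items()},
            sites=tuple(PlantedSite(**s) for s in payload["sites"]),
        )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: ExpressionSimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Duplicate-array intensities with planted induced gene sets.

    Planted genes get a per-gene fold drawn log-uniformly from
    ``induced_fold_range``, applied to the conditions where the gene's set
    is induced; identical seeds give identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_planted = sum(config.set_sizes)
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    n_only, n_uisgf3, n_ifng = config.set_sizes
    ifnb_only = frozenset(genes[i] for i in planted_idx[:n_only])
    u_isgf3 = frozenset(genes[i] for i in planted_idx[n_only : n_only + n_uisgf3])
    ifng_overlap = frozenset(genes[i] for i in planted_idx[n_only + n_uisgf3 :])
    ifnb_induced = ifnb_only | u_isgf3 | ifng_overlap

    induced_in = {
        "control": frozenset(),
        "ifnb": ifnb_induced,
        "yf": u_isgf3,
        "ifng": ifng_overlap,
    }

    baseline_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                               config.n_genes)
    baseline_log2[planted_idx] = np.maximum(baseline_log2[planted_idx],
                                            config.planted_floor_log2)
    baseline = 2.0 ** baseline_log2
    lo, hi = config.induced_fold_range
    folds = 2.0 ** rng.uniform(np.log2(lo), np.log2(hi), config.n_genes)

    columns, data = [], []
    for cond in CONDITIONS:
        induced = np.array([g in induced_in[cond] for g in genes])
        mean = baseline * np.where(induced, folds, 1.0)
        for rep in range(1, config.replicate_count + 1):
            noise = (
                2.0 ** rng.normal(0.0, config.noise_sd_log2, config.n_genes)
                if config.noise_sd_log2 > 0
                else 1.0
            )
            columns.append(f"{cond}_r{rep}")
            data.append(mean * noise)
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    samples = pd.DataFrame(
        {
            "condition": [c.rsplit("_r", 1)[0] for c in columns],
            "replicate": [int(c.rsplit("_r", 1)[1]) for c in columns],
        },
        index=pd.Index(columns, name="sample"),
    )
    truth = SyntheticTruth(
        gene_sets={
            "ifnb_induced": ifnb_induced,
            "u_isgf3": u_isgf3,
            "ifng_induced": ifng_overlap,
            "isgf3_only": ifnb_only,
        }
    )
    return ExpressionMatrix(values=values, samples=samples), truth


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _draw_background(rng: np.random.Generator, n: int, background) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape == (4,):
        return rng.choice(4, size=n, p=bg / bg.sum())
    if bg.shape == (4, 4):
        trans = bg / bg.sum(axis=1, keepdims=True)
        out = np.empty(n, dtype=int)
        out[0] = rng.integers(4)
        for i in range(1, n):
            out[i] = rng.choice(4, p=trans[out[i - 1]])
        return out
    raise ValueError("background must be a length-4 composition or a 4x4 transition matrix")


def _draw_from_pwm(rng: np.random.Generator, probs: np.ndarray) -> str:
    return "".join(BASES[rng.choice(4, p=probs[i])] for i in range(probs.shape[0]))


def _decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def simulate_promoters(
    config: PromoterSimConfig,
) -> tuple[dict[str, list[SeqRecord]], SyntheticTruth]:
    """Two promoter groups with planted ISRE cores; one group has conserved flanks.

    Group ``isgf3_only`` promoters carry the core with background flanks;
    group ``u_isgf3`` promoters carry the core plus 5'/3' flanks conserved
    at ``flank_conservation`` toward a fixed group consensus.  Minus-strand
    insertions (probability ``strand_prob``) reverse-complement the whole
    flank+core+flank block.  Identical seeds give identical FASTA output.
    """
    rng = np.random.default_rng(config.seed)
    probs = config.core_pwm.probabilities()
    L = config.core_length
    f = config.flank_width
    lo, hi = config.insert_position_range
    # fixed group-specific flank consensus for the conserved group
    consensus5 = _decode(rng.integers(0, 4, f)) if f else ""
    consensus3 = _decode(rng.integers(0, 4, f)) if f else ""

    groups: dict[str, list[SeqRecord]] = {"isgf3_only": [], "u_isgf3": []}
    sites: list[PlantedSite] = []
    for group in ("isgf3_only", "u_isgf3"):
        conserved = group == "u_isgf3"
        for i in range(config.n_per_group):
            seq_id = f"{group}_{i + 1:03d}"
            codes = _draw_background(rng, config.length, config.background)
            seq = list(_decode(codes))
            placed: list[tuple[int, int]] = []
            for _ in range(config.sites_per_promoter):
                for _attempt in range(1000):
                    p = int(rng.integers(lo, hi + 1))
                    if all(p + L + f <= a or p - f >= b for a, b in placed):
                        break
                else:
                    raise RuntimeError("could not place non-overlapping sites")
                placed.append((p - f, p + L + f))
                core = _draw_from_pwm(rng, probs)

                def _flank(consensus: str) -> str:
                    out = []
                    for j in range(f):
                        bg_base = BASES[_draw_background(rng, 1, config.background)[0]]
                        if conserved and rng.random() < config.flank_conservation:
                            out.append(consensus[j])
                        else:
                            out.append(bg_base)
                    return "".join(out)

                flank5, flank3 = _flank(consensus5), _flank(consensus3)
                block = flank5 + core + flank3
                strand = "-" if rng.random() < config.strand_prob else "+"
                if strand == "-":
                    block = reverse_complement(block)
                seq[p - f : p + L + f] = list(block)
                sites.append(
                    PlantedSite(seq_id, group, p, strand, core, flank5, flank3)
                )
            groups[group].append(
                SeqRecord(Seq("".join(seq)), id=seq_id, description=group)
            )
    truth = SyntheticTruth(
        gene_sets={g: frozenset(r.id for r in recs) for g, recs in groups.items()},
        sites=tuple(sites),
    )
    return groups, truth


def verify_planted_sites(truth: SyntheticTruth, sequences: dict[str, str],
                         core_length: int, flank_width: int) -> bool:
    """Check that each recorded site matches the emitted sequence (strand-aware)."""
    for s in truth.sites:
        seq = sequences[s.seq_id]
        block = seq[s.offset - flank_width : s.offset + core_length + flank_width]
        if s.strand == "-":
            block = reverse_complement(block)
        expected = s.flank5 + s.core + s.flank3
        if block.upper() != expected.upper():
            return False
    return True


def write_promoter_fasta(records: list[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_sites_bed(truth: SyntheticTruth, path: str | Path, core_length: int) -> None:
    """Planted core coordinates as BED6 (0-based half-open)."""
    lines = [
        f"{s.seq_id}\t{s.offset}\t{s.offset + core_length}\t{s.group}\t0\t{s.strand}"
        for s in truth.sites
    ]
    Path(path).write_text("\n".join(lines) + "\n")
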