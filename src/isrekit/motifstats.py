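"""Binding-site population statistics.

Quantifies how two populations of aligned binding sites differ: per-group
position frequency matrices, information content for sequence logos, the
symmetrized position-averaged Kullback-Leibler divergence between group
PFMs, a label-permutation significance test for that divergence, and
unguided k-means clustering of one-hot-encoded sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .matrices import BASE_INDEX, BASES, PositionMatrix

__all__ = [
    "SiteAlignment",
    "DivergenceResult",
    "ClusterResult",
    "build_pfm",
    "information_content",
    "kl_divergence_profile",
    "divergence_permutation_test",
    "kmeans_site_clustering",
    "logo_matrix_export",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class SiteAlignment:
    """A group of aligned, fixed-length binding-site sequences."""

    group: str
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if not seqs:
            raise ValueError("empty site alignment")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("ragged site lengths in alignment")
        bad = set("".join(seqs)) - set(BASES)
        if bad:
            raise ValueError(f"non-ACGT characters in alignment: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def onehot(self) -> np.ndarray:
        """(n_sites, length, 4) one-hot encoding."""
        idx = np.array([[BASE_INDEX[b] for b in s] for s in self.sequences])
        out = np.zeros((*idx.shape, 4))
        np.put_along_axis(out, idx[..., None], 1.0, axis=2)
        return out


@dataclass(frozen=True)
class DivergenceResult:
    """Symmetrized position-averaged KL divergence between two PFMs.

    Permutation fields are ``None`` when only the divergence profile was
    computed (no significance test).
    """

    per_position_d: np.ndarray
    mean_d: float
    n_perm: int | None = None
    p_value: float | None = None
    perm_null: dict | None = None
    seed: int | None = None


@dataclass(frozen=True)
class ClusterResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray  # (k, length, 4) per-position base-frequency vectors
    within_ss: float
    silhouette: float
    purity: float
    seed: int | None = None


def build_pfm(sites: SiteAlignment, pseudocount: float = 0.5) -> PositionMatrix:
    """Position frequency matrix from aligned sites.

    ``p_i(b) = (count_i(b) + pseudocount) / (n + 4 * pseudocount)``; a
    positive pseudocount (default 0.5, half-Laplace) keeps every
    probability finite for downstream KL.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = sites.onehot().sum(axis=0)  # (L, 4)
    n = len(sites)
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    return PositionMatrix(probs, kind="probability", pseudocount=0.0, name=sites.group)


def information_content(
    pfm: PositionMatrix,
    n_sites: int | None = None,
    small_sample_correction: bool = True,
) -> np.ndarray:
    """Per-position information content in bits, as drawn by sequence logos.

    ``IC_i = 2 + sum_b p_i(b) log2 p_i(b) - e(n)`` with the small-sample
    correction ``e(n) = 3 / (2 ln2 n)`` (the logo-tool default), clipped
    below at 0.
    """
    probs = pfm.probabilities()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        if n_sites is None or n_sites <= 0:
            raise ValueError("n_sites must be a positive count when the correction is on")
        ic = ic - 3.0 / (2.0 * LN2 * n_sites)
    return np.clip(ic, 0.0, None)


def _sym_kl(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-position symmetrized KL in bits for (L, 4) probability arrays."""
    d_pq = np.sum(p * np.log2(p / q), axis=1)
    d_qp = np.sum(q * np.log2(q / p), axis=1)
    return 0.5 * (d_pq + d_qp)


def kl_divergence_profile(pfm_a: PositionMatrix, pfm_b: PositionMatrix) -> DivergenceResult:
    """Symmetrized KL divergence per position, averaged over positions.

    ``D_i = 1/2 [ KL(p_i || q_i) + KL(q_i || p_i) ]`` in bits, and
    ``mean_d`` is the average of ``D_i`` over motif positions.  Both
    matrices must be strictly positive (apply a pseudocount upstream).
    """
    p = pfm_a.probabilities()
    q = pfm_b.probabilities()
    if p.shape != q.shape:
        raise ValueError("PFMs must have equal lengths for a positionwise divergence")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("zero probability in PFM; raise the pseudocount")
    d = _sym_kl(p, q)
    return DivergenceResult(per_position_d=d, mean_d=float(d.mean()))


def _mean_d_from_counts(counts_a, n_a, counts_b, n_b, pc):
    pa = (counts_a + pc) / (n_a + 4.0 * pc)
    pb = (counts_b + pc) / (n_b + 4.0 * pc)
    return float(_sym_kl(pa, pb).mean())


def divergence_permutation_test(
    group_a: SiteAlignment,
    group_b: SiteAlignment,
    n_perm: int = 999,
    pseudocount: float = 0.5,
    seed: int | None = None,
) -> DivergenceResult:
    """Label-permutation test of the symmetrized position-averaged KL.

    The null shuffles group labels over the pooled sites, preserving
    group sizes; for each permutation the two PFMs are rebuilt and the
    mean divergence recomputed.  ``p = (1 + #{perm >= observed}) /
    (n_perm + 1)``.  Deterministic under a fixed seed.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for a usable p-value grid")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 sites for a divergence test")
    if group_a.length != group_b.length:
        raise ValueError("site lengths differ between groups")
    if pseudocount <= 0:
        raise ValueError("a positive pseudocount is required for finite KL")
    xa, xb = group_a.onehot(), group_b.onehot()
    pooled = np.concatenate([xa, xb])  # (n, L, 4)
    n_a, n_b = len(group_a), len(group_b)
    total = pooled.sum(axis=0)
    observed = _mean_d_from_counts(xa.sum(axis=0), n_a, xb.sum(axis=0), n_b, pseudocount)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for r in range(n_perm):
        idx = rng.permutation(n_a + n_b)[:n_a]
        ca = pooled[idx].sum(axis=0)
        null[r] = _mean_d_from_counts(ca, n_a, total - ca, n_b, pseudocount)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    pa = build_pfm(group_a, pseudocount).probabilities()
    pb = build_pfm(group_b, pseudocount).probabilities()
    return DivergenceResult(
        per_position_d=_sym_kl(pa, pb),
        mean_d=observed,
        n_perm=n_perm,
        p_value=p,
        perm_null={
            "mean": float(null.mean()),
            "sd": float(null.std(ddof=1)),
            "q05": float(np.quantile(null, 0.05)),
            "q50": float(np.quantile(null, 0.50)),
            "q95": float(np.quantile(null, 0.95)),
        },
        seed=seed,
    )


def kmeans_site_clustering(
    sequences: Sequence[str],
    group_labels: Sequence[str] | None = None,
    k_values: Sequence[int] = (2, 3, 4),
    n_restarts: int = 20,
    seed: int | None = None,
) -> dict[int, ClusterResult]:
    """Unguided k-means over one-hot-encoded sites, one result per k.

    Sites are embedded as length-4L one-hot vectors and clustered by Lloyd
    iterations (best of ``n_restarts`` by within-cluster sum of squares).
    Each result reports silhouette (NaN where undefined, i.e. k=1 or
    k=n) and, when group labels are supplied, cluster purity against them.
    The recommended k is the silhouette argmax.
    """
    pooled = SiteAlignment("pooled", tuple(sequences))
    X = pooled.onehot().reshape(len(pooled), -1)
    n = X.shape[0]
    labels = np.asarray(group_labels) if group_labels is not None else None
    if labels is not None and labels.size != n:
        raise ValueError("group_labels length must match number of sites")
    results: dict[int, ClusterResult] = {}
    for k in k_values:
        if k < 1 or k > n:
            raise ValueError(f"k={k} outside [1, n_sites={n}]")
        km = KMeans(
            n_clusters=k,
            n_init=n_restarts,
            max_iter=300,
            tol=1e-8,
            random_state=seed,
        ).fit(X)
        assign = km.labels_
        sil = float("nan")
        if 1 < k < n and len(np.unique(assign)) > 1:
            sil = float(silhouette_score(X, assign))
        purity = float("nan")
        if labels is not None:
            purity = sum(
                pd.Series(labels[assign == c]).value_counts().iloc[0]
                for c in np.unique(assign)
            ) / float(n)
        results[k] = ClusterResult(
            k=k,
            assignments=assign,
            centroids=km.cluster_centers_.reshape(k, pooled.length, 4),
            within_ss=float(km.inertia_),
            silhouette=sil,
            purity=purity,
            seed=seed,
        )
    return results


def recommended_k(results: dict[int, ClusterResult]) -> int:
    """k maximizing silhouette among the evaluated values."""
    valid = {k: r.silhouette for k, r in results.items() if np.isfinite(r.silhouette)}
    if not valid:
        raise ValueError("no k with a defined silhouette")
    return max(valid, key=valid.get)


def logo_matrix_export(pfm: PositionMatrix, ic: np.ndarray) -> pd.DataFrame:
    """Logo letter heights: ``height(b, i) = p_i(b) * IC_i``.

    Returns a frame with 1-based ``position``, per-base heights in bits,
    and the column information content (= sum of its letter heights).
    """
    probs = pfm.probabilities()
    ic = np.asarray(ic, dtype=float)
    if ic.shape[0] != probs.shape[0]:
        raise ValueError("IC vector length must match PFM length")
    heights = probs * ic[:, None]
    df = pd.DataFrame(heights, columns=list(BASES))
    df.insert(0, "position", np.arange(1, probs.shape[0] + 1))
    df["ic_bits"] = ic
    return df


def plot_logo(logo_table: pd.DataFrame, path) -> None:
    """Stacked-bar rendering of a logo table (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    fig, ax = plt.subplots(figsize=(0.4 * len(logo_table) + 1, 2.5))
    bottom = np.zeros(len(logo_table))
    for b in BASES:
        ax.bar(logo_table["position"], logo_table[b], bottom=bottom, color=colors[b], label=b)
        bottom += logo_table[b].to_numpy()
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
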