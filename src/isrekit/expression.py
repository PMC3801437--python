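"""Expression-based classification of interferon-stimulated genes.

Normalizes an intensity matrix by the quantile method, calls induction
per gene from duplicate arrays (differential p-value, treated-signal and
fold-change gates), and performs the set algebra that defines the
U-ISGF3-induced and ISGF3-only gene groups:

* ``ifnb_induced`` - genes up after IFN-beta treatment;
* ``u_isgf3``      - the subset also induced by Y701F-STAT1 (which cannot
  be tyrosine-phosphorylated, so induction implicates the
  unphosphorylated ISGF3 complex);
* ``isgf3_only``   - IFN-beta-induced genes left after removing the
  U-ISGF3 subset and the IFN-gamma-inducible overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionMatrix",
    "InductionCall",
    "GeneSetPartition",
    "quantile_normalize",
    "score_induction",
    "induced_set",
    "partition_isgs",
    "calls_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples intensity table (linear scale) with sample metadata.

    ``samples`` maps each column of ``values`` to a (condition, replicate)
    pair: a DataFrame indexed by sample id with columns ``condition`` and
    ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite values in expression matrix")
        if np.any(arr < 0):
            raise ValueError("negative intensities in expression matrix")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet missing columns: {sorted(missing)}")

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.samples["condition"]))

    def condition_columns(self, condition: str) -> list[str]:
        cols = self.samples.index[self.samples["condition"] == condition]
        return [c for c in self.values.columns if c in set(cols)]

    def write(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, matrix_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(values=values, samples=samples)


@dataclass(frozen=True)
class InductionCall:
    gene_id: str
    treated_mean: float
    control_mean: float
    fold_change: float
    diff_p: float
    induced: bool
    flagged: bool = False  # control mean was zero; fold undefined


@dataclass(frozen=True)
class GeneSetPartition:
    """The four gene sets and their set-algebra relations."""

    ifnb_induced: frozenset
    u_isgf3: frozenset
    ifng_induced: frozenset
    isgf3_only: frozenset

    def summary(self) -> dict[str, int]:
        remaining = self.ifnb_induced - self.u_isgf3
        return {
            "ifnb_induced": len(self.ifnb_induced),
            "u_isgf3": len(self.u_isgf3),
            "remaining_after_u_isgf3": len(remaining),
            "ifng_induced": len(self.ifng_induced),
            "ifng_overlap": len(remaining & self.ifng_induced),
            "isgf3_only": len(self.isgf3_only),
        }


def quantile_normalize(matrix: ExpressionMatrix | pd.DataFrame):
    """Force every column to share one empirical distribution.

    Each column's rank-r value is replaced by the mean over columns of the
    rank-r sorted values.  Ties within a column are broken by position
    (ordinal ranks), so after normalization every column's sorted value
    vector is exactly the vector of per-rank column means.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in expression matrix")
    order = np.argsort(arr, axis=0, kind="stable")
    rank_means = np.mean(np.take_along_axis(arr, order, axis=0), axis=1)
    out = np.empty_like(arr)
    np.put_along_axis(out, order, rank_means[:, None], axis=0)
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(values=res, samples=matrix.samples)
    return res


def _differential_p(log_t: np.ndarray, log_c: np.ndarray, test: str) -> np.ndarray:
    """Two-sided per-gene p-values on log2 values; rows are genes."""
    if test in ("pooled_t", "welch_t"):
        import warnings

        with warnings.catch_warnings():
            # near-identical duplicates trigger a precision-loss warning;
            # the zero-variance case is handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(log_t, log_c, axis=1, equal_var=(test == "pooled_t"))
        p = np.asarray(res.pvalue, dtype=float)
    elif test == "shrunken_t":
        # pooled per-gene variance moderated toward the median variance
        n1, n2 = log_t.shape[1], log_c.shape[1]
        df_resid = n1 + n2 - 2
        ss = log_t.var(axis=1, ddof=1) * (n1 - 1) + log_c.var(axis=1, ddof=1) * (n2 - 1)
        s2 = ss / df_resid
        d0 = 4.0
        s2_prior = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 0.0
        s2_mod = (d0 * s2_prior + df_resid * s2) / (d0 + df_resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (log_t.mean(axis=1) - log_c.mean(axis=1)) / np.sqrt(
                s2_mod * (1.0 / n1 + 1.0 / n2)
            )
        p = 2.0 * sps.t.sf(np.abs(t), d0 + df_resid)
    else:
        raise ValueError(f"unknown differential test {test!r}")
    # degenerate zero-variance genes: identical replicates
    diff = log_t.mean(axis=1) - log_c.mean(axis=1)
    zero_var = (log_t.var(axis=1) == 0) & (log_c.var(axis=1) == 0)
    p = np.where(zero_var & (diff != 0), 0.0, p)
    p = np.where(zero_var & (diff == 0), 1.0, p)
    return p


def score_induction(
    matrix: ExpressionMatrix,
    treated: str,
    control: str,
    fold_min: float = 2.0,
    p_max: float = 0.05,
    signal_min: float = 25.0,
    test: str = "pooled_t",
    log_offset: float = 1.0,
) -> list[InductionCall]:
    """Per-gene induction calls for a treated-vs-control contrast.

    Fold change is the ratio of linear-scale replicate means; the
    differential p-value comes from a two-sample test on
    ``log2(value + log_offset)``.  A gene is induced when all three gates
    pass: ``diff_p <= p_max`` (inclusive), ``treated_mean > signal_min``
    (strict) and ``fold_change > fold_min`` (strict).  Genes whose control
    mean is zero have an undefined fold; they are flagged, never induced,
    and reported with ``fold_change = nan``.
    """
    t_cols = matrix.condition_columns(treated)
    c_cols = matrix.condition_columns(control)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError(
            f"contrast {treated!r} vs {control!r} needs >= 2 replicates per condition"
        )
    tv = matrix.values[t_cols].to_numpy(dtype=float)
    cv = matrix.values[c_cols].to_numpy(dtype=float)
    t_mean = tv.mean(axis=1)
    c_mean = cv.mean(axis=1)
    p = _differential_p(np.log2(tv + log_offset), np.log2(cv + log_offset), test)
    calls: list[InductionCall] = []
    for i, gene in enumerate(matrix.values.index):
        if c_mean[i] == 0:
            logger.warning("gene %s: control mean is zero; fold undefined, excluded", gene)
            calls.append(
                InductionCall(str(gene), float(t_mean[i]), 0.0, float("nan"),
                              float(p[i]), False, flagged=True)
            )
            continue
        fold = t_mean[i] / c_mean[i]
        induced = (p[i] <= p_max) and (t_mean[i] > signal_min) and (fold > fold_min)
        calls.append(
            InductionCall(str(gene), float(t_mean[i]), float(c_mean[i]),
                          float(fold), float(p[i]), bool(induced))
        )
    return calls


def induced_set(calls: list[InductionCall]) -> frozenset:
    return frozenset(c.gene_id for c in calls if c.induced)


def calls_to_frame(calls: list[InductionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene_id,
                "treated_mean": c.treated_mean,
                "control_mean": c.control_mean,
                "fold_change": c.fold_change,
                "diff_p": c.diff_p,
                "induced": c.induced,
                "flagged": c.flagged,
            }
            for c in calls
        ]
    )


def partition_isgs(ifnb, yf, ifng) -> GeneSetPartition:
    """Set algebra defining the U-ISGF3 and ISGF3-only gene groups.

    ``u_isgf3 = ifnb & yf`` (IFN-beta-induced genes also induced by
    Y701F-STAT1); ``isgf3_only = ifnb - u_isgf3 - ifng`` (IFN-beta-induced
    genes neither U-ISGF3-inducible nor IFN-gamma-inducible).  Empty sets
    are legal.
    """
    ifnb, yf, ifng = frozenset(ifnb), frozenset(yf), frozenset(ifng)
    u_isgf3 = ifnb & yf
    isgf3_only = ifnb - u_isgf3 - ifng
    return GeneSetPartition(
        ifnb_induced=ifnb,
        u_isgf3=u_isgf3,
        ifng_induced=ifng,
        isgf3_only=isgf3_only,
    )
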