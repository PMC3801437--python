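"""Small assay quantification formulas: qPCR, ChIP-qPCR, plaque titres.

Relative expression by the delta-delta-Ct method, absolute quantification
by a log10 standard curve, ChIP enrichment as percent of a 2% input
aliquot, and plaque-forming-unit titres from serial dilutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "DdctResult",
    "CurveFit",
    "TitreResult",
    "ddct_fold_change",
    "standard_curve_quantify",
    "chip_percent_input",
    "fold_over_igg",
    "plaque_titre",
    "fold_reduction",
]


@dataclass(frozen=True)
class DdctResult:
    fold: float
    ddct: float
    ddct_sd: float
    fold_low: float   # 2^-(ddct + sd)
    fold_high: float  # 2^-(ddct - sd)


@dataclass(frozen=True)
class CurveFit:
    slope: float       # cycles per log10 quantity; < 0 for a valid series
    intercept: float   # cycles
    r_squared: float
    efficiency: float  # amplification factor - 1; 1.0 means 100%


@dataclass(frozen=True)
class TitreResult:
    pfu_per_ml: float
    detection_limit: float
    below_detection: bool


def _mean_sd(x) -> tuple[float, float]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("Ct values must be finite")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def ddct_fold_change(
    ct_target_treated,
    ct_ref_treated,
    ct_target_control,
    ct_ref_control,
) -> DdctResult:
    """Relative expression by the delta-delta-Ct method (efficiency 2 exact).

    ``ddCt = (Ct_tt - Ct_rt) - (Ct_tc - Ct_rc)`` and ``fold = 2^-ddCt``.
    Replicate inputs are reduced by their mean; the standard deviations of
    the four means propagate in quadrature to an sd on ddCt, reported as a
    fold interval ``2^-(ddCt +/- sd)``.
    """
    means_sds = [_mean_sd(x) for x in
                 (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)]
    (m_tt, s_tt), (m_rt, s_rt), (m_tc, s_tc), (m_rc, s_rc) = means_sds
    ddct = (m_tt - m_rt) - (m_tc - m_rc)
    sd = float(np.sqrt(s_tt**2 + s_rt**2 + s_tc**2 + s_rc**2))
    return DdctResult(
        fold=float(2.0 ** -ddct),
        ddct=float(ddct),
        ddct_sd=sd,
        fold_low=float(2.0 ** -(ddct + sd)),
        fold_high=float(2.0 ** -(ddct - sd)),
    )


def standard_curve_quantify(standards, unknowns) -> tuple[CurveFit, np.ndarray]:
    """Quantify unknown Cts against a dilution-series standard curve.

    ``standards`` is a sequence of ``(log10 quantity, Ct)`` pairs (>= 3,
    spanning >= 2 log10 units).  Fits ``Ct = slope * log10(q) + intercept``
    by least squares; unknowns map back as ``q = 10^((Ct - intercept) /
    slope)``.  Amplification efficiency is ``10^(-1/slope) - 1``.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (log10 quantity, Ct) standards")
    logq, ct = pts[:, 0], pts[:, 1]
    if logq.max() - logq.min() < 2.0:
        raise ValueError("standards must span >= 2 log10 units")
    fit = sps.linregress(logq, ct)
    if fit.slope >= 0:
        raise ValueError("non-negative slope: not a valid dilution series")
    curve = CurveFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(10.0 ** (-1.0 / fit.slope) - 1.0),
    )
    unk = np.atleast_1d(np.asarray(unknowns, dtype=float))
    quantities = 10.0 ** ((unk - curve.intercept) / curve.slope)
    return curve, quantities


def chip_percent_input(q_ip: float, q_input2pct: float, rescale_total: bool = False) -> float:
    """ChIP enrichment as percent of the measured 2% input aliquot.

    By default the ratio is to the 2% aliquot itself (``100 * q_ip /
    q_input2pct``), not rescaled to total chromatin; ``rescale_total``
    divides by 50x the aliquot to express percent of total input.
    """
    if q_input2pct <= 0:
        raise ZeroDivisionError("input quantity must be positive")
    denom = q_input2pct * 50.0 if rescale_total else q_input2pct
    return 100.0 * q_ip / denom


def fold_over_igg(pct_input_antibody: float, pct_input_igg: float) -> float:
    if pct_input_igg <= 0:
        raise ZeroDivisionError("IgG percent input must be positive")
    return pct_input_antibody / pct_input_igg


def plaque_titre(plaque_count: int, dilution: float, inoculum_volume_ml: float) -> TitreResult:
    """Virus titre in PFU/ml from a plaque count at one dilution.

    ``titre = count / (dilution * volume)``; zero plaques report 0 with
    the detection limit ``1 / (dilution * volume)``.
    """
    if not (0.0 < dilution <= 1.0):
        raise ValueError("dilution must be in (0, 1]")
    if inoculum_volume_ml <= 0:
        raise ValueError("inoculum volume must be positive")
    if plaque_count < 0:
        raise ValueError("plaque count must be non-negative")
    denom = dilution * inoculum_volume_ml
    return TitreResult(
        pfu_per_ml=plaque_count / denom,
        detection_limit=1.0 / denom,
        below_detection=plaque_count == 0,
    )


def fold_reduction(titre_control: float, titre_treated: float) -> float:
    if titre_treated <= 0:
        raise ZeroDivisionError("treated titre must be positive")
    return titre_control / titre_treated
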