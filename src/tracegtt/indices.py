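"""Insulin-sensitivity indices.

Tissue-specific indices from tracer kinetics and reconstructed EGP:

- IS-P (peripheral) = k2 / INS(0->120): fractional glucose clearance per
  unit of average insulin exposure, units (1/min)/(ng/mL).
- IS-L (liver) = (mean EGP x mean INS) / (EGP x INS): a dimensionless
  relative index normalised so the cohort-reference animal scores 1;
  high EGP despite high insulin (failed suppression) lowers it.

Whole-body surrogates from the raw OGTT series use the literature-standard
forms (the study that motivated this package cites them without printing
formulas): HOMA-IR = G0 * I0 / 22.5 with glucose in mM and insulin in
uU/mL, and Matsuda = 10000 / sqrt(G0 * I0 * Gmean * Imean) with glucose in
mg/dL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tracegtt.errors import DomainError

#: mM -> mg/dL for glucose (molar mass 180.156 g/mol).
MM_TO_MG_DL = 18.0156

#: ng/mL -> uU/mL for insulin; a documented convention, configurable.
NG_ML_TO_UU_ML = 23.1


@dataclass
class IndexSet:
    """Per-animal sensitivity indices and the IS-L averaging window."""

    is_p: float
    is_l: float
    homa_ir: float
    matsuda: float
    window: tuple[float, float]


def is_peripheral(k2: float, ins_avg_0_120: float) -> float:
    """IS-P = k2 / average insulin over 0-120 min, (1/min)/(ng/mL)."""
    if k2 <= 0 or ins_avg_0_120 <= 0:
        raise DomainError("k2 and average insulin must be positive")
    return k2 / ins_avg_0_120


def is_liver(egp: float, ins: float, egp_ref: float, ins_ref: float) -> float:
    """IS-L = (reference EGP x reference INS) / (EGP x INS).

    The references are arithmetic means over the analysed cohort for the
    same test and averaging window, so the index is dimensionless and the
    cohort centre sits near 1.
    """
    if min(egp, ins, egp_ref, ins_ref) <= 0:
        raise DomainError("all EGP and insulin inputs must be positive")
    return (egp_ref * ins_ref) / (egp * ins)


def homa_ir(fasting_glucose_mm: float, fasting_insulin_uu_ml: float) -> float:
    """HOMA-IR = fasting glucose (mM) x fasting insulin (uU/mL) / 22.5."""
    if fasting_glucose_mm <= 0 or fasting_insulin_uu_ml <= 0:
        raise DomainError("fasting values must be positive")
    return fasting_glucose_mm * fasting_insulin_uu_ml / 22.5


def matsuda(
    glucose_mm: np.ndarray,
    insulin_uu_ml: np.ndarray,
    times: np.ndarray,
) -> float:
    """Matsuda whole-body insulin-sensitivity index from OGTT series.

    10000 / sqrt(G0 * I0 * Gmean * Imean), glucose converted to mg/dL and
    the means taken as trapezoidal time-averages over the sampled window
    (0-120 min in the standard design).
    """
    glucose_mm = np.asarray(glucose_mm, dtype=float)
    insulin_uu_ml = np.asarray(insulin_uu_ml, dtype=float)
    times = np.asarray(times, dtype=float)
    if glucose_mm.shape != times.shape or insulin_uu_ml.shape != times.shape:
        raise DomainError("series must be aligned on the same times")
    if times[0] != 0:
        raise DomainError("t = 0 sample required")
    if np.any(glucose_mm <= 0) or np.any(insulin_uu_ml <= 0):
        raise DomainError("glucose and insulin must be positive")
    g = glucose_mm * MM_TO_MG_DL
    span = times[-1] - times[0]
    g_mean = np.trapezoid(g, times) / span
    i_mean = np.trapezoid(insulin_uu_ml, times) / span
    return float(10000.0 / np.sqrt(g[0] * insulin_uu_ml[0] * g_mean * i_mean))
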