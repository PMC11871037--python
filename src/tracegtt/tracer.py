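"""Two-compartment oral tracer kinetics.

The model has a gastrointestinal compartment (1) and a plasma compartment
(2). Tracer leaves the gut at the apparent absorption rate ka = k1 + kL,
where k1 is the absorbed flux into plasma and kL an unproductive loss;
bioavailability is F = k1 / (k1 + kL). Plasma tracer is cleared at the
fractional rate k2 ("glucose effectiveness"). With a tracer dose D given at
t = 0 and a glucose distribution volume V, the plasma tracer concentration
follows the closed form

    c(t) = A * ka / (ka - k2) * (exp(-k2 t) - exp(-ka t)),   A = F D / V.

Only (ka, k2, A) are identifiable from the tracer curve alone; F is
derived from the fitted amplitude by supplying a distribution volume
(default 0.2 mL per g body weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from tracegtt.errors import DomainError, InsufficientDataError

#: Molar mass of glucose, g/mol — converts mg doses to mmol.
GLUCOSE_MOLAR_MASS = 180.156

#: Default glucose distribution volume per gram body weight, mL/g.
POOL_VOLUME_PER_G = 0.2


def dose_to_concentration(dose_mg: float, pool_volume_ml: float) -> float:
    """Convert a glucose dose in mg to its pool concentration in mM."""
    if pool_volume_ml <= 0:
        raise DomainError("pool volume must be positive")
    return (dose_mg / GLUCOSE_MOLAR_MASS) / (pool_volume_ml / 1000.0)


@dataclass
class TracerCurve:
    """A plasma tracer concentration time course.

    tracer_conc is total glucose concentration times enrichment, in mM.
    """

    times: np.ndarray
    tracer_conc: np.ndarray
    dose_tracer_mg: float
    body_weight_g: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tracer_conc = np.asarray(self.tracer_conc, dtype=float)
        if self.times.shape != self.tracer_conc.shape:
            raise DomainError("times and tracer_conc must be aligned")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if self.times[0] != 0:
            raise DomainError("tracer curve must start at t = 0")
        if np.any(self.tracer_conc < 0):
            raise DomainError("tracer concentrations must be non-negative")


@dataclass
class TracerFit:
    """Fitted tracer kinetics with derived absorption decomposition."""

    ka: float
    k2: float
    amplitude: float
    F: float
    k1: float
    kL: float
    residual_sse: float
    param_se: dict[str, float]
    converged: bool
    warnings: list[str] = field(default_factory=list)


def tracer_model(
    t: np.ndarray | float,
    ka: float,
    k2: float,
    amplitude: float,
) -> np.ndarray | float:
    """Closed-form plasma tracer concentration of the two-compartment model.

    Returns ``amplitude * ka/(ka-k2) * (exp(-k2 t) - exp(-ka t))``; in the
    degenerate limit ka -> k2 the analytic limit
    ``amplitude * ka * t * exp(-ka t)`` is used.
    """
    if ka <= 0 or k2 <= 0:
        raise DomainError("rate constants must be positive")
    t = np.asarray(t, dtype=float)
    if np.isclose(ka, k2, rtol=1e-10, atol=0):
        out = amplitude * ka * t * np.exp(-ka * t)
    else:
        out = amplitude * ka / (ka - k2) * (np.exp(-k2 * t) - np.exp(-ka * t))
    return out if out.ndim else float(out)


def fit_tracer(
    curve: TracerCurve,
    pool_volume_ml: float | None = None,
    init: dict[str, float] | None = None,
    weights: np.ndarray | None = None,
) -> TracerFit:
    """Fit (ka, k2, amplitude) to a tracer curve by Levenberg-Marquardt.

    The fit is parameterised as ka = k2 + delta with delta > 0, which makes
    label switching between the two exponential rates impossible. Residuals
    are unweighted by default. Bioavailability F is derived from the fitted
    amplitude via the supplied distribution volume (default
    0.2 mL/g x body weight); F > 1 indicates a misspecified volume and is
    recorded as a warning, never an exception.
    """
    if np.count_nonzero(curve.times > 0) < 5:
        raise InsufficientDataError("need at least 5 post-zero time points")
    if pool_volume_ml is None:
        pool_volume_ml = POOL_VOLUME_PER_G * curve.body_weight_g

    defaults = {"ka": 0.05, "k2": 0.02, "amplitude": 2.0 * curve.tracer_conc.max()}
    if init:
        defaults.update(init)

    params = lmfit.Parameters()
    params.add("k2", value=defaults["k2"], min=1e-6, max=1.0)
    params.add(
        "delta", value=max(defaults["ka"] - defaults["k2"], 1e-4), min=1e-9, max=1.0
    )
    params.add("ka", expr="k2 + delta", max=2.0)
    params.add("amplitude", value=defaults["amplitude"], min=1e-12)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        pred = tracer_model(curve.times, p["ka"].value, p["k2"].value, p["amplitude"].value)
        res = pred - curve.tracer_conc
        return res * weights if weights is not None else res

    result = lmfit.minimize(residual, params, method="leastsq")

    ka = float(result.params["ka"].value)
    k2 = float(result.params["k2"].value)
    amplitude = float(result.params["amplitude"].value)
    dose_conc = dose_to_concentration(curve.dose_tracer_mg, pool_volume_ml)
    F = amplitude / dose_conc

    fit_warnings: list[str] = []
    if F > 1:
        msg = f"derived bioavailability F = {F:.3f} > 1: pool volume likely misspecified"
        fit_warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    if not result.success:
        fit_warnings.append(f"optimizer did not converge: {result.message}")

    ses = {}
    for name in ("ka", "k2", "amplitude"):
        se = result.params[name].stderr
        ses[name] = float(se) if se is not None else float("nan")

    return TracerFit(
        ka=ka,
        k2=k2,
        amplitude=amplitude,
        F=F,
        k1=F * ka,
        kL=(1.0 - F) * ka,
        residual_sse=float(np.sum(np.asarray(result.residual) ** 2)),
        param_se=ses,
        converged=bool(result.success),
        warnings=fit_warnings,
    )


def decompose_rates(ka: float, F: float) -> tuple[float, float]:
    """Split the apparent absorption rate into absorbed and lost fluxes.

    k1 = F * ka (gut -> plasma) and kL = (1 - F) * ka (gut loss), so that
    ka = k1 + kL and F = k1 / (k1 + kL) hold identically.
    """
    if not 0 < F <= 1:
        raise DomainError("bioavailability F must lie in (0, 1]")
    if ka <= 0:
        raise DomainError("ka must be positive")
    return F * ka, (1.0 - F) * ka


def compose_rates(k1: float, kL: float) -> tuple[float, float]:
    """Inverse of :func:`decompose_rates`: (k1, kL) -> (F, ka)."""
    if k1 <= 0 or kL < 0:
        raise DomainError("k1 must be positive and kL non-negative")
    ka = k1 + kL
    return k1 / ka, ka
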