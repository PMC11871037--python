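"""Synthetic virtual-mouse cohorts with forward-simulated OGTT/MMTT data.

Every downstream stage of the package is validated against this generator:
it draws per-animal kinetic and physiological parameters (the ground
truth), forward-simulates the measurement design of a tracer tolerance
test — blood glucose and raw mass-isotopologue spectra at
0, 5, 10, 20, 30, 45, 60, 90, 120 min, blood-spot insulin at
0, 10, 30, 60, 90, 120 min — and applies multiplicative lognormal
measurement noise. The oral bolus is 1 g glucose per kg body weight of
which 5% w/w is [U-13C6] tracer; tracer and tracee share absorption
kinetics because they travel in the same bolus.

Ground-truth EGP follows a double-exponential suppression dip: after the
bolus EGP falls from its basal value, reaches a minimum (between 10 and
30 min for an OGTT; delayed for a mixed meal) and recovers toward a lower
stationary level as the suppression decays. Any smooth positive shape
would do for testing; this one is the documented default because it
matches the qualitative physiology of insulin-suppressed hepatic output.

Group effects (LF control, HF high-fat, GDM gestational-diabetes exposure)
are multiplicative shifts on the ground-truth parameters, optionally
sex-specific; the defaults emulate the qualitative pattern reported for
GDM offspring (faster absorption ka, blunted insulin response, lower basal
EGP in females).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from tracegtt.errors import ConfigurationError, DomainError, NumericalError, SchemaError
from tracegtt.mid import (
    IsotopologueSpectrum,
    N_GLUCOSE_CARBONS,
    forward_convolve,
    natural_abundance_matrix,
)
from tracegtt.tracer import (
    GLUCOSE_MOLAR_MASS,
    POOL_VOLUME_PER_G,
    dose_to_concentration,
    tracer_model,
)
from tracegtt.insulin import BLOOD_SPOT_FACTOR, insulin_model

GLUCOSE_TIMES = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)
INSULIN_TIMES = (0.0, 10.0, 30.0, 60.0, 90.0, 120.0)

DOSE_MG_PER_G_BW = 1.0      # 1 g glucose per kg body weight
TRACER_FRACTION = 0.05      # 5% w/w of the bolus is tracer

GROUPS = ("LF", "HF", "GDM")
SEXES = ("M", "F")

#: Parameter names group effects may shift (multiplicatively).
SHIFTABLE = frozenset(
    {
        "ka", "F", "k2_true", "egp_basal", "fasting_glucose", "body_weight",
        "ins_C", "ins_ke", "ins_ka", "ins_baseline",
        "egp_suppression_depth", "egp_suppression_tau",
    }
)

#: Default group effects: GDM offspring absorb glucose faster, mount a
#: blunted insulin response, and (females only) run a lower basal EGP.
DEFAULT_GROUP_EFFECTS: dict[str, dict] = {
    "LF": {},
    "HF": {"ka": 1.05},
    "GDM": {"ka": 1.30, "ins_C": 0.70, "egp_basal": {"F": 0.75, "M": 1.0}},
}


@dataclass
class VirtualMouse:
    """Ground-truth kinetic and physiological parameters of one animal.

    Rates are 1/min, concentrations mM (glucose) or ng/mL (insulin),
    weights g. pool_volume (mL) is the glucose distribution volume — pure
    plumbing for amount<->concentration conversion, fixed at 0.2 mL/g BW.
    The fasting steady state egp_basal = k2_true x fasting_glucose holds by
    construction.
    """

    id: str
    dam_id: str
    group: str
    sex: str
    body_weight: float
    k1: float
    kL: float
    k2_true: float
    pool_volume: float
    fasting_glucose: float
    egp_basal: float
    egp_suppression_depth: float
    egp_suppression_tau: tuple[float, float]
    ins_C: float
    ins_ke: float
    ins_ka: float
    ins_baseline: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        for name in ("k1", "k2_true", "pool_volume", "fasting_glucose",
                     "ins_C", "ins_ke", "ins_ka"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.kL < 0:
            raise DomainError("kL cannot be negative")
        if not 0 <= self.egp_suppression_depth <= 1:
            raise DomainError("suppression depth must lie in [0, 1]")
        if self.ins_ka <= self.ins_ke:
            raise DomainError("insulin rise rate must exceed decay rate")
        if not np.isclose(self.egp_basal, self.k2_true * self.fasting_glucose,
                          rtol=1e-9):
            raise DomainError("fasting steady state egp_basal = k2 x G_fast violated")

    @property
    def ka(self) -> float:
        return self.k1 + self.kL

    @property
    def F(self) -> float:
        return self.k1 / (self.k1 + self.kL)

    def egp_true(self, t: np.ndarray | float) -> np.ndarray | float:
        """Ground-truth EGP(t), mM/min: basal x (1 - depth x dip(t))."""
        t = np.asarray(t, dtype=float)
        tau1, tau2 = self.egp_suppression_tau
        tpk = np.log(tau1 / tau2) / (1.0 / tau2 - 1.0 / tau1)
        norm = np.exp(-tpk / tau1) - np.exp(-tpk / tau2)
        dip = (np.exp(-t / tau1) - np.exp(-t / tau2)) / norm
        out = self.egp_basal * (1.0 - self.egp_suppression_depth * dip)
        return out if out.ndim else float(out)


@dataclass
class CohortDesign:
    """Cohort layout, group effects, noise levels and protocol."""

    n_per_group_per_sex: int = 2
    group_effects: dict[str, dict] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_EFFECTS.items()}
    )
    noise_cv_glucose: float = 0.03
    noise_cv_enrichment: float = 0.02
    noise_cv_insulin: float = 0.10
    protocol: str = "OGTT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group_per_sex < 1:
            raise ConfigurationError("need at least one animal per group per sex")
        if min(self.noise_cv_glucose, self.noise_cv_enrichment,
               self.noise_cv_insulin) < 0:
            raise ConfigurationError("noise CVs must be non-negative")
        if self.protocol not in ("OGTT", "MMTT"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        for group, effects in self.group_effects.items():
            if group not in GROUPS:
                raise ConfigurationError(f"group effect for unknown group {group!r}")
            for key, val in effects.items():
                if key not in SHIFTABLE:
                    raise ConfigurationError(
                        f"unknown group-effect parameter {key!r}; "
                        f"valid: {sorted(SHIFTABLE)}"
                    )
                if isinstance(val, dict) and set(val) - set(SEXES):
                    raise ConfigurationError(
                        f"sex-specific shift for {key!r} has invalid keys {sorted(set(val) - set(SEXES))}"
                    )


@dataclass
class MeasurementRecord:
    """Simulated measurements of one tolerance test on one animal."""

    animal_id: str
    glucose_times: np.ndarray
    glucose: np.ndarray                      # total blood glucose, mM
    mid_raw: list[IsotopologueSpectrum]      # one raw spectrum per glucose time
    insulin_times: np.ndarray
    insulin_spot: np.ndarray                 # blood-spot scale, ng/mL
    dose_total_mg: float
    dose_tracer_fraction: float


# baseline (LF male) parameter means; females differ in body weight only,
# biological between-animal scatter is lognormal with the CVs below
_BASE_MEANS = {
    "body_weight": {"M": 27.0, "F": 22.0},   # g, young adult mice
    "ka": 0.05,                               # 1/min
    "F": 0.8,
    "k2_true": 0.02,                          # 1/min
    "fasting_glucose": 9.0,                   # mM after a 6-h fast
    "egp_suppression_depth": 0.6,
    "ins_C": 2.0,                             # ng/mL
    "ins_ke": 0.015,                          # 1/min
    "ins_ka": 0.06,                           # 1/min
    "ins_baseline": 0.4,                      # ng/mL
}
_BASE_CVS = {
    "body_weight": 0.07,
    "ka": 0.12,
    "k2_true": 0.12,
    "fasting_glucose": 0.08,
    "egp_suppression_depth": 0.10,
    "ins_C": 0.15,
    "ins_ke": 0.10,
    "ins_ka": 0.10,
    "ins_baseline": 0.15,
}
# mixed meals empty from the stomach more slowly and suppress EGP later
_MMTT_KA_FACTOR = 0.6
_SUPPRESSION_TAU = {"OGTT": (40.0, 8.0), "MMTT": (120.0, 25.0)}


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


def _shift(effects: dict, key: str, sex: str) -> float:
    val = effects.get(key, 1.0)
    if isinstance(val, dict):
        return float(val.get(sex, 1.0))
    return float(val)


def sample_cohort(design: CohortDesign) -> list[VirtualMouse]:
    """Draw a cohort of virtual mice with group effects applied.

    Each dam contributes one male and one female offspring, so the number
    of dams per group equals n_per_group_per_sex and dam-as-experimental-
    unit statistics are well defined. Fully deterministic given the design
    seed.
    """
    rng = np.random.default_rng([design.seed, 0xC0])
    mice: list[VirtualMouse] = []
    for group in GROUPS:
        effects = design.group_effects.get(group, {})
        for dam_idx in range(design.n_per_group_per_sex):
            dam_id = f"{group}-D{dam_idx + 1:02d}"
            for sex in SEXES:
                params = {}
                for key, cv in _BASE_CVS.items():
                    mean = _BASE_MEANS[key]
                    if isinstance(mean, dict):
                        mean = mean[sex]
                    params[key] = mean * _lognormal_factor(rng, cv)
                for key in params:
                    params[key] *= _shift(effects, key, sex)
                params["egp_suppression_depth"] = min(params["egp_suppression_depth"], 1.0)

                ka = params["ka"]
                if design.protocol == "MMTT":
                    ka *= _MMTT_KA_FACTOR
                F = _BASE_MEANS["F"] * _lognormal_factor(rng, 0.05)
                F = min(F * _shift(effects, "F", sex), 1.0)
                k2 = params["k2_true"]

                # basal EGP follows the fasting steady state unless shifted,
                # in which case fasting glucose moves with it
                egp_basal = k2 * params["fasting_glucose"]
                egp_basal *= _shift(effects, "egp_basal", sex)
                fasting = egp_basal / k2
                tau = tuple(
                    x * _shift(effects, "egp_suppression_tau", sex)
                    for x in _SUPPRESSION_TAU[design.protocol]
                )

                mouse = VirtualMouse(
                    id=f"{group}-{sex}{dam_idx + 1:02d}",
                    dam_id=dam_id,
                    group=group,
                    sex=sex,
                    body_weight=params["body_weight"],
                    k1=F * ka,
                    kL=(1.0 - F) * ka,
                    k2_true=k2,
                    pool_volume=POOL_VOLUME_PER_G * params["body_weight"],
                    fasting_glucose=fasting,
                    egp_basal=egp_basal,
                    egp_suppression_depth=params["egp_suppression_depth"],
                    egp_suppression_tau=tau,
                    ins_C=params["ins_C"],
                    ins_ke=params["ins_ke"],
                    ins_ka=params["ins_ka"],
                    ins_baseline=params["ins_baseline"],
                )
                mice.append(mouse)
    return mice


def _record_rng(design: CohortDesign, mouse_id: str) -> np.random.Generator:
    return np.random.default_rng([design.seed, zlib.crc32(mouse_id.encode())])


def simulate_unlabeled(
    mouse: VirtualMouse, dose_unlabeled_conc: float, times: np.ndarray
) -> np.ndarray:
    """Integrate the unlabelled-glucose balance; returns Q_u(t) in mM."""

    def rhs(t, y):
        absorption = mouse.F * mouse.ka * dose_unlabeled_conc * np.exp(-mouse.ka * t)
        return [absorption + mouse.egp_true(t) - mouse.k2_true * y[0]]

    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), [mouse.fasting_glucose],
        t_eval=times, rtol=1e-10, atol=1e-12, method="LSODA",
    )
    if not sol.success:
        raise NumericalError(
            f"unlabelled-glucose integration failed for {mouse.id}: {sol.message} "
            f"(ka={mouse.ka:.4g}, k2={mouse.k2_true:.4g})"
        )
    return sol.y[0]


def simulate_test(
    mouse: VirtualMouse,
    design: CohortDesign,
    rng: np.random.Generator | None = None,
    na_matrix: np.ndarray | None = None,
) -> MeasurementRecord:
    """Forward-simulate one tolerance test for one virtual mouse.

    Tracer follows the closed-form two-compartment solution; unlabelled
    glucose integrates its mass balance with the ground-truth EGP;
    insulin is the biexponential increment plus fasting baseline. Raw MID
    spectra are the natural-abundance forward convolution of the true
    (m0, m6) mixture. Multiplicative lognormal noise at the design CVs is
    applied per observation. Deterministic given the design seed and
    animal id.
    """
    if rng is None:
        rng = _record_rng(design, mouse.id)
    if na_matrix is None:
        na_matrix = natural_abundance_matrix()

    times = np.asarray(GLUCOSE_TIMES)
    dose_total_mg = DOSE_MG_PER_G_BW * mouse.body_weight
    dose_tracer_mg = TRACER_FRACTION * dose_total_mg
    dose_unlabeled_mg = dose_total_mg - dose_tracer_mg

    tracer_conc = np.asarray(tracer_model(
        times, mouse.ka, mouse.k2_true,
        mouse.F * dose_to_concentration(dose_tracer_mg, mouse.pool_volume),
    ))
    q_unlabeled = simulate_unlabeled(
        mouse, dose_to_concentration(dose_unlabeled_mg, mouse.pool_volume), times
    )

    total_true = tracer_conc + q_unlabeled
    enrichment_true = tracer_conc / total_true

    glucose = total_true * _lognormal_factor(rng, design.noise_cv_glucose, times.size)

    spectra: list[IsotopologueSpectrum] = []
    for e in enrichment_true:
        true_mix = np.zeros(N_GLUCOSE_CARBONS + 1)
        true_mix[0] = 1.0 - e
        true_mix[N_GLUCOSE_CARBONS] = e
        raw = forward_convolve(true_mix, na_matrix).fractions
        raw = raw * _lognormal_factor(rng, design.noise_cv_enrichment, raw.size)
        spectra.append(IsotopologueSpectrum(raw, kind="raw"))

    ins_times = np.asarray(INSULIN_TIMES)
    ins_plasma = mouse.ins_baseline + np.asarray(
        insulin_model(ins_times, mouse.ins_C, mouse.ins_ke, mouse.ins_ka)
    )
    ins_spot = (ins_plasma / BLOOD_SPOT_FACTOR) * _lognormal_factor(
        rng, design.noise_cv_insulin, ins_times.size
    )

    return MeasurementRecord(
        animal_id=mouse.id,
        glucose_times=times,
        glucose=glucose,
        mid_raw=spectra,
        insulin_times=ins_times,
        insulin_spot=ins_spot,
        dose_total_mg=dose_total_mg,
        dose_tracer_fraction=TRACER_FRACTION,
    )


def simulate_cohort(
    design: CohortDesign,
) -> tuple[list[VirtualMouse], list[MeasurementRecord]]:
    """Sample a cohort and simulate one tolerance test per animal."""
    mice = sample_cohort(design)
    na_matrix = natural_abundance_matrix()
    records = [simulate_test(m, design, na_matrix=na_matrix) for m in mice]
    return mice, records


# ---------------------------------------------------------------------------
# dataset I/O: long-format CSV + ground-truth JSON sidecar


def write_dataset(
    records: list[MeasurementRecord],
    mice: list[VirtualMouse],
    path: str | Path,
    protocol: str = "OGTT",
) -> None:
    """Write a cohort to ``measurements.csv`` + ``ground_truth.json``.

    The CSV is long format with columns animal_id, dam_id, group, sex,
    body_weight_g, protocol, time_min, analyte, value where analyte is one
    of glucose, insulin, mid_m0..mid_m6. The sidecar stores every
    ground-truth parameter keyed by animal id.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    by_id = {m.id: m for m in mice}
    if set(r.animal_id for r in records) - set(by_id):
        raise SchemaError("records reference animals missing from the cohort")

    rows = []
    for rec in records:
        m = by_id[rec.animal_id]
        meta = (m.id, m.dam_id, m.group, m.sex, m.body_weight, protocol)
        for t, g, spec in zip(rec.glucose_times, rec.glucose, rec.mid_raw):
            rows.append((*meta, t, "glucose", g))
            for k, frac in enumerate(spec.fractions):
                rows.append((*meta, t, f"mid_m{k}", frac))
        for t, ins in zip(rec.insulin_times, rec.insulin_spot):
            rows.append((*meta, t, "insulin", ins))
    df = pd.DataFrame(
        rows,
        columns=["animal_id", "dam_id", "group", "sex", "body_weight_g",
                 "protocol", "time_min", "analyte", "value"],
    )
    df.to_csv(path / "measurements.csv", index=False, float_format="%.12g")

    truth = {}
    for m in mice:
        d = asdict(m)
        d["egp_suppression_tau"] = list(d["egp_suppression_tau"])
        truth[m.id] = d
    with open(path / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_dataset(path: str | Path) -> tuple[pd.DataFrame, dict | None]:
    """Read a cohort directory back: (long table, ground truth or None)."""
    path = Path(path)
    df = pd.read_csv(path / "measurements.csv")
    required = {"animal_id", "time_min", "analyte", "value"}
    if not required <= set(df.columns):
        raise SchemaError(f"measurements.csv missing columns {sorted(required - set(df.columns))}")
    truth = None
    sidecar = path / "ground_truth.json"
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
    return df, truth
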