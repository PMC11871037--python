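"""Mass-isotopologue natural-abundance correction.

GC-MS measurement of the glucose pentaacetate derivative yields raw ion
intensities m0..mN that mix the tracer signal with naturally occurring heavy
isotopes (13C, 2H, 15N, 17O, 18O) on every atom of the measured ion. The
correction solves the linear model

    raw = M @ corrected

by least squares, where column j of M is the theoretical measured spectrum
of a species carrying exactly j labelled carbons with natural abundance on
all remaining atoms. The same matrix, applied forward, turns a true
isotopologue mixture into the spectrum a mass spectrometer would record —
used by the cohort simulator and as the round-trip oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tracegtt.errors import ConfigurationError, DomainError, NumericalError

#: IUPAC 2021 representative isotopic abundances, as mass-shift polynomials
#: (index = extra mass units relative to the lightest isotope).
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
}

#: Elemental composition of the default measured ion: glucose pentaacetate
#: ammonium adduct [C16H22O11 + NH4]+, monitored under positive chemical
#: ionisation. Six of the carbons are the glucose backbone (labellable).
GLUCOSE_PENTAACETATE_NH4 = {"C": 16, "H": 26, "N": 1, "O": 11}

#: Number of labellable carbon positions for a [U-13C6]glucose tracer.
N_GLUCOSE_CARBONS = 6


@dataclass
class IsotopologueSpectrum:
    """Fractional abundances m0..mN of an analyte's isotopic mass variants.

    Parameters
    ----------
    fractions
        Vector of length N+1 over mass shifts 0..N. Normalised to sum 1
        on construction.
    kind
        ``"raw"`` for as-measured spectra (must be non-negative) or
        ``"corrected"`` for natural-abundance-corrected spectra (small
        negative components may legitimately appear from least squares).
    """

    fractions: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1 or self.fractions.size < 1:
            raise ConfigurationError("fractions must be a non-empty 1-d vector")
        if self.kind not in ("raw", "corrected"):
            raise ConfigurationError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "raw" and np.any(self.fractions < 0):
            raise DomainError("raw spectra cannot have negative intensities")
        total = self.fractions.sum()
        if total <= 0:
            raise DomainError("spectrum must have positive total intensity")
        self.fractions = self.fractions / total

    @property
    def n_mass_shifts(self) -> int:
        return self.fractions.size - 1


def _element_polynomial(element: str, count: int) -> np.ndarray:
    """Mass-shift distribution of `count` atoms of one element."""
    poly = np.array([1.0])
    base = np.asarray(ISOTOPE_ABUNDANCES[element], dtype=float)
    for _ in range(count):
        poly = np.convolve(poly, base)
    return poly


def natural_abundance_matrix(
    formula: dict[str, int] | None = None,
    n_label_positions: int = N_GLUCOSE_CARBONS,
    n_mass_shifts: int = N_GLUCOSE_CARBONS,
    abundances: dict[str, tuple[float, ...]] | None = None,
) -> np.ndarray:
    """Build the natural-abundance convolution matrix for a measured ion.

    Parameters
    ----------
    formula
        Elemental composition of the measured ion, e.g.
        ``{"C": 16, "H": 26, "N": 1, "O": 11}`` (the default glucose
        pentaacetate ammonium adduct).
    n_label_positions
        Number of carbon positions that can carry the 13C label; must not
        exceed the carbon count of the formula.
    n_mass_shifts
        Highest retained mass shift N; the matrix is (N+1) x (N+1) over
        the window m0..mN. The default window m0..m6 contains the fully
        labelled species of a uniformly labelled glucose tracer; a narrower
        m0..m4 window can be selected with ``n_mass_shifts=4``.
    abundances
        Override hook for the isotope abundance table.

    Returns
    -------
    numpy.ndarray
        Square matrix whose column j is the theoretical measured spectrum
        (truncated to the window) of a species with exactly j labelled
        carbons. Columns sum to <= 1; mass shifts beyond the window are
        discarded, not renormalised.
    """
    if formula is None:
        formula = GLUCOSE_PENTAACETATE_NH4
    if any(v < 0 for v in formula.values()):
        raise ConfigurationError("negative atom counts in formula")
    unknown = set(formula) - set(ISOTOPE_ABUNDANCES)
    if unknown:
        raise ConfigurationError(f"no abundance table for elements {sorted(unknown)}")
    n_carbons = formula.get("C", 0)
    if n_label_positions > n_carbons:
        raise ConfigurationError(
            f"{n_label_positions} label positions exceed {n_carbons} carbons"
        )
    if n_mass_shifts < 1:
        raise ConfigurationError("mass window must retain at least m0..m1")

    table = dict(ISOTOPE_ABUNDANCES)
    if abundances:
        table.update(abundances)

    matrix = np.zeros((n_mass_shifts + 1, n_mass_shifts + 1))
    for j in range(min(n_label_positions, n_mass_shifts) + 1):
        # j carbons are fixed 13C (deterministic shift j); natural abundance
        # on every remaining atom of the ion
        poly = np.array([1.0])
        for element, count in formula.items():
            if element == "C":
                count = count - j
            base = np.asarray(table[element], dtype=float)
            for _ in range(count):
                poly = np.convolve(poly, base)
        for shift, p in enumerate(poly):
            if j + shift <= n_mass_shifts:
                matrix[j + shift, j] += p
    # species beyond the labellable range cannot occur; identity placeholder
    # keeps the matrix square and well conditioned
    for j in range(n_label_positions + 1, n_mass_shifts + 1):
        matrix[j, j] = 1.0
    return matrix


def forward_convolve(
    corrected: IsotopologueSpectrum | np.ndarray,
    matrix: np.ndarray,
) -> IsotopologueSpectrum:
    """Predict the measured (raw) spectrum of a true isotopologue mixture.

    The forward model of the correction: ``raw = matrix @ corrected``,
    renormalised to sum 1 over the retained window.
    """
    x = corrected.fractions if isinstance(corrected, IsotopologueSpectrum) else np.asarray(corrected, float)
    if x.size != matrix.shape[1]:
        raise ConfigurationError(
            f"spectrum length {x.size} does not match matrix columns {matrix.shape[1]}"
        )
    raw = matrix @ x
    return IsotopologueSpectrum(raw, kind="raw")


def correct_mid(
    raw: IsotopologueSpectrum | np.ndarray,
    matrix: np.ndarray,
    nonnegative: bool = False,
    max_condition: float = 1e8,
) -> IsotopologueSpectrum:
    """Correct a raw spectrum for natural isotope abundance.

    Solves ``matrix @ x ~= raw`` in the least-squares sense (the multiple
    linear regression of classic MID correction) and renormalises the
    solution to sum 1. Negative components are retained by default so that
    ill-conditioning and noise are visible to the user; pass
    ``nonnegative=True`` for a non-negative least-squares solve.
    """
    y = raw.fractions if isinstance(raw, IsotopologueSpectrum) else np.asarray(raw, float)
    y = y / y.sum()
    if y.size != matrix.shape[0]:
        raise ConfigurationError(
            f"spectrum length {y.size} does not match matrix rows {matrix.shape[0]}"
        )
    cond = np.linalg.cond(matrix)
    if not np.isfinite(cond) or cond > max_condition:
        raise NumericalError(
            f"correction matrix ill-conditioned (condition number {cond:.3g})"
        )
    if nonnegative:
        from scipy.optimize import nnls

        x, _ = nnls(matrix, y)
    else:
        x, *_ = np.linalg.lstsq(matrix, y, rcond=None)
    return IsotopologueSpectrum(x, kind="corrected")


def enrichment_from_mid(
    corrected: IsotopologueSpectrum,
    labelled_shift: int = N_GLUCOSE_CARBONS,
    use_one_minus_m0: bool = False,
) -> float:
    """Tracer enrichment from a corrected spectrum.

    Default: the fraction of the fully labelled species (m6 for a
    [U-13C6]glucose tracer). ``use_one_minus_m0=True`` instead reports
    1 - m0, the total labelled fraction.
    """
    if corrected.kind != "corrected":
        raise ConfigurationError("enrichment requires a corrected spectrum")
    if use_one_minus_m0:
        return float(1.0 - corrected.fractions[0])
    if corrected.n_mass_shifts < labelled_shift:
        raise ConfigurationError(
            f"mass window m0..m{corrected.n_mass_shifts} does not contain the "
            f"fully labelled species m{labelled_shift}"
        )
    return float(corrected.fractions[labelled_shift])


def unlabeled_fraction(corrected: IsotopologueSpectrum) -> float:
    """m0 fraction of a corrected spectrum (the unlabelled species)."""
    if corrected.kind != "corrected":
        raise ConfigurationError("requires a corrected spectrum")
    return float(corrected.fractions[0])
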