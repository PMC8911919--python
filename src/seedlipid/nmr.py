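"""Quantitative ¹H NMR of seed lipids.

The area under each signal of a triacylglycerol ¹H spectrum is proportional
to the number of contributing protons, so ratios of signal integrals give
the molar proportions of the acyl classes directly.  This module integrates
assigned chemical-shift windows, converts the integrals into the four
fatty-acid percentages

    linolenic (18:3) = 100 · E / (F + E)
    linoleic  (18:2) = 100 · [A/B − 2·E/(F + E)]
    oleic     (18:1) = 100 · [C/(2B) − A/B + E/(F + E)]
    saturated        = 100 · [1 − C/(2B)]

(A bis-allylic CH₂, B α-CH₂ to the carbonyl, C allylic CH₂, E ω-3 terminal
CH₃, F terminal CH₃ of all other chains), and quantifies total lipid
against an external oil reference spectrum by comparing mass-normalised
total integrals.  The four percentages sum to 100 identically for any
positive integrals — a useful internal consistency check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateInputError,
    InconsistentIntegralsError,
    RangeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Signal labels in upfield→downfield order of their default windows.
SIGNAL_LABELS = (
    "F", "E", "G", "D", "C", "B", "A", "alpha1", "alpha2", "beta", "H",
)

#: Default assignment windows (ppm).  Centers follow the standard
#: vegetable-oil assignments (terminal CH₃ 0.88/0.97, (CH₂)ₙ 1.30,
#: β-CH₂ 1.61, allylic 2.02, α-CH₂ 2.30, bis-allylic 2.77, glycerol
#: 4.14/4.30/5.23, olefinic 5.35); the olefinic/glycerol-β boundary sits
#: at 5.26 ppm because the two signals overlap slightly.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "F": (0.80, 0.925),
    "E": (0.925, 1.06),
    "G": (1.12, 1.48),
    "D": (1.50, 1.74),
    "C": (1.90, 2.14),
    "B": (2.18, 2.42),
    "A": (2.65, 2.89),
    "alpha1": (4.05, 4.22),
    "alpha2": (4.22, 4.39),
    "beta": (5.12, 5.26),
    "H": (5.26, 5.52),
}


@dataclass(frozen=True)
class NMRSpectrum:
    """A 1-D ¹H spectrum: chemical-shift axis (ppm) and intensity trace.

    The ppm axis is stored strictly decreasing (display convention) but any
    strictly monotonic axis is accepted and reordered.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    sample_mass: float = float("nan")  # mg

    def __post_init__(self):
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or ppm.shape != intensity.shape or ppm.size < 2:
            raise ValidationError("ppm and intensity must be equal-length 1-D arrays of size >= 2")
        diffs = np.diff(ppm)
        if np.all(diffs > 0):  # ascending → flip to display convention
            ppm, intensity = ppm[::-1], intensity[::-1]
        elif not np.all(diffs < 0):
            raise ValidationError("ppm axis must be strictly monotonic")
        if not np.all(np.isfinite(intensity)):
            raise ValidationError("intensities must be finite")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)


@dataclass(frozen=True)
class SignalAssignment:
    label: str
    window: tuple[float, float]
    description: str = ""

    def __post_init__(self):
        low, high = self.window
        if not low < high:
            raise ValidationError(f"assignment {self.label!r}: window low must be < high")


def default_assignments() -> list[SignalAssignment]:
    """The eleven default windows as a validated assignment set."""
    return [SignalAssignment(lbl, DEFAULT_WINDOWS[lbl]) for lbl in SIGNAL_LABELS]


def _validate_assignment_set(assignments: list[SignalAssignment]) -> None:
    labels = [a.label for a in assignments]
    if len(set(labels)) != len(labels):
        raise ValidationError("assignment labels must be unique")
    ordered = sorted(assignments, key=lambda a: a.window[0])
    for left, right in zip(ordered, ordered[1:]):
        if right.window[0] < left.window[1]:
            raise ValidationError(
                f"windows {left.label!r} and {right.label!r} overlap"
            )


@dataclass(frozen=True)
class IntegralTable:
    """Signal areas keyed by label; ``normalized`` means they sum to 100."""

    areas: dict[str, float]
    normalized: bool = False

    def __post_init__(self):
        for label, area in self.areas.items():
            if area < 0:
                raise ValidationError(f"negative area for signal {label!r}")
        if self.normalized:
            total = sum(self.areas.values())
            if abs(total - 100.0) > 1e-9:
                raise ValidationError(f"normalized table sums to {total}, not 100")

    def total(self) -> float:
        return float(sum(self.areas.values()))


@dataclass(frozen=True)
class AcylComposition:
    """Percentages of total acyl chains by class; sums to 100."""

    linolenic_pct: float
    linoleic_pct: float
    oleic_pct: float
    saturated_pct: float

    def __post_init__(self):
        vals = self.as_tuple()
        if abs(sum(vals) - 100.0) > 1e-9:
            raise ValidationError("composition must sum to 100")
        if any(v < 0 or v > 100 for v in vals):
            raise ValidationError("composition values must lie in [0, 100]")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.linolenic_pct, self.linoleic_pct, self.oleic_pct, self.saturated_pct)


@dataclass(frozen=True)
class LipidQuantResult:
    sample_id: str
    total_lipid_pct: float  # % dry mass
    reference_id: str

    def __post_init__(self):
        if self.total_lipid_pct < 0:
            raise ValidationError("total lipid percentage cannot be negative")


def integrate_region(
    spectrum: NMRSpectrum,
    window: tuple[float, float],
    baseline: str = "endpoint-linear",
) -> float:
    """Trapezoidal area of the spectrum over a ppm window.

    ``baseline='endpoint-linear'`` subtracts the straight line joining the
    intensities interpolated at the two window edges before integrating;
    ``'none'`` integrates the raw trace.  A negative net area (possible with
    noise after baseline subtraction) is floored at zero with a warning.
    """
    low, high = float(window[0]), float(window[1])
    if not low < high:
        raise ValidationError("window low must be < high")
    if baseline not in ("none", "endpoint-linear"):
        raise ValidationError(f"unknown baseline mode {baseline!r}")
    x = spectrum.ppm[::-1]  # ascending for interpolation
    y = spectrum.intensity[::-1]
    if high < x[0] or low > x[-1]:
        raise RangeError(
            f"window [{low}, {high}] ppm outside spectral range [{x[0]}, {x[-1]}]"
        )
    lo = max(low, float(x[0]))
    hi = min(high, float(x[-1]))
    inside = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, x, y)], y[inside], [np.interp(hi, x, y)]))
    if baseline == "endpoint-linear":
        ys = ys - np.interp(xs, [xs[0], xs[-1]], [ys[0], ys[-1]])
    area = float(np.trapezoid(ys, xs))
    if area < 0:
        logger.warning(
            "negative area %.4g in window [%.3f, %.3f] ppm floored at 0 (sample %s)",
            area, low, high, spectrum.sample_id,
        )
        area = 0.0
    return area


def assign_and_integrate(
    spectrum: NMRSpectrum,
    assignments: list[SignalAssignment] | None = None,
    baseline: str = "endpoint-linear",
) -> IntegralTable:
    """Integrate every assigned window, returning an unnormalized table."""
    if assignments is None:
        assignments = default_assignments()
    _validate_assignment_set(assignments)
    areas: dict[str, float] = {}
    for a in assignments:
        try:
            areas[a.label] = integrate_region(spectrum, a.window, baseline=baseline)
        except (RangeError, ValidationError) as exc:
            raise type(exc)(f"signal {a.label!r}: {exc}") from exc
    return IntegralTable(areas=areas, normalized=False)


def normalize_integrals(table: IntegralTable) -> IntegralTable:
    """Rescale areas so they sum to 100 (idempotent)."""
    total = table.total()
    if total <= 0:
        raise DegenerateInputError("cannot normalize an all-zero integral table")
    scale = 100.0 / total
    return IntegralTable(
        areas={k: v * scale for k, v in table.areas.items()},
        normalized=True,
    )


def acyl_composition(table: IntegralTable, tol: float = 2.0) -> AcylComposition:
    """Fatty-acid class percentages from the integral ratios.

    Scale-invariant: normalized and raw tables give identical results.  Raw
    percentages slightly outside [0, 100] (within ``tol`` points, as happens
    with noisy integrals) are clipped and the four classes renormalized;
    larger violations indicate inconsistent integrals and raise.
    """
    try:
        A, B, C, E, F = (table.areas[k] for k in ("A", "B", "C", "E", "F"))
    except KeyError as exc:
        raise ValidationError(f"integral table missing signal {exc.args[0]!r}") from exc
    if B <= 0:
        raise DegenerateInputError("signal B area must be positive")
    if E + F <= 0:
        raise DegenerateInputError("E + F must be positive")

    omega3 = E / (F + E)
    raw = np.array([
        100.0 * omega3,
        100.0 * (A / B - 2.0 * omega3),
        100.0 * (C / (2.0 * B) - A / B + omega3),
        100.0 * (1.0 - C / (2.0 * B)),
    ])
    if np.any(raw < -tol) or np.any(raw > 100.0 + tol):
        raise InconsistentIntegralsError(
            f"integral ratios imply composition {np.round(raw, 2).tolist()} "
            f"outside [0, 100] by more than {tol} points"
        )
    if np.any(raw < 0) or np.any(raw > 100):
        logger.warning(
            "composition %s clipped into [0, 100] and renormalized",
            np.round(raw, 3).tolist(),
        )
        raw = np.clip(raw, 0.0, 100.0)
        raw = raw * (100.0 / raw.sum())
    return AcylComposition(*[float(v) for v in raw])


def total_lipid(
    sample_table: IntegralTable,
    sample_mass: float,
    reference_table: IntegralTable,
    reference_mass: float,
    sample_id: str = "",
    reference_id: str = "reference-oil",
    lipid_labels: tuple[str, ...] | None = None,
) -> LipidQuantResult:
    """Total lipid (% dry mass) relative to an external oil reference.

    Both integral tables must be unnormalized (raw areas).  Each total area
    is divided by the weighed mass (mg); the sample/reference ratio of these
    mass-normalised totals, times 100, is the lipid mass fraction, because
    the reference is pure oil.  ``lipid_labels`` restricts the sum to a
    subset of windows (default: every assigned window).
    """
    if sample_table.normalized or reference_table.normalized:
        raise ValidationError("total_lipid requires unnormalized integral tables")
    if sample_mass <= 0 or reference_mass <= 0:
        raise ValidationError("sample and reference masses must be positive")
    if lipid_labels is None:
        sample_sum = sample_table.total()
        ref_sum = reference_table.total()
    else:
        missing = [k for k in lipid_labels if k not in sample_table.areas or k not in reference_table.areas]
        if missing:
            raise ValidationError(f"lipid labels missing from tables: {missing}")
        sample_sum = sum(sample_table.areas[k] for k in lipid_labels)
        ref_sum = sum(reference_table.areas[k] for k in lipid_labels)
    if ref_sum <= 0:
        raise DegenerateInputError("reference integral sum must be positive")
    pct = 100.0 * (sample_sum / sample_mass) / (ref_sum / reference_mass)
    return LipidQuantResult(sample_id=sample_id, total_lipid_pct=pct, reference_id=reference_id)


def assignments_from_mapping(windows: dict[str, tuple[float, float]]) -> list[SignalAssignment]:
    """Build a validated assignment list from a label→(low, high) mapping."""
    assignments = [SignalAssignment(lbl, (float(lo), float(hi))) for lbl, (lo, hi) in windows.items()]
    _validate_assignment_set(assignments)
    return assignments
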