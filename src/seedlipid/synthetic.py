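"""Synthetic NMR and NIR spectra with known ground truth.

Every downstream stage (integration, acyl-composition equations, total
lipid, pretreatments, PLS cross-validation) is tested against data whose
true composition and lipid content are known by construction.

The NMR forward model places one peak per assigned signal and sets the
amplitudes so that the integrated area in each assignment window equals

    lipid_mass_fraction/100 × sample_mass × Σ_type (fraction × protons)

where the proton counts per acyl type follow the standard triacylglycerol
assignments (bis-allylic A, α-carbonyl B, allylic C, ω-3 terminal methyl E,
other terminal methyls F, olefinic H, glycerol backbone α/β).  Because
Lorentzian lines have heavy tails that leak a few percent of their area
into adjacent windows at any realistic linewidth, the generator solves a
small linear system built from the analytic truncated-peak areas so each
window's *net* area matches its target exactly (up to trapezoid
discretization of the digital grid).

The NIR forward model is a Beer–Lambert mixture: absorbance is linear in
lipid mass fraction through a set of C–H overtone/combination bands riding
on a fixed water/starch background, then corrupted by per-sample
multiplicative scatter, a low-order polynomial additive baseline, and white
noise — the three artefacts that SNV/detrend/MSC pretreatments exist to
remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .errors import ValidationError
from .nmr import DEFAULT_WINDOWS, SIGNAL_LABELS, NMRSpectrum
from .nir import NIRSpectrum

ACYL_TYPES = ("linolenic", "linoleic", "oleic", "saturated")

#: Default peak centers (ppm) for the eleven signals, from the standard
#: vegetable-oil assignment literature.
DEFAULT_CENTERS: dict[str, float] = {
    "F": 0.88, "E": 0.97, "G": 1.30, "D": 1.61, "C": 2.02, "B": 2.30,
    "A": 2.77, "alpha1": 4.14, "alpha2": 4.30, "beta": 5.23, "H": 5.35,
}


def proton_count_table() -> dict[str, dict[str, float]]:
    """Protons contributed to each signal per acyl chain, by acyl type.

    A: bis-allylic CH₂ (4 H for 18:3, 2 H for 18:2, none otherwise);
    B: α-CH₂ to the carbonyl (2 H every chain); C: allylic CH₂ (4 H for any
    unsaturated chain); D: β-CH₂ (2 H every chain); E: terminal CH₃ of ω-3
    chains (3 H, linolenic only); F: terminal CH₃ of all other chains (3 H);
    G: mid-chain (CH₂)ₙ envelope (type-specific); H: olefinic CH (2 H per
    double bond).  The glycerol backbone contributes 4 α H (split 2+2 over
    the α1/α2 multiplets) and 1 β H per triacylglycerol, i.e. per three
    chains, so the per-chain counts are 2/3, 2/3 and 1/3.
    """
    g = {"linolenic": 10.0, "linoleic": 14.0, "oleic": 20.0, "saturated": 24.0}
    table: dict[str, dict[str, float]] = {}
    for label in SIGNAL_LABELS:
        table[label] = {}
        for t in ACYL_TYPES:
            unsat = t in ("linolenic", "linoleic", "oleic")
            n_db = {"linolenic": 3, "linoleic": 2, "oleic": 1, "saturated": 0}[t]
            count = {
                "A": {"linolenic": 4.0, "linoleic": 2.0}.get(t, 0.0),
                "B": 2.0,
                "C": 4.0 if unsat else 0.0,
                "D": 2.0,
                "E": 3.0 if t == "linolenic" else 0.0,
                "F": 0.0 if t == "linolenic" else 3.0,
                "G": g[t],
                "H": 2.0 * n_db,
                "alpha1": 2.0 / 3.0,
                "alpha2": 2.0 / 3.0,
                "beta": 1.0 / 3.0,
            }[label]
            table[label][t] = count
    return table


@dataclass(frozen=True)
class AcylMixture:
    """Molar fractions of acyl chains by class; must sum to one."""

    frac_linolenic: float
    frac_linoleic: float
    frac_oleic: float
    frac_saturated: float

    def __post_init__(self):
        fr = self.as_tuple()
        if any(f < 0 or f > 1 for f in fr):
            raise ValidationError("acyl fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise ValidationError(f"acyl fractions sum to {sum(fr)}, not 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.frac_linolenic, self.frac_linoleic, self.frac_oleic, self.frac_saturated)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ACYL_TYPES, self.as_tuple()))


@dataclass(frozen=True)
class PeakModel:
    """One spectral line: center (ppm), height, half-width at half-maximum."""

    center: float
    height: float
    width: float
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.width <= 0:
            raise ValidationError("peak width must be positive")
        if self.height < 0:
            raise ValidationError("peak height must be non-negative")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValidationError(f"unknown peak shape {self.shape!r}")

    def profile(self, x: np.ndarray) -> np.ndarray:
        u = (np.asarray(x, dtype=float) - self.center) / self.width
        if self.shape == "lorentzian":
            return self.height / (1.0 + u * u)
        return self.height * np.exp(-np.log(2.0) * u * u)


def _unit_peak_window_area(center, width, shape, low, high) -> float:
    """Analytic area of a unit-height peak over [low, high]."""
    if shape == "lorentzian":
        return width * (np.arctan((high - center) / width)
                        - np.arctan((low - center) / width))
    sigma = width / np.sqrt(2.0 * np.log(2.0))
    return sigma * np.sqrt(np.pi / 2.0) * (
        erf((high - center) / (sigma * np.sqrt(2.0)))
        - erf((low - center) / (sigma * np.sqrt(2.0)))
    )


def target_window_areas(
    mixture: AcylMixture,
    lipid_mass_fraction: float,
    sample_mass: float,
    scale: float = 1.0,
) -> dict[str, float]:
    """Ground-truth area per assignment window under the proton-count model."""
    fr = mixture.as_dict()
    counts = proton_count_table()
    amp = scale * (lipid_mass_fraction / 100.0) * sample_mass
    return {
        label: amp * sum(fr[t] * counts[label][t] for t in ACYL_TYPES)
        for label in SIGNAL_LABELS
    }


def simulate_nmr(
    mixture: AcylMixture,
    lipid_mass_fraction: float = 100.0,
    sample_mass: float = 7.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    ppm_range: tuple[float, float] = (0.0, 6.0),
    n_points: int = 8192,
    hwhm: float = 0.01,
    shape: str = "lorentzian",
    windows: dict[str, tuple[float, float]] | None = None,
    centers: dict[str, float] | None = None,
    scale: float = 1.0,
    sample_id: str = "synthetic",
) -> NMRSpectrum:
    """Simulate a ¹H spectrum of a triacylglycerol mixture.

    Peak amplitudes are chosen (via an 11×11 linear solve over the analytic
    truncated-peak areas) so that the integrated area of each assignment
    window equals the proton-count forward model exactly, up to the
    trapezoid discretization of the ``n_points`` grid.  Gaussian noise of
    standard deviation ``noise_sd`` is then added; the same seed reproduces
    the spectrum bit for bit.
    """
    if not 0.0 <= lipid_mass_fraction <= 100.0:
        raise ValidationError("lipid_mass_fraction must lie in [0, 100]")
    if sample_mass <= 0:
        raise ValidationError("sample_mass must be positive")
    if n_points < 16:
        raise ValidationError("n_points too small")
    windows = dict(windows or DEFAULT_WINDOWS)
    centers = dict(centers or DEFAULT_CENTERS)
    labels = list(windows)
    targets = target_window_areas(mixture, lipid_mass_fraction, sample_mass, scale)
    t = np.array([targets.get(lbl, 0.0) for lbl in labels])

    # M[i, j]: area a unit-height peak j deposits inside window i.
    M = np.array([
        [_unit_peak_window_area(centers[pj], hwhm, shape, *windows[wi])
         for pj in labels]
        for wi in labels
    ])
    heights = np.linalg.solve(M, t)

    lo, hi = min(ppm_range), max(ppm_range)
    ppm = np.linspace(hi, lo, n_points)  # decreasing, display convention
    intensity = np.zeros(n_points)
    for h, lbl in zip(heights, labels):
        if h != 0.0:
            intensity += PeakModel(centers[lbl], abs(h), hwhm, shape).profile(ppm) * np.sign(h)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        intensity = intensity + rng.normal(0.0, noise_sd, n_points)
    return NMRSpectrum(ppm=ppm, intensity=intensity,
                       sample_id=sample_id, sample_mass=sample_mass)


# ---------------------------------------------------------------------------
# NIR simulation

#: Lipid C–H overtone/combination bands: (center nm, sigma nm, absorbance
#: per % lipid at band maximum).
LIPID_BANDS = (
    (1210.0, 18.0, 0.008),
    (1725.0, 14.0, 0.016),
    (1765.0, 14.0, 0.012),
    (2307.0, 12.0, 0.020),
    (2347.0, 12.0, 0.018),
)

#: Non-lipid matrix bands (water, starch, protein) plus a broad background:
#: (center nm, sigma nm, absorbance).
MATRIX_BANDS = (
    (1450.0, 45.0, 0.25),
    (1940.0, 55.0, 0.45),
    (2100.0, 40.0, 0.30),
    (2180.0, 30.0, 0.15),
    (1600.0, 600.0, 0.10),
)

#: Constant absorbance offset keeping corrupted spectra physically positive.
BASE_OFFSET = 0.30


@dataclass(frozen=True)
class NIRSimConfig:
    """Configuration of the NIR reflectance simulator.

    Defaults mirror a small whole-seed calibration set: 18 samples spanning
    1.3–2.6 % lipid (dry mass), 350–2500 nm at 1 nm, 5 % multiplicative
    scatter, a random quadratic additive baseline and 0.5 mAU white noise.
    """

    n_samples: int = 18
    lipid_range: tuple[float, float] = (1.3, 2.6)
    band_centers: tuple[float, ...] = tuple(b[0] for b in LIPID_BANDS)
    band_widths: tuple[float, ...] = tuple(b[1] for b in LIPID_BANDS)
    band_amplitudes: tuple[float, ...] = tuple(b[2] for b in LIPID_BANDS)
    scatter_mult_sd: float = 0.05
    baseline_coeffs_sd: float = 0.01
    baseline_degree: int = 2
    noise_sd: float = 5e-4
    seed: int = 0
    wavelength_range: tuple[float, float] = (350.0, 2500.0)
    wavelength_step: float = 1.0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        lo, hi = self.lipid_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ValidationError("lipid_range must lie within [0, 100]")
        if any(w <= 0 for w in self.band_widths):
            raise ValidationError("band widths must be positive")
        if len(self.band_centers) != len(self.band_widths) or len(
            self.band_centers
        ) != len(self.band_amplitudes):
            raise ValidationError("band centers/widths/amplitudes must align")
        if self.baseline_degree < 0:
            raise ValidationError("baseline_degree must be >= 0")


def _gaussian_bands(wl: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(wl)
    for c, s, a in bands:
        out += a * np.exp(-0.5 * ((wl - c) / s) ** 2)
    return out


def simulate_nir(
    config: NIRSimConfig,
    lipid_values: np.ndarray | None = None,
) -> tuple[list[NIRSpectrum], np.ndarray]:
    """Simulate a reflectance dataset with known lipid ground truth.

    True absorbance is ``lipid% × lipid-band profile + matrix background``;
    each sample's absorbance is then multiplied by ``1 + N(0,
    scatter_mult_sd)``, shifted by a random polynomial baseline of degree
    ``baseline_degree`` (coefficients ~ N(0, baseline_coeffs_sd) on a
    [-1, 1]-scaled wavelength axis), perturbed by white noise, and converted
    to reflectance ``R = 10^(-A)``.  ``lipid_values`` overrides the uniform
    draw from ``lipid_range`` (useful for designed test sets).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_lipid, rng_scatter, rng_base, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    wl = np.arange(config.wavelength_range[0],
                   config.wavelength_range[1] + config.wavelength_step / 2,
                   config.wavelength_step)
    if lipid_values is None:
        lo, hi = config.lipid_range
        y = np.sort(rng_lipid.uniform(lo, hi, config.n_samples))
    else:
        y = np.asarray(lipid_values, dtype=float)
        if y.size != config.n_samples:
            raise ValidationError("lipid_values length must equal n_samples")

    lipid_profile = _gaussian_bands(
        wl, zip(config.band_centers, config.band_widths, config.band_amplitudes)
    )
    background = BASE_OFFSET + _gaussian_bands(wl, MATRIX_BANDS)
    u = 2.0 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1.0

    spectra: list[NIRSpectrum] = []
    for i in range(config.n_samples):
        A = y[i] * lipid_profile + background
        mult = 1.0 + rng_scatter.normal(0.0, config.scatter_mult_sd) \
            if config.scatter_mult_sd > 0 else 1.0
        coeffs = (
            rng_base.normal(0.0, config.baseline_coeffs_sd, config.baseline_degree + 1)
            if config.baseline_coeffs_sd > 0
            else np.zeros(config.baseline_degree + 1)
        )
        A = mult * A + np.polynomial.polynomial.polyval(u, coeffs)
        if config.noise_sd > 0:
            A = A + rng_noise.normal(0.0, config.noise_sd, wl.size)
        A = np.maximum(A, 1e-6)  # keep reflectance in (0, 1]
        spectra.append(NIRSpectrum(
            wavelength=wl, signal=10.0 ** (-A),
            mode="reflectance", sample_id=f"sim{i:02d}",
        ))
    return spectra, y
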