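"""File formats, run configuration and the two end-to-end pipelines.

Canonical on-disk formats are plain CSV: spectra as two-column files
(``ppm,intensity`` for NMR; ``wavelength_nm,reflectance`` or
``wavelength_nm,absorbance`` for NIR), NIR datasets as a wide matrix CSV
(first column ``sample_id``, remaining columns wavelengths in nm) with a
companion ``sample_id,lipid_pct`` reference file, and assignment windows as
TOML.  Reports round half-up at this layer only; all upstream math is full
precision.
"""

from __future__ import annotations

import csv
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, nir, nmr
from .calibration import round_half_up
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


def read_spectrum_csv(path, kind: str):
    """Read a two-column spectrum CSV as an NMRSpectrum or NIRSpectrum.

    The axis is sorted to each kind's canonical order; duplicate abscissae
    are rejected, and malformed rows are reported with their line number.
    """
    if kind not in ("nmr", "nir"):
        raise ValidationError(f"kind must be 'nmr' or 'nir', got {kind!r}")
    path = Path(path)
    xs, ys = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) != 2:
            raise ParseError(f"{path}: expected two columns, got {len(header)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ParseError(f"{path}: expected two fields", line=lineno)
            try:
                xs.append(float(row[0]))
                ys.append(float(row[1]))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {row!r}", line=lineno
                ) from None
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.size < 2:
        raise ParseError(f"{path}: need at least two data rows")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(np.diff(x) == 0):
        raise ValidationError(f"{path}: duplicate abscissa values")
    if kind == "nmr":
        return nmr.NMRSpectrum(ppm=x[::-1], intensity=y[::-1], sample_id=path.stem)
    mode = "absorbance" if header[1].strip().lower() == "absorbance" else "reflectance"
    return nir.NIRSpectrum(wavelength=x, signal=y, mode=mode, sample_id=path.stem)


def write_spectrum_csv(path, spectrum) -> None:
    """Write a spectrum as two-column CSV (inverse of read_spectrum_csv)."""
    path = Path(path)
    if isinstance(spectrum, nmr.NMRSpectrum):
        header, x, y = ("ppm", "intensity"), spectrum.ppm, spectrum.intensity
    else:
        header = ("wavelength_nm", spectrum.mode)
        x, y = spectrum.wavelength, spectrum.signal
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(zip((format(v, ".17g") for v in x),
                        (format(v, ".17g") for v in y)))


def read_assignments_toml(path=None) -> list[nmr.SignalAssignment]:
    """Assignment windows from TOML (``[windows]`` table of label = [low, high])."""
    if path is None:
        return nmr.default_assignments()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "windows" not in data:
        raise ValidationError(f"{path}: missing [windows] table")
    return nmr.assignments_from_mapping(
        {k: (v[0], v[1]) for k, v in data["windows"].items()}
    )


def read_nir_matrix_csv(matrix_path, reference_path) -> nir.SpectraMatrix:
    """Wide spectra CSV + ``sample_id,lipid_pct`` reference CSV → SpectraMatrix.

    Signals are taken as reflectance and converted to absorbance unless the
    matrix file name contains ``absorbance``.
    """
    df = pd.read_csv(matrix_path)
    if df.columns[0] != "sample_id":
        raise ValidationError(f"{matrix_path}: first column must be 'sample_id'")
    try:
        wl = np.asarray([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: non-numeric wavelength column: {exc}") from None
    ref = pd.read_csv(reference_path).set_index("sample_id")["lipid_pct"]
    ids = df["sample_id"].astype(str)
    missing = [s for s in ids if s not in ref.index.astype(str)]
    if missing:
        raise ValidationError(f"reference file missing samples: {missing}")
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    if "absorbance" not in Path(matrix_path).stem:
        if np.any(X <= 0):
            raise ValidationError(f"{matrix_path}: non-positive reflectance")
        X = np.log10(1.0 / X)
    y = ref.loc[ids].to_numpy(dtype=float)
    return nir.SpectraMatrix(X=X, wavelength=wl, reference_y=y,
                             sample_ids=tuple(ids))


@dataclass
class RunConfig:
    """Validated knobs for both pipelines."""

    assignments: list = field(default_factory=nmr.default_assignments)
    baseline: str = "endpoint-linear"
    lipid_window_labels: tuple[str, ...] | None = None
    pretreatment_recipes: tuple[tuple[str, ...], ...] = (
        (), ("snv", "detrend", "deriv1"), ("snv", "detrend", "deriv1", "msc"),
    )
    n_factors: int = 4
    detrend_order: int = 2
    derivative_gap: int = 4
    derivative_segment: int = 4
    nir_range: tuple[float, float] = (1100.0, 2500.0)
    seed: int = 0
    decimals: int = 2

    def __post_init__(self):
        if self.baseline not in ("none", "endpoint-linear"):
            raise ValidationError(f"unknown baseline mode {self.baseline!r}")
        if self.n_factors < 1:
            raise ValidationError("n_factors must be >= 1")
        if self.decimals < 0:
            raise ValidationError("decimals must be >= 0")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        kwargs = {}
        if "windows" in data:
            kwargs["assignments"] = nmr.assignments_from_mapping(
                {k: (v[0], v[1]) for k, v in data["windows"].items()}
            )
        for key in ("baseline", "n_factors", "detrend_order", "derivative_gap",
                    "derivative_segment", "seed", "decimals"):
            if key in data:
                kwargs[key] = data[key]
        if "nir_range" in data:
            kwargs["nir_range"] = tuple(data["nir_range"])
        if "pretreatment_recipes" in data:
            kwargs["pretreatment_recipes"] = tuple(
                tuple(r) for r in data["pretreatment_recipes"]
            )
        return cls(**kwargs)


@dataclass
class ReportBundle:
    """Rounded report tables plus the structured warning/decision log."""

    composition: pd.DataFrame | None = None
    lipid: pd.DataFrame | None = None
    calibration: pd.DataFrame | None = None
    cv_summary: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("composition", "lipid", "calibration", "cv_summary"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.csv", index=False)
        (out / "run.log").write_text("".join(line + "\n" for line in self.log))


class _LogCapture(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record):
        self.sink.append(f"{record.name}: {record.getMessage()}")


def run_nmr_pipeline(
    config: RunConfig,
    sample_paths: list,
    reference_path,
    calibration_path=None,
) -> ReportBundle:
    """Spectra → integrals → composition + total lipid (+ Soxhlet calibration).

    Each sample spectrum is integrated over the configured windows, the
    acyl-class percentages computed, and total lipid quantified against the
    reference-oil spectrum.  If a paired Soxhlet table is given (path or
    ``'published'`` for the bundled one) correction factors and correlations
    are appended.
    """
    if reference_path is None:
        raise ValidationError("an external reference-oil spectrum is required")
    bundle = ReportBundle()
    capture = _LogCapture(bundle.log)
    logging.getLogger("seedlipid").addHandler(capture)
    try:
        reference = read_spectrum_csv(reference_path, kind="nmr")
        ref_table = nmr.assign_and_integrate(
            reference, config.assignments, baseline=config.baseline
        )
        comp_rows, lipid_rows = [], []
        for p in sample_paths:
            spec = read_spectrum_csv(p, kind="nmr")
            table = nmr.assign_and_integrate(
                spec, config.assignments, baseline=config.baseline
            )
            comp = nmr.acyl_composition(table)
            d = config.decimals
            comp_rows.append({
                "sample_id": spec.sample_id,
                "linolenic_pct": round_half_up(comp.linolenic_pct, d),
                "linoleic_pct": round_half_up(comp.linoleic_pct, d),
                "oleic_pct": round_half_up(comp.oleic_pct, d),
                "saturated_pct": round_half_up(comp.saturated_pct, d),
            })
            mass = spec.sample_mass if np.isfinite(spec.sample_mass) else 1.0
            ref_mass = reference.sample_mass if np.isfinite(reference.sample_mass) else 1.0
            quant = nmr.total_lipid(
                table, mass, ref_table, ref_mass,
                sample_id=spec.sample_id, reference_id=reference.sample_id,
                lipid_labels=config.lipid_window_labels,
            )
            lipid_rows.append({
                "sample_id": quant.sample_id,
                "total_lipid_pct": round_half_up(quant.total_lipid_pct, config.decimals),
                "reference_id": quant.reference_id,
            })
        bundle.composition = pd.DataFrame(comp_rows)
        bundle.lipid = pd.DataFrame(lipid_rows)
        if calibration_path is not None:
            tables = calibration.load_paired_tables(
                None if calibration_path == "published" else calibration_path
            )
            comparisons = calibration.compare_all(tables)
            bundle.calibration = calibration.comparison_report(
                comparisons, decimals=config.decimals
            )
    finally:
        logging.getLogger("seedlipid").removeHandler(capture)
    return bundle


def run_nir_pipeline(config: RunConfig, matrix_path, reference_path) -> ReportBundle:
    """Absorbance → truncation → pretreatment recipes → LOOCV summary rows."""
    if not config.pretreatment_recipes:
        raise ValidationError("at least one pretreatment recipe is required")
    bundle = ReportBundle()
    capture = _LogCapture(bundle.log)
    logging.getLogger("seedlipid").addHandler(capture)
    try:
        matrix = read_nir_matrix_csv(matrix_path, reference_path)
        matrix = nir.truncate(matrix, *config.nir_range)
        rows = []
        for recipe in config.pretreatment_recipes:
            cv = nir.loocv(
                matrix, config.n_factors, list(recipe),
                detrend_order=config.detrend_order,
                gap=config.derivative_gap, segment=config.derivative_segment,
            )
            d = config.decimals
            rows.append({
                "pretreatment": "+".join(recipe) or "none",
                "factors": cv.n_factors,
                "r_squared": round_half_up(cv.r_squared, d),
                "secv": round_half_up(cv.secv, d),
                "reference_sd": round_half_up(
                    float(np.std(matrix.reference_y, ddof=1)), d
                ),
                "rpd": round_half_up(cv.rpd, d),
            })
        bundle.cv_summary = pd.DataFrame(rows)
    finally:
        logging.getLogger("seedlipid").removeHandler(capture)
    return bundle
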