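"""NIR chemometrics: pretreatments, NIPALS PLS1 and leave-one-out validation.

Implements the standard near-infrared calibration stack for predicting a
constituent (here, lipid % dry mass) from diffuse-reflectance spectra:

* reflectance → absorbance, ``A = log10(1/R)``
* wavelength truncation to the informative NIR range (1100–2500 nm)
* scatter/baseline pretreatments: SNV, polynomial detrend, gap-segment
  first derivative, multiplicative scatter correction (MSC)
* PLS1 regression fit by NIPALS with per-factor deflation
* leave-one-out cross-validation reporting bias-corrected SECV, R² and
  RPD = sd(y)/SECV

Pretreatments whose parameters depend on other samples (the MSC reference
spectrum) are re-estimated inside each cross-validation training fold so the
left-out sample never informs its own prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateInputError,
    NumericalError,
    RangeError,
    ValidationError,
)


@dataclass(frozen=True)
class NIRSpectrum:
    """One reflectance or absorbance spectrum on a strictly increasing nm grid."""

    wavelength: np.ndarray
    signal: np.ndarray
    mode: str = "reflectance"  # or "absorbance"
    sample_id: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if wl.ndim != 1 or wl.shape != sig.shape or wl.size < 2:
            raise ValidationError("wavelength and signal must be equal-length 1-D arrays")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if self.mode not in ("reflectance", "absorbance"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "reflectance" and (np.any(sig <= 0) or np.any(sig > 1)):
            raise ValidationError("reflectance values must lie in (0, 1]")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class SpectraMatrix:
    """Samples × wavelengths absorbance matrix with reference lipid values."""

    X: np.ndarray
    wavelength: np.ndarray
    reference_y: np.ndarray
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        wl = np.asarray(self.wavelength, dtype=float)
        y = np.asarray(self.reference_y, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (samples x wavelengths)")
        if X.shape[1] != wl.size:
            raise ValidationError("column count must match wavelength grid length")
        if X.shape[0] != y.size:
            raise ValidationError("row count must match reference_y length")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        ids = self.sample_ids or tuple(f"s{i}" for i in range(X.shape[0]))
        if len(ids) != X.shape[0]:
            raise ValidationError("sample_ids length must match row count")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "reference_y", y)
        object.__setattr__(self, "sample_ids", tuple(ids))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]


def stack_spectra(spectra: list[NIRSpectrum], reference_y) -> SpectraMatrix:
    """Stack absorbance spectra sharing one grid into a SpectraMatrix."""
    if not spectra:
        raise ValidationError("need at least one spectrum")
    grid = spectra[0].wavelength
    rows = []
    for s in spectra:
        if s.mode != "absorbance":
            raise ValidationError(f"sample {s.sample_id!r} is not in absorbance mode")
        if s.wavelength.shape != grid.shape or not np.allclose(s.wavelength, grid):
            raise ValidationError("all spectra must share one wavelength grid")
        rows.append(s.signal)
    return SpectraMatrix(
        X=np.vstack(rows),
        wavelength=grid,
        reference_y=np.asarray(reference_y, dtype=float),
        sample_ids=tuple(s.sample_id for s in spectra),
    )


def to_absorbance(spectrum: NIRSpectrum) -> NIRSpectrum:
    """Convert reflectance to absorbance, A = log10(1/R)."""
    if spectrum.mode != "reflectance":
        raise ValidationError("spectrum is not in reflectance mode")
    if np.any(spectrum.signal <= 0):
        raise ValidationError("reflectance must be positive to take log10(1/R)")
    return NIRSpectrum(
        wavelength=spectrum.wavelength,
        signal=np.log10(1.0 / spectrum.signal),
        mode="absorbance",
        sample_id=spectrum.sample_id,
    )


def truncate(matrix: SpectraMatrix, low: float, high: float) -> SpectraMatrix:
    """Restrict columns to wavelengths in [low, high] inclusive."""
    if not low < high:
        raise ValidationError("low must be < high")
    keep = (matrix.wavelength >= low) & (matrix.wavelength <= high)
    if not np.any(keep):
        raise RangeError(f"no wavelengths in [{low}, {high}] nm")
    return replace(matrix, X=matrix.X[:, keep], wavelength=matrix.wavelength[keep])


def snv(matrix: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: center each row, scale to unit sd (ddof=1)."""
    mu = matrix.X.mean(axis=1, keepdims=True)
    sd = matrix.X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise DegenerateInputError(
            f"constant spectrum, SNV undefined: sample {matrix.sample_ids[bad[0]]!r}"
        )
    return replace(matrix, X=(matrix.X - mu) / sd)


def detrend(matrix: SpectraMatrix, order: int = 2) -> SpectraMatrix:
    """Subtract a least-squares polynomial of the wavelength from each row."""
    if order < 0:
        raise ValidationError("polynomial order must be >= 0")
    if matrix.n_wavelengths <= order:
        raise ValidationError("need more wavelengths than the polynomial order")
    # Legendre-style scaled abscissa keeps the Vandermonde well conditioned.
    u = 2.0 * (matrix.wavelength - matrix.wavelength[0]) / (
        matrix.wavelength[-1] - matrix.wavelength[0]
    ) - 1.0
    V = np.vander(u, order + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(V, matrix.X.T, rcond=None)
    if rank < order + 1:
        raise NumericalError("rank-deficient polynomial fit in detrend")
    return replace(matrix, X=matrix.X - (V @ coef).T)


def forward_derivative(matrix: SpectraMatrix, gap: int = 4, segment: int = 4) -> SpectraMatrix:
    """First-order gap-segment derivative.

    Each output point is the difference between two ``segment``-point block
    averages whose starts are ``gap`` points apart, divided by the block
    offset in nm.  The output grid is the midpoint of the two block centers
    and is shorter than the input by ``gap + segment - 1`` points.
    """
    if gap < 1 or segment < 1:
        raise ValidationError("gap and segment must be >= 1")
    p = matrix.n_wavelengths
    n_out = p - gap - segment + 1
    if n_out < 2:
        raise RangeError("too few wavelengths for the requested gap/segment")
    step = np.diff(matrix.wavelength)
    if not np.allclose(step, step[0]):
        raise ValidationError("gap-segment derivative requires an evenly spaced grid")
    dx = float(step[0])
    kernel = np.ones(segment) / segment
    # block average at each start index, valid positions 0..p-segment
    smoothed = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), 1, matrix.X
    )
    deriv = (smoothed[:, gap:gap + n_out] - smoothed[:, :n_out]) / (gap * dx)
    centers = matrix.wavelength[:n_out] + dx * ((segment - 1) / 2.0 + gap / 2.0)
    return replace(matrix, X=deriv, wavelength=centers)


def msc(matrix: SpectraMatrix, reference: np.ndarray | None = None) -> SpectraMatrix:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed on the reference (OLS, intercept + slope) and the
    fitted scatter model inverted: ``(row - intercept) / slope``.  With no
    reference given the column mean of the matrix is used.
    """
    if reference is None:
        if matrix.n_samples < 2:
            raise ValidationError("mean-reference MSC needs at least 2 samples")
        reference = matrix.X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (matrix.n_wavelengths,):
        raise ValidationError("reference length must match the wavelength grid")
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise DegenerateInputError("constant MSC reference spectrum")
    rows_c = matrix.X - matrix.X.mean(axis=1, keepdims=True)
    slope = rows_c @ ref_c / denom
    if np.any(slope == 0):
        bad = int(np.flatnonzero(slope == 0)[0])
        raise DegenerateInputError(f"zero MSC slope for sample {matrix.sample_ids[bad]!r}")
    intercept = matrix.X.mean(axis=1) - slope * reference.mean()
    corrected = (matrix.X - intercept[:, None]) / slope[:, None]
    return replace(matrix, X=corrected)


@dataclass(frozen=True)
class PLSModel:
    """PLS1 regression model in both factor and b-vector form.

    Prediction: ``y_hat = y_mean + (x - x_mean) @ b``.
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # p x k
    x_loadings: np.ndarray   # p x k
    y_loadings: np.ndarray   # k
    b: np.ndarray            # p

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.y_mean + (X - self.x_mean) @ self.b

    def predict_by_factors(self, X: np.ndarray) -> np.ndarray:
        """Prediction via the score/deflation recursion (consistency check)."""
        E = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean
        yhat = np.full(E.shape[0], self.y_mean)
        for k in range(self.n_factors):
            t = E @ self.weights[:, k]
            yhat += t * self.y_loadings[k]
            E = E - np.outer(t, self.x_loadings[:, k])
        return yhat


def pls_fit(
    matrix: SpectraMatrix,
    n_factors: int,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> PLSModel:
    """Fit PLS1 by NIPALS on column-centered X and centered y.

    Each factor's weight vector is iterated to convergence (relative change
    < ``tol``; for a single response NIPALS converges in one pass) and both
    X and y are deflated before the next factor.  The b-vector is assembled
    as ``W (PᵀW)⁻¹ q`` so a single inner product reproduces the recursive
    prediction.
    """
    n, p = matrix.X.shape
    if not 1 <= n_factors <= min(n - 1, p):
        raise ValidationError(
            f"n_factors must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    y = matrix.reference_y
    if np.std(y) == 0:
        raise DegenerateInputError("reference values have zero variance")
    x_mean = matrix.X.mean(axis=0)
    y_mean = float(y.mean())
    E = matrix.X - x_mean
    f = y - y_mean

    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    for k in range(n_factors):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:
            raise NumericalError(f"zero weight vector at factor {k + 1}; reduce n_factors")
        w /= norm
        for _ in range(max_iter):
            t = E @ w
            tt = float(t @ t)
            if tt == 0:
                raise NumericalError(f"zero score vector at factor {k + 1}")
            qk = float(f @ t) / tt
            w_new = E.T @ (f * qk)
            n_new = np.linalg.norm(w_new)
            if n_new == 0:
                break
            w_new /= n_new
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        else:
            raise NumericalError(f"NIPALS did not converge at factor {k + 1}")
        t = E @ w
        tt = float(t @ t)
        pk = E.T @ t / tt
        qk = float(f @ t) / tt
        E = E - np.outer(t, pk)
        f = f - qk * t
        W[:, k], P[:, k], q[k] = w, pk, qk

    try:
        b = W @ np.linalg.solve(P.T @ W, q)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular PᵀW in b-vector assembly") from exc
    return PLSModel(
        n_factors=n_factors, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q, b=b,
    )


@dataclass(frozen=True)
class CVResult:
    """Leave-one-out cross-validation summary."""

    predictions: np.ndarray
    bias: float
    secv: float
    r_squared: float
    rpd: float
    n_factors: int

    def __post_init__(self):
        if self.secv < 0:
            raise ValidationError("SECV cannot be negative")
        object.__setattr__(
            self, "predictions", np.asarray(self.predictions, dtype=float)
        )


# ---------------------------------------------------------------------------
# Pretreatment recipes

#: op name -> (function applied to a SpectraMatrix, is_row_local)
_ROW_LOCAL_OPS = {
    "snv": snv,
    "detrend": detrend,
    "deriv1": forward_derivative,
}


def apply_pretreatments(
    train: SpectraMatrix,
    ops: list[str],
    test: SpectraMatrix | None = None,
    *,
    detrend_order: int = 2,
    gap: int = 4,
    segment: int = 4,
) -> tuple[SpectraMatrix, SpectraMatrix | None]:
    """Apply an ordered pretreatment recipe to a training set (and optionally
    a held-out set, using only training-derived statistics).

    Recognised ops: ``snv``, ``detrend``, ``deriv1``, ``msc``.  The first
    three are row-local; ``msc`` uses the training-set mean as its reference
    for both training and held-out rows.
    """
    for op in ops:
        if op == "snv":
            train = snv(train)
            test = snv(test) if test is not None else None
        elif op == "detrend":
            train = detrend(train, order=detrend_order)
            test = detrend(test, order=detrend_order) if test is not None else None
        elif op == "deriv1":
            train = forward_derivative(train, gap=gap, segment=segment)
            test = (
                forward_derivative(test, gap=gap, segment=segment)
                if test is not None else None
            )
        elif op == "msc":
            ref = train.X.mean(axis=0)
            train = msc(train, reference=ref)
            test = msc(test, reference=ref) if test is not None else None
        else:
            raise ValidationError(f"unknown pretreatment op {op!r}")
    return train, test


def loocv(
    matrix: SpectraMatrix,
    n_factors: int,
    pretreatment: list[str] | None = None,
    *,
    detrend_order: int = 2,
    gap: int = 4,
    segment: int = 4,
    secv_ddof: int = 1,
) -> CVResult:
    """Leave-one-out cross-validation of a pretreatment + PLS1 pipeline.

    For each sample the recipe's data-dependent statistics and the PLS model
    are fit on the remaining n−1 samples, and the left-out spectrum is
    predicted.  Reported statistics::

        bias = mean(y_hat - y)
        SECV = sqrt( sum((y_hat - y - bias)^2) / (n - secv_ddof) )
        R²   = squared Pearson correlation of (y_hat, y)
        RPD  = sd(y, ddof=1) / SECV
    """
    n = matrix.n_samples
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 samples")
    if n_factors > n - 2:
        raise ValidationError(
            f"n_factors={n_factors} too large for folds of size {n - 1}"
        )
    pretreatment = list(pretreatment or [])
    preds = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train = SpectraMatrix(
            X=matrix.X[keep], wavelength=matrix.wavelength,
            reference_y=matrix.reference_y[keep],
            sample_ids=tuple(np.asarray(matrix.sample_ids)[keep]),
        )
        test = SpectraMatrix(
            X=matrix.X[~keep], wavelength=matrix.wavelength,
            reference_y=matrix.reference_y[~keep],
            sample_ids=(matrix.sample_ids[i],),
        )
        train, test = apply_pretreatments(
            train, pretreatment, test,
            detrend_order=detrend_order, gap=gap, segment=segment,
        )
        model = pls_fit(train, n_factors)
        preds[i] = model.predict(test.X)[0]

    y = matrix.reference_y
    resid = preds - y
    bias = float(resid.mean())
    secv = float(np.sqrt(np.sum((resid - bias) ** 2) / (n - secv_ddof)))
    r = float(np.corrcoef(preds, y)[0, 1])
    return CVResult(
        predictions=preds, bias=bias, secv=secv,
        r_squared=r * r,
        rpd=rpd(float(np.std(y, ddof=1)), secv) if secv > 0 else float("inf"),
        n_factors=n_factors,
    )


def rpd(reference_sd: float, secv: float) -> float:
    """Ratio of the reference values' standard deviation to the SECV."""
    if secv <= 0:
        raise DegenerateInputError("SECV must be positive to form an RPD")
    return reference_sd / secv
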