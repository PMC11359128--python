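"""Semivariogram modelling and ordinary kriging.

The semivariogram gamma(h) is half the expected squared difference between
field values a lag distance h apart.  Five isotropic model families are
supported (nugget C0, partial sill C, range a, and for the stable family a
shape exponent omega):

========== =====================================================
family      gamma(h) for h > 0            (gamma(0) = 0 always)
========== =====================================================
exponential C0 + C * (1 - exp(-h/a))
gaussian    C0 + C * (1 - exp(-h^2/a^2))
spherical   C0 + C * (3h/(2a) - (h/a)^3 / 2)          for h <= a
circular    C0 + C * (1 - 2/pi * (acos(h/a)
                       - h/a * sqrt(1 - h^2/a^2)))    for h <= a
stable      C0 + C * (1 - exp(-(h/a)^omega)),  omega in (0, 2]
========== =====================================================

Spherical and circular reach the sill C0+C exactly at h = a; the others
approach it asymptotically (effective ranges 3a and sqrt(3)a for the
exponential and Gaussian).  Ordinary kriging solves, per target, the
covariance-form system with a Lagrange multiplier enforcing that the
weights sum to one; the covariance is C(h) = sill - gamma(h) with the
nugget entering only the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .io import SampleSet, ValidationError

__all__ = [
    "FAMILIES",
    "VariogramModel",
    "EmpiricalVariogram",
    "KrigingRaster",
    "CrossValidationReport",
    "model_semivariance",
    "empirical_semivariogram",
    "fit_variogram",
    "krige",
    "krige_grid",
    "loo_cross_validate",
    "classify_spd",
    "select_best_model",
]

FAMILIES = ("circular", "spherical", "exponential", "gaussian", "stable")

#: nugget/sill ratio cut points of the spatial-dependence classification
SPD_STRONG, SPD_WEAK = 0.25, 0.75


@dataclass(frozen=True)
class VariogramModel:
    """Fitted spatial-structure parameters of one metal.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    nugget : float
        Semivariance at infinitesimal lag (micro-scale variance plus
        measurement error), >= 0.
    partial_sill : float
        Spatially structured variance, >= 0.  ``sill = nugget + partial_sill``.
    range_ : float
        Distance constant a (km), > 0.
    shape : float
        Stable-model exponent omega in (0, 2]; ignored by other families.
    """

    family: str
    nugget: float
    partial_sill: float
    range_: float
    shape: float = 1.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown variogram family {self.family!r}; choose from {FAMILIES}"
            )
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValidationError("nugget and partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValidationError("range must be > 0")
        if self.family == "stable" and not (0 < self.shape <= 2):
            raise ValidationError("stable shape omega must lie in (0, 2]")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def effective_range(self) -> float:
        """Distance at which the model reaches ~95% of the sill."""
        if self.family == "exponential":
            return 3.0 * self.range_
        if self.family == "gaussian":
            return float(np.sqrt(3.0)) * self.range_
        if self.family == "stable":
            return float(3.0 ** (1.0 / self.shape)) * self.range_
        return self.range_

    def semivariance(self, h) -> np.ndarray:
        return model_semivariance(self, h)

    def covariance(self, h) -> np.ndarray:
        """C(h) = sill - gamma(h); equals the full sill at h = 0."""
        return self.sill - self.semivariance(h)


def model_semivariance(model: VariogramModel, h) -> np.ndarray:
    """Evaluate gamma(h) for one model; h may be scalar or array, in km."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValidationError("lag distance h must be >= 0")
    c0, c, a = model.nugget, model.partial_sill, model.range_
    hr = h / a
    if model.family == "exponential":
        g = c0 + c * (1.0 - np.exp(-hr))
    elif model.family == "gaussian":
        g = c0 + c * (1.0 - np.exp(-(hr**2)))
    elif model.family == "stable":
        with np.errstate(invalid="ignore"):
            g = c0 + c * (1.0 - np.exp(-np.power(hr, model.shape)))
    elif model.family == "spherical":
        hr = np.minimum(hr, 1.0)
        g = c0 + c * (1.5 * hr - 0.5 * hr**3)
    elif model.family == "circular":
        hr = np.minimum(hr, 1.0)
        g = c0 + c * (1.0 - 2.0 / np.pi * (np.arccos(hr) - hr * np.sqrt(1.0 - hr**2)))
    else:  # pragma: no cover - guarded in __post_init__
        raise ValidationError(f"unknown family {model.family!r}")
    return np.where(h == 0.0, 0.0, g)


@dataclass
class EmpiricalVariogram:
    """Binned method-of-moments semivariogram estimate."""

    lag_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    max_lag: float
    lag_width: float

    def __post_init__(self) -> None:
        if not (
            len(self.lag_centers) == len(self.semivariance) == len(self.pair_counts)
        ):
            raise ValidationError("empirical variogram vectors must align")

    @property
    def populated(self) -> np.ndarray:
        """Mask of bins containing at least one pair (others excluded from fits)."""
        return self.pair_counts > 0


def empirical_semivariogram(
    samples: SampleSet,
    metal: str,
    lag_width: float | None = None,
    max_lag: float | None = None,
    n_bins: int = 12,
) -> EmpiricalVariogram:
    """Method-of-moments semivariogram: gamma(bin) = sum (zi-zj)^2 / (2 N).

    Pairs are assigned to equal-width bins by distance; the default
    ``max_lag`` is half the maximum pairwise distance split into
    ``n_bins`` bins.
    """
    if samples.n < 2:
        raise ValidationError("need at least 2 samples for a semivariogram")
    z = samples.values(metal)
    d = pdist(samples.coords)
    dz2 = pdist(z[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if lag_width is None:
        lag_width = max_lag / n_bins
    if lag_width <= 0 or max_lag <= 0:
        raise ValidationError("lag_width and max_lag must be > 0")
    keep = d <= max_lag
    if not keep.any():
        raise ValidationError(f"no pairs within max_lag={max_lag}")
    nb = int(np.ceil(max_lag / lag_width))
    idx = np.minimum((d[keep] / lag_width).astype(int), nb - 1)
    counts = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=dz2[keep], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / (2.0 * counts)
    gamma[counts == 0] = np.nan
    centers = (np.arange(nb) + 0.5) * lag_width
    return EmpiricalVariogram(centers, gamma, counts, max_lag, lag_width)


def _fit_starts(family: str, emp: EmpiricalVariogram) -> list[np.ndarray]:
    """Multistart initial points, ordered least-structured first.

    The pure-nugget start is tried first so that a flat empirical
    variogram resolves deterministically to C ~ 0 instead of trading the
    nugget off against structure at an arbitrary range.
    """
    m = emp.populated
    level = float(np.average(emp.semivariance[m], weights=emp.pair_counts[m]))
    level = max(level, 1e-12)
    hmax = emp.max_lag
    starts = [np.array([level, 1e-6, hmax / 3.0])]
    for frac in (0.15, 0.35, 0.6, 1.0):
        starts.append(np.array([0.2 * level, 0.8 * level, frac * hmax]))
    if family == "stable":
        starts = [np.append(s, w) for s in starts for w in (1.0, 1.5)]
    return starts


def fit_variogram(
    emp: EmpiricalVariogram, family: str, n_starts: int = 5
) -> tuple[VariogramModel, float]:
    """Weighted least-squares fit of one family to an empirical variogram.

    Minimizes sum N(h) * (gamma_hat(h) - gamma(h))^2 over populated bins
    with bounds C0 >= 0, C >= 0, a in (0, 2*max_lag] (and omega in
    (0, 2] for the stable family), restarting from several range values.
    Returns the fitted model and the achieved objective.
    """
    mask = emp.populated & np.isfinite(emp.semivariance)
    if mask.sum() < 3:
        raise ValidationError("need >= 3 populated lag bins to fit a variogram")
    h = emp.lag_centers[mask]
    g = emp.semivariance[mask]
    w = np.sqrt(emp.pair_counts[mask].astype(float))

    def residuals(theta: np.ndarray) -> np.ndarray:
        shape = theta[3] if family == "stable" else 1.5
        m = VariogramModel(family, theta[0], theta[1], theta[2], shape)
        return w * (m.semivariance(h) - g)

    lo = [0.0, 0.0, 1e-9]
    hi = [np.inf, np.inf, 2.0 * emp.max_lag]
    if family == "stable":
        lo, hi = lo + [0.05], hi + [2.0]

    best: tuple[float, np.ndarray] | None = None
    failures: list[str] = []
    for start in _fit_starts(family, emp)[: n_starts * (2 if family == "stable" else 1)]:
        start = np.clip(start, lo, hi)
        try:
            sol = least_squares(residuals, start, bounds=(lo, hi), method="trf")
        except Exception as exc:  # noqa: BLE001 - collected for diagnostics
            failures.append(str(exc))
            continue
        obj = float(np.sum(sol.fun**2))
        if best is None or obj < best[0] * (1.0 - 1e-12) - 1e-15:
            best = (obj, sol.x)
    if best is None:
        raise ValidationError(
            f"variogram fit failed for family {family!r}: {failures}"
        )
    obj, theta = best
    shape = float(theta[3]) if family == "stable" else 1.5
    model = VariogramModel(family, float(theta[0]), float(theta[1]), float(theta[2]), shape)
    return model, obj


def _dedupe(coords: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicated locations (kriging system is singular otherwise)."""
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    warnings.warn(
        f"{len(coords) - len(uniq)} duplicate sample locations averaged before kriging",
        stacklevel=3,
    )
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inv, values)
    np.add.at(counts, inv, 1.0)
    return uniq, sums / counts


def _ok_solve(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the ordinary-kriging system per target over a k-nearest neighborhood."""
    n = len(coords)
    k = min(k, n)
    tree = cKDTree(coords)
    _, nbr = tree.query(targets, k=k)
    nbr = np.atleast_2d(nbr)
    if k == 1:
        nbr = nbr.reshape(-1, 1)
    full_cov = model.covariance(squareform(pdist(coords))) if n > 1 else np.array([[model.sill]])
    np.fill_diagonal(full_cov, model.sill)

    preds = np.empty(len(targets))
    variances = np.empty(len(targets))
    clipped = False
    for t, target in enumerate(targets):
        idx = nbr[t]
        cmat = full_cov[np.ix_(idx, idx)]
        d0 = np.linalg.norm(coords[idx] - target, axis=1)
        c0 = model.covariance(d0)
        m = len(idx)
        lhs = np.empty((m + 1, m + 1))
        lhs[:m, :m] = cmat
        lhs[:m, m] = 1.0
        lhs[m, :m] = 1.0
        lhs[m, m] = 0.0
        rhs = np.append(c0, 1.0)
        try:
            sol = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
        lam, mu = sol[:m], sol[m]
        preds[t] = float(lam @ values[idx])
        var = float(model.sill - lam @ c0 - mu)
        if var < 0:
            clipped = clipped or var < -1e-8
            var = 0.0
        variances[t] = var
    if clipped:
        warnings.warn("negative kriging variances clipped to 0", stacklevel=3)
    return preds, variances


def krige(
    samples: SampleSet,
    metal: str,
    model: VariogramModel,
    targets,
    k: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging predictions and kriging variances at target points.

    The neighborhood is the ``k`` nearest samples (all samples when
    n < k).  Weights sum to one by construction of the constrained
    system; duplicate sample locations are averaged first.
    """
    if model.sill <= 0:
        raise ValidationError("kriging requires a model with positive sill")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    coords, values = _dedupe(samples.coords, samples.values(metal))
    return _ok_solve(coords, values, model, targets, k)


@dataclass
class KrigingRaster:
    """Gridded kriging predictions and variances for one metal.

    Row 0 is the *south* edge; cell centers are at
    ``origin + (j + 0.5, i + 0.5) * cell_size``.
    """

    origin: tuple[float, float]
    cell_size: float
    prediction: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        if self.prediction.shape != self.variance.shape:
            raise ValidationError("prediction/variance grids must share a shape")
        if np.any(self.variance[np.isfinite(self.variance)] < 0):
            raise ValidationError("kriging variance must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.prediction.shape[0]

    @property
    def n_cols(self) -> int:
        return self.prediction.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys


def krige_grid(
    samples: SampleSet,
    metal: str,
    model: VariogramModel,
    bbox: tuple[float, float, float, float],
    cell_size: float,
    k: int = 16,
) -> KrigingRaster:
    """Krige one metal over a regular grid covering ``bbox`` = (xmin, ymin, xmax, ymax)."""
    if cell_size <= 0:
        raise ValidationError("cell_size must be > 0")
    xmin, ymin, xmax, ymax = bbox
    n_cols = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
    n_rows = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
    xs = xmin + (np.arange(n_cols) + 0.5) * cell_size
    ys = ymin + (np.arange(n_rows) + 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    preds, variances = krige(samples, metal, model, targets, k=k)
    return KrigingRaster(
        (xmin, ymin),
        cell_size,
        preds.reshape(n_rows, n_cols),
        variances.reshape(n_rows, n_cols),
    )


@dataclass
class CrossValidationReport:
    """Leave-one-out kriging diagnostics for one metal/model pair.

    ``mse`` is the mean standardized residual (ideal 0) and ``rmsse`` the
    root-mean-square standardized residual (ideal 1); ``mean_error`` is
    the plain (unstandardized) mean error kept as an extra diagnostic.
    """

    metal: str
    model: VariogramModel
    predictions: np.ndarray = field(repr=False)
    std_errors: np.ndarray = field(repr=False)
    mse: float = 0.0
    rmsse: float = 0.0
    mean_error: float = 0.0

    @property
    def nugget_sill_ratio(self) -> float:
        return self.model.nugget / self.model.sill

    @property
    def spd(self) -> str:
        return classify_spd(self.model)[0]


def loo_cross_validate(
    samples: SampleSet, metal: str, model: VariogramModel, k: int = 16
) -> CrossValidationReport:
    """Leave-one-out cross-validation of an ordinary-kriging model.

    Each sample is predicted from the remaining n-1; the standardized
    residual r_i = (zhat_i - z_i) / sigma_i uses the kriging standard
    error sigma_i.
    """
    if samples.n < 3:
        raise ValidationError("leave-one-out CV needs at least 3 samples")
    coords, values = _dedupe(samples.coords, samples.values(metal))
    n = len(coords)
    preds = np.empty(n)
    sigmas = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        sub = coords[mask], values[mask]
        p, v = _ok_solve(sub[0], sub[1], model, coords[i][None, :], k=min(k, n - 1))
        preds[i], sigmas[i] = p[0], float(np.sqrt(v[0]))
        mask[i] = True
    zero = sigmas == 0.0
    if zero.any():
        raise ValidationError(
            f"zero kriging standard error at sample index {int(np.argmax(zero))}: "
            "degenerate model (no nugget and coincident support?)"
        )
    r = (preds - values) / sigmas
    return CrossValidationReport(
        metal=metal,
        model=model,
        predictions=preds,
        std_errors=sigmas,
        mse=float(np.mean(r)),
        rmsse=float(np.sqrt(np.mean(r**2))),
        mean_error=float(np.mean(preds - values)),
    )


def classify_spd(model: VariogramModel) -> tuple[str, float]:
    """Spatial-dependence class from the nugget/sill ratio.

    ratio < 0.25 -> strong, 0.25-0.75 -> moderate (boundaries inclusive),
    ratio > 0.75 -> weak.  Returns (label, unrounded ratio); reports
    round the ratio to 2 decimals.
    """
    if model.sill <= 0:
        raise ValidationError("SPD classification requires a positive sill")
    ratio = model.nugget / model.sill
    if ratio < SPD_STRONG:
        label = "strong"
    elif ratio > SPD_WEAK:
        label = "weak"
    else:
        label = "moderate"
    return label, ratio


def select_best_model(
    samples: SampleSet,
    metal: str,
    families=FAMILIES,
    k: int = 16,
    lag_width: float | None = None,
    max_lag: float | None = None,
) -> tuple[VariogramModel, list[dict]]:
    """Fit each candidate family, cross-validate, and rank by CV score.

    score = \\|MSE\\| + \\|RMSSE - 1\\|, ties broken by the fitting objective
    and then input order.  Returns the winning model and the full ranked
    table (one dict per family).
    """
    families = list(families)
    if len(families) < 1:
        raise ValidationError("need at least one candidate family")
    emp = empirical_semivariogram(samples, metal, lag_width=lag_width, max_lag=max_lag)
    rows: list[dict] = []
    failures: list[str] = []
    for order, fam in enumerate(families):
        try:
            model, obj = fit_variogram(emp, fam)
            cv = loo_cross_validate(samples, metal, model, k=k)
        except ValidationError as exc:
            failures.append(f"{fam}: {exc}")
            continue
        rows.append(
            {
                "family": fam,
                "model": model,
                "objective": obj,
                "mse": cv.mse,
                "rmsse": cv.rmsse,
                "mean_error": cv.mean_error,
                "score": abs(cv.mse) + abs(cv.rmsse - 1.0),
                "order": order,
            }
        )
    if not rows:
        raise ValidationError(f"all variogram fits failed for {metal}: {failures}")
    rows.sort(key=lambda r: (r["score"], r["objective"], r["order"]))
    return rows[0]["model"], rows
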