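"""Per-arm regression learners used to predict the next patient's outcome.

Continuous-outcome families: polynomial least squares, k-nearest-neighbour,
Gaussian-process regression (squared-exponential kernel plus observation
noise), cubic smoothing spline (GCV) and random forest.  Every family is
wrapped in a small degenerate-data fallback ladder (requested family ->
reduced-degree polynomial -> arm mean) so the allocation engine always has
a prediction once the burn-in is complete.

Survival families predict mean survival time (days) from censored data on
two binary biomarkers coded {1, 2}:

* ``cellwise`` — per biomarker-cell exponential maximum likelihood,
  mean = (total observed time in cell) / (events in cell), with shrinkage
  of empty or zero-event cells to the arm-pooled exponential mean.  This
  coincides with a saturated log-link exponential regression.
* ``main_effects`` — log-link exponential regression with additive main
  effects of the two biomarkers (the parametric analogue of a low-order
  polynomial), fitted by Newton iteration on the 4 aggregated cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "FittedPredictor",
    "fit_polynomial",
    "fit_nearest_neighbor",
    "fit_gaussian_process",
    "fit_spline",
    "fit_random_forest",
    "fit_survival_cellwise",
    "fit_survival_parametric",
    "make_learner",
    "CONTINUOUS_FAMILIES",
    "SURVIVAL_FAMILIES",
]


@dataclass
class FittedPredictor:
    """A fitted per-arm regression, exposing deterministic point prediction."""

    family: str
    _predict: Callable[[np.ndarray], np.ndarray]
    n_obs: int = 0
    state: object = None

    def predict(self, x) -> float | np.ndarray:
        """Predicted outcome at biomarker vector(s) ``x``.

        Accepts a scalar, a single biomarker vector, or an (n, d) array.
        """
        xa = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.asarray(self._predict(xa), dtype=float).ravel()
        return float(out[0]) if np.asarray(x).ndim <= 1 else out


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot fit a learner on an empty dataset")
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    return x, y


# ---------------------------------------------------------------------------
# Continuous-outcome families
# ---------------------------------------------------------------------------

def fit_polynomial(x, y, degree: int = 3) -> FittedPredictor:
    """Least-squares polynomial in the (scalar) biomarker.

    The degree is automatically reduced to (#distinct x values) - 1 so the
    fit is always full rank; a single repeated x value degenerates to the
    mean outcome at that point.
    """
    x, y = _as_xy(x, y)
    x1 = x[:, 0]
    deg = min(degree, len(np.unique(x1)) - 1)
    if deg <= 0:
        return _fit_mean(y, family="polynomial")
    # Polynomial.fit maps x to [-1, 1] internally, keeping the basis stable.
    poly = np.polynomial.Polynomial.fit(x1, y, deg)
    return FittedPredictor("polynomial", lambda xa: poly(xa[:, 0]),
                           n_obs=len(y), state=poly)


def _fit_mean(y, family: str) -> FittedPredictor:
    m = float(np.mean(y))
    return FittedPredictor(family, lambda xa: np.full(len(xa), m), n_obs=len(y))


def default_k_neighbors(n_obs: int) -> int:
    """Default neighbourhood size: max(3, ceil(sqrt(n)))."""
    return max(3, math.ceil(math.sqrt(n_obs)))


def fit_nearest_neighbor(x, y, k_neighbors: int | None = None) -> FittedPredictor:
    """k-nearest-neighbour regression on the biomarker (Euclidean distance).

    ``k`` is capped at the dataset size; distance ties at the k-th
    neighbour include every tied point.
    """
    x, y = _as_xy(x, y)
    k = default_k_neighbors(len(y)) if k_neighbors is None else k_neighbors
    k = min(k, len(y))

    def predict(xa: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(xa[:, None, :] - x[None, :, :], axis=2)
        kth = np.partition(d, k - 1, axis=1)[:, k - 1]
        mask = d <= kth[:, None] + 1e-12 * (1.0 + kth[:, None])
        return (mask @ y) / mask.sum(axis=1)

    return FittedPredictor("nearest", predict, n_obs=len(y))


def fit_gaussian_process(x, y, seed: int | None = None, n_restarts: int = 5,
                         fixed_kernel=None) -> FittedPredictor:
    """Gaussian-process posterior-mean regression.

    Squared-exponential (RBF) kernel with a constant amplitude and an
    additive white-noise term; hyperparameters by bounded marginal-
    likelihood maximisation with ``n_restarts`` restarts.  Passing
    ``fixed_kernel`` (a fitted kernel) skips the hyperparameter search and
    only recomputes the posterior — the allocation engine uses this to
    refit cheaply between scheduled hyperparameter updates.  A failed
    search falls back to fixed default hyperparameters with a warning.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    x, y = _as_xy(x, y)
    span = float(np.ptp(x[:, 0])) or 1.0
    if fixed_kernel is not None:
        kernel, optimizer, restarts = fixed_kernel, None, 0
    else:
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * RBF(length_scale=span / 4.0, length_scale_bounds=(span / 50.0, span * 10.0))
            + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-8, 1e3))
        )
        optimizer, restarts = "fmin_l_bfgs_b", n_restarts
    gp = GaussianProcessRegressor(
        kernel=kernel, optimizer=optimizer, n_restarts_optimizer=restarts,
        normalize_y=True, random_state=seed,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(x, y)
        if not np.isfinite(gp.log_marginal_likelihood_value_):
            raise FloatingPointError("non-finite marginal likelihood")
    except Exception:  # pragma: no cover - rare optimizer failure
        warnings.warn("GP hyperparameter search failed; using default hyperparameters")
        gp = GaussianProcessRegressor(kernel=kernel, optimizer=None,
                                      normalize_y=True, random_state=seed)
        gp.fit(x, y)
    return FittedPredictor("gp", lambda xa: gp.predict(xa), n_obs=len(y), state=gp)


def fit_spline(x, y) -> FittedPredictor:
    """Cubic smoothing spline, smoothing parameter by generalized
    cross-validation.  Needs >= 4 distinct x values; otherwise falls back
    to a reduced-degree polynomial.  Duplicate x values are aggregated to
    weighted means, which leaves the penalized least-squares fit unchanged.
    """
    x, y = _as_xy(x, y)
    x1 = x[:, 0]
    ux, inv, counts = np.unique(x1, return_inverse=True, return_counts=True)
    if len(ux) < 4:
        return fit_polynomial(x, y, degree=3)
    uy = np.bincount(inv, weights=y) / counts
    try:
        spl = make_smoothing_spline(ux, uy, w=counts.astype(float))
    except Exception:
        return fit_polynomial(x, y, degree=3)
    return FittedPredictor("spline", lambda xa: spl(xa[:, 0]), n_obs=len(y), state=spl)


def fit_random_forest(x, y, n_trees: int = 100, seed: int | None = None
                      ) -> FittedPredictor:
    """Random-forest regression (tree-average prediction)."""
    from sklearn.ensemble import RandomForestRegressor

    x, y = _as_xy(x, y)
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(x, y)
    return FittedPredictor("random_forest", lambda xa: rf.predict(xa),
                           n_obs=len(y), state=rf)


# ---------------------------------------------------------------------------
# Survival families (censored outcomes, two binary biomarkers coded {1, 2})
# ---------------------------------------------------------------------------

def _cell_index(x: np.ndarray) -> np.ndarray:
    """Map (n, 2) biomarker codes on {1,2} to flat cell index 0..3."""
    xi = np.asarray(x, dtype=float).astype(int) - 1
    return xi[:, 0] * 2 + xi[:, 1]


def _cell_totals(x, t, d) -> tuple[np.ndarray, np.ndarray]:
    idx = _cell_index(np.atleast_2d(x))
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    time_c = np.bincount(idx, weights=t, minlength=4)
    events_c = np.bincount(idx, weights=d, minlength=4)
    return time_c, events_c


def _pooled_exponential_mean(t, d) -> float:
    """Arm-pooled exponential MLE, degrading gracefully with no events."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    total_events = d.sum()
    if total_events > 0:
        return float(t.sum() / total_events)
    # Zero events anywhere: total observed time is a conservative lower
    # bound for the mean (the likelihood is maximized at infinity).
    return float(max(t.sum(), 1.0))


def fit_survival_cellwise(x, t, d) -> FittedPredictor:
    """Per-cell exponential MLE of mean survival, with shrinkage fallback.

    Each of the four biomarker cells gets mean = sum(observed time) /
    number of events; cells with no events (or no patients) borrow the
    arm-pooled exponential mean.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if len(x) == 0:
        raise ValueError("cannot fit a survival learner on an empty dataset")
    time_c, events_c = _cell_totals(x, t, d)
    pooled = _pooled_exponential_mean(t, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(events_c > 0, time_c / np.maximum(events_c, 1.0), pooled)

    def predict(xa: np.ndarray) -> np.ndarray:
        return means[_cell_index(xa)]

    return FittedPredictor("cellwise", predict, n_obs=len(x), state=means)


def fit_survival_parametric(x, t, d, family: str = "main_effects"
                            ) -> FittedPredictor:
    """Log-link exponential regression of survival on the biomarker codes.

    ``family='main_effects'`` fits hazard ``log lambda = b0 + b1*z1 + b2*z2``
    (z = code - 1) by Newton iteration on the cell-aggregated likelihood;
    the predicted mean survival is ``1 / lambda``.  ``family='saturated'``
    (main effects + interaction) has the cellwise MLE as its closed form
    and simply delegates to :func:`fit_survival_cellwise`.  Non-convergence
    falls back to the cellwise estimator.
    """
    if family == "saturated":
        return fit_survival_cellwise(x, t, d)
    if family != "main_effects":
        raise ValueError(f"unknown survival family: {family!r}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if len(x) == 0:
        raise ValueError("cannot fit a survival learner on an empty dataset")
    time_c, events_c = _cell_totals(x, t, d)
    if events_c.sum() == 0 or time_c.sum() <= 0:
        return fit_survival_cellwise(x, t, d)
    # Cell design matrix: intercept, z1, z2 for cells (z1, z2) in {0,1}^2.
    Z = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=float)
    beta = np.array([math.log(events_c.sum() / time_c.sum()), 0.0, 0.0])

    def loglik(b):
        eta = np.clip(Z @ b, -30.0, 30.0)
        return float(events_c @ eta - np.exp(eta) @ time_c)

    ok = False
    for _ in range(100):
        lam = np.exp(np.clip(Z @ beta, -30.0, 30.0))
        grad = Z.T @ (events_c - lam * time_c)
        hess = -(Z.T * (lam * time_c)) @ Z
        try:
            step = np.linalg.solve(hess - 1e-10 * np.eye(3), grad)
        except np.linalg.LinAlgError:
            break
        # Backtracking line search keeps the iteration monotone; a cell
        # with events but almost no exposure can otherwise overshoot.
        base = loglik(beta)
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            if np.all(np.isfinite(cand)) and loglik(cand) >= base - 1e-12:
                break
            scale *= 0.5
        beta = beta - scale * step
        if np.max(np.abs(scale * step)) < 1e-10:
            ok = True
            break
    if not ok or not np.all(np.isfinite(beta)):
        return fit_survival_cellwise(x, t, d)

    def predict(xa: np.ndarray) -> np.ndarray:
        z = np.column_stack([np.ones(len(xa)),
                             np.asarray(xa, dtype=float) - 1.0])
        return np.exp(-(z @ beta))  # mean = 1 / hazard

    return FittedPredictor("survival_main_effects", predict, n_obs=len(x), state=beta)


# ---------------------------------------------------------------------------
# Family registry used by the trial engine
# ---------------------------------------------------------------------------

CONTINUOUS_FAMILIES = ("polynomial", "nearest", "gp", "spline", "random_forest")
SURVIVAL_FAMILIES = ("cellwise", "main_effects")

#: Aliases mapping the continuous-family names onto their survival-setting
#: analogues: flexible nonparametric families correspond to the saturated /
#: cellwise estimator, polynomial regression to additive main effects.
SURVIVAL_ALIASES = {
    "spline": "cellwise",
    "gp": "cellwise",
    "nearest": "cellwise",
    "saturated": "cellwise",
    "polynomial": "main_effects",
}


def make_learner(family: str, setting: str, seed: int | None = None,
                 **kwargs) -> Callable:
    """Return ``fit(x, y)`` / ``fit(x, t, d)`` for the named family.

    In the survival setting the continuous family names are accepted as
    aliases (see ``SURVIVAL_ALIASES``).  The returned callable applies the
    degenerate-data fallback ladder for continuous families.
    """
    if setting == "survival":
        fam = SURVIVAL_ALIASES.get(family, family)
        if fam == "random_forest" or family == "random_forest":
            raise ValueError("random forest is not supported in the survival setting")
        if fam == "cellwise":
            return lambda x, t, d: fit_survival_cellwise(x, t, d)
        if fam == "main_effects":
            return lambda x, t, d: fit_survival_parametric(x, t, d, "main_effects")
        raise ValueError(f"unknown survival learner family: {family!r}")

    if family == "polynomial":
        degree = kwargs.get("degree", 3)
        return lambda x, y: fit_polynomial(x, y, degree=degree)
    if family == "nearest":
        k = kwargs.get("k_neighbors")
        return lambda x, y: fit_nearest_neighbor(x, y, k_neighbors=k)
    if family == "gp":
        n_restarts = kwargs.get("n_restarts", 5)
        return lambda x, y, fixed_kernel=None: fit_gaussian_process(
            x, y, seed=seed, n_restarts=n_restarts, fixed_kernel=fixed_kernel)
    if family == "spline":
        return lambda x, y: fit_spline(x, y)
    if family == "random_forest":
        n_trees = kwargs.get("n_trees", 100)
        return lambda x, y: fit_random_forest(x, y, n_trees=n_trees, seed=seed)
    raise ValueError(f"unknown learner family: {family!r}")
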