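"""Composite-index oxygen-concentration model with Monte-Carlo cross-validation.

The model estimates near-surface oxygen concentration OC (% by volume) from
three environmental drivers: elevation E (m), air temperature T (degC) and leaf
area index L (dimensionless).  Each driver is Min-Max normalized to [0, 1] and
combined into a single composite index

    Tmp = w_E * N_E + w_T * N_T + w_L * N_L

with fixed relative-contribution weights (defaults -0.3958, 0.3550, 0.2492:
elevation depresses OC, temperature and vegetation raise it).  OC is then a
simple linear function of the index,

    OC = a * Tmp + b,

whose slope/intercept are fitted by repeated random-subsampling
cross-validation: for each candidate training-set size m, many random splits
are drawn, an OLS line is fitted on each training subset and scored by RMSE on
the held-out remainder; the reported coefficients for that m are the averages
across splits, and the most robust m is the one whose held-out RMSE has the
smallest standard deviation.

The published plateau-wide model is ``OC = 1.0283 * Tmp + 20.2509`` (selected
at m = 76 from n = 422 harmonized points).  Those constants are the package
defaults for :class:`LinearModel` and :data:`PLATEAU_WEIGHTS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateBoundsError, DegenerateDataError, ParameterError

__all__ = [
    "ContributionWeights",
    "NormalizationBounds",
    "LinearModel",
    "CVResult",
    "PLATEAU_WEIGHTS",
    "PLATEAU_MODEL",
    "fit_minmax_bounds",
    "normalize",
    "composite_index",
    "predict_oxygen",
    "cross_validate",
    "select_robust_model",
    "CompositeIndexRegressor",
]


@dataclass(frozen=True)
class ContributionWeights:
    """Fixed relative contributions of the three drivers to the index.

    The weight carries the sign: elevation's contribution is negative,
    temperature's and LAI's positive.  For the default values the absolute
    weights sum to 1.
    """

    w_elevation: float = -0.3958
    w_temperature: float = 0.3550
    w_lai: float = 0.2492

    def __post_init__(self) -> None:
        if not (self.w_elevation < 0 < self.w_temperature and self.w_lai > 0):
            raise ValueError("expected w_elevation < 0 and positive temperature/LAI weights")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_elevation, self.w_temperature, self.w_lai])


PLATEAU_WEIGHTS = ContributionWeights()


@dataclass(frozen=True)
class NormalizationBounds:
    """Per-variable Min-Max ranges, in native units (m, degC, dimensionless)."""

    elevation: tuple[float, float]
    temperature: tuple[float, float]
    lai: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("elevation", "temperature", "lai"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise DegenerateBoundsError(f"degenerate bounds for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class LinearModel:
    """OC = slope * Tmp + intercept; defaults are the published coefficients."""

    slope: float = 1.0283
    intercept: float = 20.2509
    r_squared: Optional[float] = None


PLATEAU_MODEL = LinearModel()


@dataclass(frozen=True)
class CVResult:
    """Cross-validation summary for one training-set size m."""

    m: int
    n_reps: int
    mean_slope: float
    mean_intercept: float
    rmse_mean: float
    rmse_std: float

    def to_model(self) -> LinearModel:
        return LinearModel(slope=self.mean_slope, intercept=self.mean_intercept)


def fit_minmax_bounds(
    elevation: Sequence[float],
    temperature: Sequence[float],
    lai: Sequence[float],
) -> NormalizationBounds:
    """Observed min/max of each driver over points where all three are present.

    Raises :class:`DegenerateBoundsError` if any driver is constant (including
    the single-point case).
    """
    cols = [np.asarray(v, dtype=float) for v in (elevation, temperature, lai)]
    if not (cols[0].shape == cols[1].shape == cols[2].shape):
        raise ParameterError("elevation, temperature and lai must have equal length")
    ok = np.isfinite(cols[0]) & np.isfinite(cols[1]) & np.isfinite(cols[2])
    if ok.sum() < 2:
        raise DegenerateBoundsError("need at least 2 complete points for Min-Max bounds")
    ranges = []
    for c in cols:
        v = c[ok]
        ranges.append((float(v.min()), float(v.max())))
    return NormalizationBounds(elevation=ranges[0], temperature=ranges[1], lai=ranges[2])


def normalize(value, bounds: tuple[float, float], clamp: bool = True):
    """Min-Max scale ``value`` to [0, 1] over ``bounds``.

    Out-of-range values (which arise when training-point bounds are applied to
    rasters) are clamped into [0, 1] by default.
    """
    lo, hi = bounds
    if not hi > lo:
        raise DegenerateBoundsError(f"degenerate bounds ({lo}, {hi})")
    scaled = (np.asarray(value, dtype=float) - lo) / (hi - lo)
    if clamp:
        scaled = np.clip(scaled, 0.0, 1.0)
    if np.ndim(value) == 0:
        return float(scaled)
    return scaled


def composite_index(n_elevation, n_temperature, n_lai, weights: ContributionWeights = PLATEAU_WEIGHTS):
    """Weighted sum of the normalized drivers (the index Tmp).

    Accepts scalars or arrays; broadcast elementwise.
    """
    tmp = (
        weights.w_elevation * np.asarray(n_elevation, dtype=float)
        + weights.w_temperature * np.asarray(n_temperature, dtype=float)
        + weights.w_lai * np.asarray(n_lai, dtype=float)
    )
    if np.ndim(tmp) == 0:
        return float(tmp)
    return tmp


def predict_oxygen(tmp, model: LinearModel = PLATEAU_MODEL):
    """Oxygen concentration (%) from the composite index: slope*Tmp + intercept."""
    oc = model.slope * np.asarray(tmp, dtype=float) + model.intercept
    if np.ndim(tmp) == 0:
        return float(oc)
    return oc


def _random_permutations(rng: np.random.Generator, n_reps: int, n: int) -> np.ndarray:
    """n_reps independent uniform permutations of range(n), as rows."""
    return np.argsort(rng.random((n_reps, n)), axis=1)


def cross_validate(
    x: Sequence[float],
    y: Sequence[float],
    m_values: Sequence[int],
    n_reps: int = 50_000,
    seed: Optional[int] = None,
    max_redraws: int = 100,
    chunk: int = 5_000,
) -> list[CVResult]:
    """Repeated random-subsampling cross-validation of the OC ~ Tmp line.

    For each training-set size ``m`` in ``m_values``, draws ``n_reps`` uniform
    without-replacement splits of the (x, y) pairs, fits OLS on the m training
    pairs of each split and computes the RMSE on the held-out remainder; the
    result records the mean slope/intercept and the mean and standard
    deviation (population formula) of the held-out RMSE.

    Reproducible given ``seed``; each m uses a substream derived from
    ``(seed, m)``, so results do not depend on the order of ``m_values``.
    Splits whose training x values are all equal are redrawn (up to
    ``max_redraws`` rounds) before failing with :class:`DegenerateDataError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ParameterError("x and y must have equal length")
    if n < 4:
        raise ParameterError("need at least 4 points for cross-validation")
    if n_reps < 2:
        raise ParameterError("n_reps must be at least 2")
    for m in m_values:
        if not 3 <= m <= n - 1:
            raise ParameterError(f"m={m} outside valid range [3, {n - 1}]")

    results = []
    for m in m_values:
        if seed is None:
            rng = np.random.default_rng()
        else:
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(m,)))
        slopes = np.empty(n_reps)
        intercepts = np.empty(n_reps)
        rmses = np.empty(n_reps)
        done = 0
        while done < n_reps:
            k = min(chunk, n_reps - done)
            perm = _random_permutations(rng, k, n)
            xs, ys = x[perm], y[perm]
            xt = xs[:, :m]
            for _ in range(max_redraws + 1):
                bad = np.ptp(xt, axis=1) == 0.0
                if not bad.any():
                    break
                nb = int(bad.sum())
                perm[bad] = _random_permutations(rng, nb, n)
                xs[bad], ys[bad] = x[perm[bad]], y[perm[bad]]
                xt = xs[:, :m]
            else:
                raise DegenerateDataError(
                    f"training x constant after {max_redraws} redraws (m={m})"
                )
            yt = ys[:, :m]
            mx, my = xt.mean(axis=1), yt.mean(axis=1)
            cov = (xt * yt).mean(axis=1) - mx * my
            var = (xt * xt).mean(axis=1) - mx * mx
            a = cov / var
            b = my - a * mx
            resid = ys[:, m:] - (a[:, None] * xs[:, m:] + b[:, None])
            slopes[done : done + k] = a
            intercepts[done : done + k] = b
            rmses[done : done + k] = np.sqrt((resid * resid).mean(axis=1))
            done += k
        results.append(
            CVResult(
                m=int(m),
                n_reps=int(n_reps),
                mean_slope=float(slopes.mean()),
                mean_intercept=float(intercepts.mean()),
                rmse_mean=float(rmses.mean()),
                rmse_std=float(rmses.std()),  # population formula
            )
        )
    return results


def select_robust_model(results: Sequence[CVResult]) -> tuple[CVResult, LinearModel]:
    """Pick the CV configuration with the smallest held-out RMSE spread.

    Ties are broken by smaller m, then smaller mean RMSE.  Returns the chosen
    summary and the linear model built from its averaged coefficients.
    """
    if not results:
        raise ParameterError("select_robust_model requires at least one CVResult")
    best = min(results, key=lambda r: (r.rmse_std, r.m, r.rmse_mean))
    return best, best.to_model()


class CompositeIndexRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the composite-index OC model.

    ``fit(X, y)`` takes ``X`` of shape (n, 3) with columns (elevation,
    temperature, LAI) in native units and ``y`` the measured oxygen
    concentrations (%).  Fitting computes Min-Max bounds from the training
    data, builds the composite index with the configured contribution
    weights, runs the Monte-Carlo cross-validation over ``m_values`` and keeps
    the most robust averaged line.  ``predict(X)`` applies bounds -> index ->
    line.

    Parameters
    ----------
    weights
        Contribution weights; default the published plateau values.
    m_values
        Training-set sizes to sweep.  ``None`` sweeps the full range
        3..n-2 as in the reference protocol (expensive; pass an explicit
        subset for routine use).
    n_reps
        Random splits per m (reference protocol: 50,000).
    random_state
        Seed for the split generator.
    clamp
        Clamp normalized values into [0, 1] when predicting outside the
        training range.

    Attributes
    ----------
    bounds_ : NormalizationBounds
    cv_results_ : list of CVResult
    best_result_ : CVResult
    model_ : LinearModel
    slope_, intercept_ : float
    r_squared_ : float, in-sample R^2 of OC on the index
    """

    def __init__(
        self,
        weights: ContributionWeights = PLATEAU_WEIGHTS,
        m_values: Optional[Sequence[int]] = None,
        n_reps: int = 50_000,
        random_state: Optional[int] = None,
        clamp: bool = True,
    ):
        self.weights = weights
        self.m_values = m_values
        self.n_reps = n_reps
        self.random_state = random_state
        self.clamp = clamp

    def _index(self, X: np.ndarray, bounds: NormalizationBounds) -> np.ndarray:
        ne = normalize(X[:, 0], bounds.elevation, clamp=self.clamp)
        nt = normalize(X[:, 1], bounds.temperature, clamp=self.clamp)
        nl = normalize(X[:, 2], bounds.lai, clamp=self.clamp)
        return composite_index(ne, nt, nl, self.weights)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ParameterError("X must have shape (n, 3): elevation, temperature, lai")
        if y.shape != (X.shape[0],):
            raise ParameterError("y must be 1-D with one value per row of X")
        n = X.shape[0]
        self.bounds_ = fit_minmax_bounds(X[:, 0], X[:, 1], X[:, 2])
        tmp = self._index(X, self.bounds_)
        m_values = self.m_values if self.m_values is not None else range(3, n - 1)
        self.cv_results_ = cross_validate(
            tmp, y, m_values=list(m_values), n_reps=self.n_reps, seed=self.random_state
        )
        self.best_result_, self.model_ = select_robust_model(self.cv_results_)
        self.slope_ = self.model_.slope
        self.intercept_ = self.model_.intercept
        pred = predict_oxygen(tmp, self.model_)
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        """Composite index values for X under the fitted bounds."""
        X = np.asarray(X, dtype=float)
        return self._index(X, self.bounds_)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return predict_oxygen(self._index(X, self.bounds_), self.model_)
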