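"""Weighted linear-quadratic fitting of ln-survival against cluster dose.

The survival model is the linear-quadratic (LQ) law with no intercept,

    ln S = -α g - β g²,

so S(0) = 1 exactly.  α has units of pg (inverse cluster dose) and β of
pg².  The fit minimizes the weighted residual sum

    χ² = Σ_i w_i (ln S_i + α g_i + β g_i²)²,

with weights w_i = 1/S_i by default (reciprocal of the survival).  The model
is linear in (α, β), so the weighted normal equations are solved in closed
form; there is no iterative optimizer and no local-minimum concern.
Negative fitted β is allowed and reported, not clipped.

``delta_chi2`` compares one combined fit across all particle groups with
independent per-group fits: Δχ² = χ²_combined − Σ_groups χ²_group.  The
per-group model nests the combined one, so Δχ² ≥ 0 up to round-off; Δχ²
near zero means a single LQ curve describes every radiation quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .survival import ClusterDosePoint

__all__ = [
    "LQFitResult",
    "ConfidenceBand",
    "DeltaChi2Result",
    "fit_lq",
    "fit_lq_arrays",
    "weighted_chi2",
    "delta_chi2",
    "confidence_band",
    "lq_weights",
]

WEIGHT_CONVENTIONS = ("reciprocal-survival", "reciprocal-survival-squared")


def lq_weights(survival: np.ndarray, convention: str = "reciprocal-survival") -> np.ndarray:
    """Fit weights from survival values under the configured convention."""
    if convention == "reciprocal-survival":
        return 1.0 / survival
    if convention == "reciprocal-survival-squared":
        return 1.0 / survival**2
    raise ValueError(
        f"unknown weights convention {convention!r}; expected one of {WEIGHT_CONVENTIONS}"
    )


@dataclass(frozen=True)
class LQFitResult:
    """Fitted LQ parameters, covariance and weighted χ²."""

    alpha: float  # pg
    beta: float  # pg²; 0 and frozen for the purely linear model
    covariance: np.ndarray  # 2×2 (or 1×1 for the linear model)
    chi2: float
    n_points: int
    weights_convention: str = "reciprocal-survival"
    model: str = "lq"  # "lq" (α, β) or "linear" (α only)

    @property
    def n_params(self) -> int:
        return 2 if self.model == "lq" else 1

    @property
    def se_alpha(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def se_beta(self) -> float:
        if self.model != "lq":
            return 0.0
        return float(np.sqrt(self.covariance[1, 1]))

    def predict_log_survival(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        return -self.alpha * g - self.beta * g**2

    def predict_survival(self, g: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_log_survival(g))


@dataclass(frozen=True)
class ConfidenceBand:
    """Pointwise ±1 SD survival band from parametric resampling of (α, β)."""

    g_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_samples: int
    seed: int


@dataclass(frozen=True)
class DeltaChi2Result:
    delta_chi2: float
    combined: LQFitResult
    groups: Mapping[str, LQFitResult] = field(default_factory=dict)


def _design(g: np.ndarray, model: str) -> np.ndarray:
    if model == "lq":
        return np.column_stack([-g, -(g**2)])
    if model == "linear":
        return -g[:, None]
    raise ValueError(f"unknown model {model!r}; expected 'lq' or 'linear'")


def fit_lq_arrays(
    g: np.ndarray,
    survival: np.ndarray,
    weights: str = "reciprocal-survival",
    model: str = "lq",
    covariance: str = "hc3",
) -> LQFitResult:
    """Closed-form weighted LQ (or linear) fit on raw arrays.

    The default parameter covariance is the HC3 leverage-corrected sandwich
    estimator.  The 1/S weights are heuristic precision weights, not true
    inverse variances, and they concentrate leverage on the few lowest-
    survival points; the plain scaled normal-equations covariance then
    underestimates parameter uncertainty severely, while HC3 keeps 2·SE
    intervals near their nominal coverage.  ``covariance="scaled"`` selects
    the classical (XᵀWX)⁻¹·χ²/(n−p) form (the ``scipy.optimize.curve_fit``
    convention with ``absolute_sigma=False``).
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(survival, dtype=float)
    if g.shape != s.shape or g.ndim != 1:
        raise ValueError("g and survival must be 1-D arrays of equal length")
    if np.any(s <= 0):
        raise ValueError("survival values must be > 0")
    n_params = 2 if model == "lq" else 1
    if g.size < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} points for a {n_params}-parameter fit, got {g.size}"
        )
    if np.unique(g).size < n_params:
        raise ValueError("design is rank-deficient: too few distinct cluster doses")

    y = np.log(s)
    w = lq_weights(s, weights)
    X = _design(g, model)
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    try:
        params = np.linalg.solve(A, b)
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"normal equations are singular: {err}") from err

    resid = y - X @ params
    chi2 = float(np.sum(w * resid**2))
    dof = g.size - n_params
    if covariance == "scaled":
        scale = chi2 / dof if dof > 0 else 0.0
        cov = A_inv * scale
    elif covariance == "hc3":
        Xw = np.sqrt(w)[:, None] * X
        leverage = np.einsum("ij,jk,ik->i", Xw, A_inv, Xw)
        leverage = np.clip(leverage, 0.0, 1.0 - 1e-12)
        omega = w**2 * resid**2 / (1.0 - leverage) ** 2
        meat = X.T @ (omega[:, None] * X)
        cov = A_inv @ meat @ A_inv
    else:
        raise ValueError(
            f"unknown covariance estimator {covariance!r}; expected 'hc3' or 'scaled'"
        )

    if model == "lq":
        alpha, beta = float(params[0]), float(params[1])
    else:
        alpha, beta = float(params[0]), 0.0
    return LQFitResult(
        alpha=alpha,
        beta=beta,
        covariance=cov,
        chi2=chi2,
        n_points=int(g.size),
        weights_convention=weights,
        model=model,
    )


def _points_to_arrays(points: Sequence[ClusterDosePoint]) -> tuple[np.ndarray, np.ndarray]:
    g = np.array([p.g for p in points], dtype=float)
    s = np.array([p.survival for p in points], dtype=float)
    return g, s


def fit_lq(
    points: Sequence[ClusterDosePoint],
    weights: str = "reciprocal-survival",
    model: str = "lq",
    covariance: str = "hc3",
) -> LQFitResult:
    """Weighted LQ fit of ln S against cluster dose for a set of points."""
    g, s = _points_to_arrays(points)
    return fit_lq_arrays(g, s, weights=weights, model=model, covariance=covariance)


def weighted_chi2(points: Sequence[ClusterDosePoint], fit: LQFitResult) -> float:
    """Σ_i w_i (ln S_i − ln Ŝ_i)² with the fit's weight convention."""
    g, s = _points_to_arrays(points)
    w = lq_weights(s, fit.weights_convention)
    resid = np.log(s) - fit.predict_log_survival(g)
    return float(np.sum(w * resid**2))


def delta_chi2(
    groups: Mapping[str, Sequence[ClusterDosePoint]],
    weights: str = "reciprocal-survival",
) -> DeltaChi2Result:
    """χ² of one combined fit minus the summed χ² of per-group fits.

    Groups are typically per particle type.  Every group must be
    individually fittable (≥ 3 points with distinct g).
    """
    if len(groups) < 1:
        raise ValueError("delta_chi2 requires at least one group")
    unfittable = [name for name, pts in groups.items() if len(pts) < 3]
    if unfittable:
        raise ValueError(
            f"groups with fewer than 3 points cannot be fit: {sorted(unfittable)}"
        )
    group_fits = {name: fit_lq(pts, weights=weights) for name, pts in groups.items()}
    all_points = [p for pts in groups.values() for p in pts]
    combined = fit_lq(all_points, weights=weights)
    delta = combined.chi2 - sum(f.chi2 for f in group_fits.values())
    return DeltaChi2Result(delta_chi2=float(delta), combined=combined, groups=group_fits)


def confidence_band(
    fit: LQFitResult,
    g_grid: np.ndarray,
    n_samples: int = 1000,
    seed: int = 0,
) -> ConfidenceBand:
    """±1 SD survival band from parametric resampling of the fit.

    Draws ``n_samples`` (α, β) pairs from a bivariate normal with the fit
    covariance, evaluates the survival curves on ``g_grid``, and returns the
    sample-mean ± 1 SD envelope, widened where necessary so that the central
    fitted curve is always contained (exp is convex, so the sample mean can
    sit slightly above the central curve).
    """
    g_grid = np.asarray(g_grid, dtype=float)
    cov = np.asarray(fit.covariance, dtype=float)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-12 * max(1.0, abs(eigvals.max())):
        raise ValueError(
            "fit covariance is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3e}); add a small diagonal jitter "
            "to the covariance before resampling"
        )
    rng = np.random.default_rng(seed)
    if fit.model == "lq":
        mean = np.array([fit.alpha, fit.beta])
        samples = rng.multivariate_normal(mean, cov, size=n_samples, method="svd")
        a, b = samples[:, 0], samples[:, 1]
    else:
        a = rng.normal(fit.alpha, np.sqrt(max(cov[0, 0], 0.0)), size=n_samples)
        b = np.zeros_like(a)
    curves = np.exp(-np.outer(a, g_grid) - np.outer(b, g_grid**2))
    mean_c = curves.mean(axis=0)
    sd_c = curves.std(axis=0)
    central = fit.predict_survival(g_grid)
    lower = np.minimum(mean_c - sd_c, central)
    upper = np.maximum(mean_c + sd_c, central)
    return ConfidenceBand(
        g_grid=g_grid, lower=lower, upper=upper, n_samples=int(n_samples), seed=int(seed)
    )
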