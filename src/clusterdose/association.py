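"""Dispersion statistics quantifying survival-vs-cluster-dose association.

Three methods measure how tightly survival points from different particle
types, energies and fluences collapse onto a single curve when plotted
against cluster dose computed with a candidate ionization parameter C_k:

Method 1 — moving window: the mean over sliding windows (sorted by cluster
dose) of the in-window population standard deviation of survival values.
Needs no response model.

Method 2 — LQ residuals: the mean relative residual |S_i − Ŝ_i|/Ŝ_i of the
points from a single weighted LQ fit (survival scale).

Method 3 — BIC: the Bayesian information criterion of the weighted LQ fit
(−2 log-likelihood plus an n_params·ln N complexity penalty), with its
standard error estimated from 100 bootstrap subsamples of 80% of the data.

For each method the preferred I_p is the k minimizing the statistic; ties
within one standard error of the minimum are reported as indistinguishable.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .lq import LQFitResult, fit_lq_arrays
from .survival import ClusterDosePoint

__all__ = [
    "DispersionResult",
    "BICResult",
    "SelectionResult",
    "moving_window",
    "moving_window_variable",
    "lq_residual_dispersion",
    "bic_score",
    "bic_bootstrap",
    "select_preferred_ip",
]


@dataclass(frozen=True)
class DispersionResult:
    """One dispersion statistic with its standard error."""

    method: str  # moving_window | lq_residuals | bic
    statistic: float
    se: float
    n_units: int  # windows / points / bootstrap samples
    settings: Mapping[str, object] = field(default_factory=dict)
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic):
            raise ValueError(f"dispersion statistic is not finite: {self.statistic}")
        if self.se < 0:
            raise ValueError(f"standard error must be >= 0, got {self.se}")

    def with_k(self, k: int) -> "DispersionResult":
        return DispersionResult(
            method=self.method,
            statistic=self.statistic,
            se=self.se,
            n_units=self.n_units,
            settings=self.settings,
            k=int(k),
        )


@dataclass(frozen=True)
class BICResult:
    llh: float  # -2 log-likelihood (or the literal legacy surrogate)
    n_params: int
    sigma_resid: float
    bic: float
    convention: str  # gaussian | paper


@dataclass(frozen=True)
class SelectionResult:
    method: str
    selected_k: int
    within_se: tuple[int, ...]  # every k whose statistic is within 1 SE of the min
    statistics: Mapping[int, float]


def _survivals(points: Sequence[ClusterDosePoint]) -> list[float]:
    return [p.survival for p in points]


def _check_sorted(points: Sequence[ClusterDosePoint]) -> None:
    for a, b in zip(points, points[1:]):
        if b.g < a.g:
            raise ValueError(
                "points must be sorted ascending in cluster dose "
                "(use sort_by_cluster_dose)"
            )


def _window_sd(values: Sequence[float]) -> float:
    """Population SD with fixed left-to-right accumulation order.

    Summation order is part of the contract so that independent
    implementations of the same window agree bit-for-bit.
    """
    n = len(values)
    total = 0.0
    for v in values:
        total += v
    mean = total / n
    ss = 0.0
    for v in values:
        d = v - mean
        ss += d * d
    return math.sqrt(ss / n)


def _mean_and_se(stats: Sequence[float]) -> tuple[float, float]:
    """Mean and SE of a statistic list; population-SD numerator throughout."""
    n = len(stats)
    total = 0.0
    for v in stats:
        total += v
    mean = total / n
    ss = 0.0
    for v in stats:
        d = v - mean
        ss += d * d
    return mean, math.sqrt(ss / n) / math.sqrt(n)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def moving_window(
    points: Sequence[ClusterDosePoint],
    window_fraction: float = 0.01,
    min_window: int = 3,
    centered: bool = False,
) -> DispersionResult:
    """Method 1: mean in-window population SD of survival values.

    The window holds n = max(min_window, round(window_fraction·N)) points
    and slides one point at a time from the lowest-cluster-dose window until
    the highest point has been included, giving N − n + 1 windows.  σ_T is
    the mean of the per-window SDs; SE_T their population SD over √N_windows.

    ``centered=True`` labels each window by its central point instead; the
    window contents and hence the statistic are identical — the option
    exists for plotting dispersion profiles against cluster dose.
    """
    N = len(points)
    if N < min_window:
        raise ValueError(f"need at least {min_window} points, got {N}")
    _check_sorted(points)
    n = max(min_window, _round_half_up(window_fraction * N))
    n = min(n, N)
    s = _survivals(points)
    sigmas = [_window_sd(s[i : i + n]) for i in range(N - n + 1)]
    sigma_t, se_t = _mean_and_se(sigmas)
    return DispersionResult(
        method="moving_window",
        statistic=sigma_t,
        se=se_t,
        n_units=len(sigmas),
        settings={
            "window_fraction": window_fraction,
            "min_window": min_window,
            "window_size": n,
            "centered": centered,
        },
    )


def moving_window_variable(
    points: Sequence[ClusterDosePoint],
    g_fraction: float = 0.05,
) -> DispersionResult:
    """Method 1 with a variable window: neighbours within ±g_fraction·g_i.

    For each point i the window is {j : |g_j − g_i| ≤ g_fraction·g_i}.
    Windows with fewer than two points have no defined SD and are skipped
    (counted in ``settings["n_skipped"]``); if every window is skipped the
    statistic is undefined and an error is raised.  Intended for datasets
    densely and evenly populated along the cluster-dose axis.
    """
    N = len(points)
    if N < 2:
        raise ValueError(f"need at least 2 points, got {N}")
    _check_sorted(points)
    g = [p.g for p in points]
    s = _survivals(points)
    sigmas = []
    skipped = 0
    for i in range(N):
        tol = g_fraction * g[i]
        lo = bisect.bisect_left(g, g[i] - tol)
        hi = bisect.bisect_right(g, g[i] + tol)
        window = s[lo:hi]
        if len(window) < 2:
            skipped += 1
            continue
        sigmas.append(_window_sd(window))
    if not sigmas:
        raise ValueError(
            "every variable window contained fewer than 2 points; "
            "dispersion undefined (dataset too sparse for a "
            f"{g_fraction:.0%} cluster-dose window)"
        )
    sigma_t, se_t = _mean_and_se(sigmas)
    return DispersionResult(
        method="moving_window",
        statistic=sigma_t,
        se=se_t,
        n_units=len(sigmas),
        settings={"g_fraction": g_fraction, "variable": True, "n_skipped": skipped},
    )


def lq_residual_dispersion(
    points: Sequence[ClusterDosePoint], fit: LQFitResult
) -> DispersionResult:
    """Method 2: mean relative residual from the LQ fit, survival scale.

    r_i = |S_i − Ŝ_i| / Ŝ_i with Ŝ the fitted survival; r_T is the mean and
    SE_T the population SD of the r_i over √N.
    """
    g = np.array([p.g for p in points], dtype=float)
    s = np.array([p.survival for p in points], dtype=float)
    s_fit = fit.predict_survival(g)
    if np.any(s_fit <= 0) or not np.all(np.isfinite(s_fit)):
        raise ValueError("fitted survival is zero or non-finite on these points")
    r = np.abs(s - s_fit) / s_fit
    r_t, se_t = _mean_and_se(r.tolist())
    return DispersionResult(
        method="lq_residuals",
        statistic=r_t,
        se=se_t,
        n_units=len(points),
        settings={"weights": fit.weights_convention, "model": fit.model},
    )


def bic_score(
    points: Sequence[ClusterDosePoint],
    model: str = "lq",
    convention: str = "gaussian",
    weights: str = "reciprocal-survival",
) -> BICResult:
    """Method 3: BIC of the weighted fit, BIC = LLH + n_params·ln N.

    Residuals are taken in ln S from the weighted fit; σ is the population
    SD of those residuals.  ``convention="gaussian"`` (default) evaluates the
    standard Gaussian −2 log-likelihood, N ln 2π + 2N ln σ + SSR/σ².  The
    ``"paper"`` convention keeps a literal legacy surrogate, −N ln σ + SSR/σ²,
    preserved only for traceability: with σ estimated from the residuals,
    SSR/σ² ≈ N and the −N ln σ term dominates, so the surrogate *decreases*
    as the fit worsens — it is not a valid −2 log-likelihood and must not be
    used for model selection.
    """
    g = np.array([p.g for p in points], dtype=float)
    s = np.array([p.survival for p in points], dtype=float)
    n_params = 2 if model == "lq" else 1
    if len(points) < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} points for the {model} model, got {len(points)}"
        )
    fit = fit_lq_arrays(g, s, weights=weights, model=model)
    resid = np.log(s) - fit.predict_log_survival(g)
    ssr = float(np.sum(resid**2))
    sigma = float(np.std(resid))  # population SD
    sigma_safe = max(sigma, 1e-150)  # perfect fits: keep log finite
    N = len(points)
    if convention == "gaussian":
        llh = N * math.log(2 * math.pi) + 2 * N * math.log(sigma_safe) + ssr / sigma_safe**2
    elif convention == "paper":
        llh = -N * math.log(sigma_safe) + ssr / sigma_safe**2
    else:
        raise ValueError(f"unknown BIC convention {convention!r}")
    bic = llh + n_params * math.log(N)
    return BICResult(
        llh=llh, n_params=n_params, sigma_resid=sigma, bic=bic, convention=convention
    )


def bic_bootstrap(
    points: Sequence[ClusterDosePoint],
    n_samples: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    model: str = "lq",
    convention: str = "gaussian",
    weights: str = "reciprocal-survival",
) -> DispersionResult:
    """Mean BIC and its SE over seeded 80% subsamples without replacement.

    Each of ``n_samples`` subsamples holds floor(subsample_fraction·N)
    points drawn without replacement; the statistic is the mean of the
    per-sample BICs and the SE their population SD over √n_samples.
    """
    N = len(points)
    n_params = 2 if model == "lq" else 1
    m = int(math.floor(subsample_fraction * N))
    if m < n_params + 1:
        raise ValueError(
            f"subsample of {m} points cannot support a {n_params}-parameter fit"
        )
    rng = np.random.default_rng(seed)
    bics = []
    pts = list(points)
    for _ in range(n_samples):
        idx = rng.choice(N, size=m, replace=False)
        sub = [pts[i] for i in idx]
        bics.append(bic_score(sub, model=model, convention=convention, weights=weights).bic)
    mean_bic, se = _mean_and_se(bics)
    return DispersionResult(
        method="bic",
        statistic=mean_bic,
        se=se,
        n_units=n_samples,
        settings={
            "n_samples": n_samples,
            "subsample_fraction": subsample_fraction,
            "model": model,
            "convention": convention,
            "weights": weights,
            "seed": seed,
        },
    )


def select_preferred_ip(results: Mapping[int, DispersionResult]) -> SelectionResult:
    """Pick the k minimizing the dispersion statistic.

    All entries must come from the same method with identical settings.
    Besides the argmin, every k whose statistic lies within one standard
    error of the minimum is reported: such k are statistically
    indistinguishable from the preferred one at the 1-SD level.
    """
    if len(results) < 2:
        raise ValueError("selection requires results for at least 2 values of k")
    methods = {r.method for r in results.values()}
    if len(methods) > 1:
        raise ValueError(f"mixed methods in selection: {sorted(methods)}")
    # seed is a stream identifier and n_skipped/window_size are per-dataset
    # diagnostics, not method parameters
    derived = {"seed", "n_skipped", "window_size"}
    settings = {
        tuple(sorted((key, repr(v)) for key, v in r.settings.items() if key not in derived))
        for r in results.values()
    }
    if len(settings) > 1:
        raise ValueError("dispersion results were computed with differing settings")
    ks = sorted(results)
    stats = {k: results[k].statistic for k in ks}
    selected = min(ks, key=lambda k: (stats[k], k))
    threshold = stats[selected] + results[selected].se
    within = tuple(k for k in ks if stats[k] <= threshold)
    return SelectionResult(
        method=methods.pop(), selected_k=selected, within_se=within, statistics=stats
    )
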