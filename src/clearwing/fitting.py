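"""Nonlinear least-squares estimation of the two-peaked emergence curve.

Trap catches are transformed to cumulative proportions of the season total,
indexed on cumulative degree-days, and the five free parameters
(alpha1, beta1, gamma1, delta_beta, gamma2; alpha2 = 1 - alpha1 by
substitution) are estimated by least squares.  Validity bounds are enforced
by optimizing in a smooth unconstrained reparameterization (logit for
alpha1, log for the positive scales, log of -gamma1), which keeps the
objective differentiable everywhere rather than relying on penalties or
active-set bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .degree_days import DegreeDaySeries
from .model import TwoPeakWeibullParams, evaluate

__all__ = [
    "TrapCatchSeries",
    "FitResult",
    "to_cumulative_proportions",
    "initial_guess",
    "fit_two_peak_weibull",
]


@dataclass
class TrapCatchSeries:
    """Adult trap counts for one site-year."""

    site: str
    year: int
    dates: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.counts = np.asarray(self.counts)
        if len(self.dates) != len(self.counts):
            raise ValueError("dates and counts length mismatch")
        if len(self.dates) > 1 and not (
            self.dates.is_monotonic_increasing and not self.dates.duplicated().any()
        ):
            raise ValueError(f"trap dates must be strictly increasing ({self.site} {self.year})")
        if np.any(self.counts < 0):
            raise ValueError(f"negative trap count in {self.site} {self.year}")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def site_year(self) -> str:
        return f"{self.site}:{self.year}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site": self.site, "year": self.year, "date": self.dates, "count": self.counts}
        )


@dataclass
class FitResult:
    """Outcome of a two-peaked Weibull fit."""

    params: TwoPeakWeibullParams
    sem: dict[str, float]
    sse: float
    n_obs: int
    f_stat: float                     # corrected convention, df (p-1, n-p)
    f_stats: dict[str, tuple[float, int, int]] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0


def to_cumulative_proportions(
    series: TrapCatchSeries, dd: DegreeDaySeries
) -> pd.DataFrame:
    """Cumulative catch proportion vs CDD for one site-year.

    Zero-catch sampling dates are retained: they pin the cumulative curve.
    Returns a frame with columns cdd, cum_prop, site_year.
    """
    total = series.total
    if total <= 0:
        raise ValueError(f"total catch is zero in {series.site} {series.year}")
    cum = np.cumsum(series.counts) / total
    cdd = np.array([dd.cdd_at(d) for d in series.dates])
    return pd.DataFrame({"cdd": cdd, "cum_prop": cum, "site_year": series.site_year})


def initial_guess(points: pd.DataFrame) -> TwoPeakWeibullParams:
    """Data-driven starting values for the five free parameters.

    alpha1 comes from the longest mid-season plateau of the cumulative
    curve (the flat stretch between the two flight periods); beta1 and
    delta_beta from the CDDs where the curve crosses alpha1/2 and
    (1+alpha1)/2; the shapes start at fixed defaults (gamma1 = -5,
    gamma2 = delta_beta/10).  All values are clamped to validity bounds.
    """
    if len(points) < 10:
        raise ValueError(f"need at least 10 points for an initial guess, got {len(points)}")
    pts = points.sort_values("cdd").reset_index(drop=True)
    cdd = pts["cdd"].to_numpy(dtype=float)
    prop = pts["cum_prop"].to_numpy(dtype=float)

    # the inter-peak lull is the mid-level slope minimum of the cumulative
    # curve: its level estimates alpha1
    grid = np.linspace(cdd.min(), cdd.max(), 201)
    prop_grid = np.interp(grid, cdd, prop)
    slope = np.gradient(prop_grid, grid)
    # damp sampling noise before locating the minimum
    kernel = np.ones(9) / 9.0
    slope = np.convolve(slope, kernel, mode="same")
    mid = (prop_grid >= 0.1) & (prop_grid <= 0.9)
    if mid.any():
        lull = np.flatnonzero(mid)[np.argmin(slope[mid])]
        alpha1 = float(np.clip(prop_grid[lull], 0.05, 0.95))
    else:
        alpha1 = 0.5

    def first_crossing(level: float, fallback: float) -> float:
        above = np.flatnonzero(prop >= level)
        return float(cdd[above[0]]) if len(above) else fallback

    beta1 = first_crossing(alpha1 / 2.0, float(np.quantile(cdd, 0.25)))
    beta2 = first_crossing((1.0 + alpha1) / 2.0, float(np.quantile(cdd, 0.75)))
    beta1 = max(beta1, 1.0)
    delta_beta = max(beta2 - beta1, 1.0)
    return TwoPeakWeibullParams(
        alpha1=alpha1, beta1=beta1, gamma1=-5.0,
        delta_beta=delta_beta, gamma2=max(delta_beta / 10.0, 1.0),
    )


def _pack(p: TwoPeakWeibullParams) -> np.ndarray:
    return np.array([
        logit(p.alpha1), np.log(p.beta1), np.log(-p.gamma1),
        np.log(p.delta_beta), np.log(p.gamma2),
    ])


def _unpack(x: np.ndarray) -> TwoPeakWeibullParams:
    return TwoPeakWeibullParams(
        alpha1=float(np.clip(expit(x[0]), 1e-12, 1 - 1e-12)),
        beta1=float(np.exp(x[1])),
        gamma1=-float(np.exp(x[2])),
        delta_beta=float(np.exp(x[3])),
        gamma2=float(np.exp(x[4])),
    )


_PARAM_NAMES = ("alpha1", "beta1", "gamma1", "delta_beta", "gamma2")


def _sem_from_jacobian(
    params: TwoPeakWeibullParams, cdd: np.ndarray, resid: np.ndarray
) -> dict[str, float]:
    """Standard errors from a finite-difference Jacobian in natural units,
    scaled by the residual mean square."""
    n, p = len(cdd), len(_PARAM_NAMES)
    if n <= p:
        return {k: float("nan") for k in _PARAM_NAMES}
    jac = np.empty((n, p))
    base = params.as_dict()
    for j, name in enumerate(_PARAM_NAMES):
        h = 1e-6 * max(abs(base[name]), 1e-3)
        up, dn = dict(base), dict(base)
        up[name] += h
        dn[name] -= h
        jac[:, j] = (
            evaluate(TwoPeakWeibullParams(**up), cdd)
            - evaluate(TwoPeakWeibullParams(**dn), cdd)
        ) / (2 * h)
    mse = float(resid @ resid) / (n - p)
    try:
        cov = mse * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(_PARAM_NAMES, (float(s) for s in se)))


def fit_two_peak_weibull(
    points: pd.DataFrame,
    init: TwoPeakWeibullParams | None = None,
    weights: pd.Series | None = None,
) -> FitResult:
    """Fit the five free parameters to pooled (cdd, cum_prop) observations.

    All site-years enter one regression with equal per-observation weight
    (pass `weights` indexed like `points` to override).  Non-convergence is
    reported via the `converged` flag, never an exception.

    The model F statistic is reported under both degrees-of-freedom
    conventions, (p-1, n-p) on the mean-corrected regression sum of squares
    and (p, n-p) on the uncorrected one, since software differs in which it
    prints for a nonlinear fit.
    """
    cdd = points["cdd"].to_numpy(dtype=float)
    y = points["cum_prop"].to_numpy(dtype=float)
    order = np.argsort(cdd, kind="stable")
    cdd, y = cdd[order], y[order]
    w = np.ones_like(y)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[order])

    if init is None:
        init = initial_guess(points)

    def residuals(x: np.ndarray) -> np.ndarray:
        return w * (evaluate(_unpack(x), cdd) - y)

    res = least_squares(
        residuals, _pack(init), method="trf",
        ftol=1e-12, xtol=1e-12, gtol=1e-10, max_nfev=500 * 6,
    )
    params = _unpack(res.x)
    resid = residuals(res.x)
    sse = float(resid @ resid)
    n, p = len(y), 5

    sst_corr = float(np.sum((y - y.mean()) ** 2))
    ssr_corr = max(sst_corr - sse, 0.0)
    ssr_uncorr = max(float(np.sum(y**2)) - sse, 0.0)
    mse = sse / (n - p) if n > p else float("nan")
    f_corr = (ssr_corr / (p - 1)) / mse if n > p and mse > 0 else float("nan")
    f_uncorr = (ssr_uncorr / p) / mse if n > p and mse > 0 else float("nan")

    return FitResult(
        params=params,
        sem=_sem_from_jacobian(params, cdd, resid),
        sse=sse,
        n_obs=n,
        f_stat=f_corr,
        f_stats={
            "corrected (p-1, n-p)": (f_corr, p - 1, n - p),
            "uncorrected (p, n-p)": (f_uncorr, p, n - p),
        },
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
    )
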