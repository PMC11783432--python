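"""Independent numerical oracles used to cross-check the implementation.

These deliberately avoid the closed forms under test: degree-days come from
brute-force quadrature of the truncated sine wave, and within-peak
percentile CDDs from bisection on the isolated mixture component.
"""

import numpy as np

from clearwing.model import evaluate_component


def quadrature_dd(tmin, tmax, ldt, n=50_001):
    """Mean daily excess of a full sine wave above `ldt` by trapezoid rule."""
    t = np.linspace(0.0, 2 * np.pi, n)
    tm = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    excess = np.maximum(tm + amp * np.sin(t) - ldt, 0.0)
    return np.trapezoid(excess, t) / (2 * np.pi)


def quadrature_dd_batch(tmin, tmax, ldt, n=50_001, chunk=200):
    """Vectorized quadrature oracle over arrays of (tmin, tmax, ldt)."""
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    ldt = np.asarray(ldt, float)
    t = np.linspace(0.0, 2 * np.pi, n)
    out = np.empty(len(tmin))
    for i in range(0, len(tmin), chunk):
        sl = slice(i, i + chunk)
        tm = ((tmax[sl] + tmin[sl]) / 2.0)[:, None]
        amp = ((tmax[sl] - tmin[sl]) / 2.0)[:, None]
        excess = np.maximum(tm + amp * np.sin(t)[None, :] - ldt[sl][:, None], 0.0)
        out[sl] = np.trapezoid(excess, t, axis=1) / (2 * np.pi)
    return out


def bisect_within_peak(params, peak, p, tol=1e-9):
    """CDD where the isolated component reaches p * alpha_peak, by bisection."""
    alpha = params.alpha1 if peak == 1 else params.alpha2
    target = p * alpha
    lo, hi = 0.0, params.beta1 + params.delta_beta
    while evaluate_component(params, peak, hi) < target:
        hi *= 2.0
    while hi - lo > tol / 4.0:
        mid = 0.5 * (lo + hi)
        if evaluate_component(params, peak, mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
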