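"""Exponential fits to cumulative-information curves.

The model is a delayed saturating exponential

    CI_mod(t) = k * I_max * (1 - exp(-(t - dt) / tau)),   t > dt (0 before),

with saturation fraction ``k`` in [0, 1] of the maximum achievable
information ``I_max`` (log2 of the number of stimuli or categories), time
constant ``tau`` (ms) and latency ``dt`` (ms).  The value of the fitted
model at 300 ms relative to ``I_max`` is the summary constant ``k300``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .data import InfoSeries

__all__ = ["ExpFit", "fit_exponential", "k_at"]


@dataclass
class ExpFit:
    k: float
    tau: float
    dt: float
    i_max: float
    mse: float
    k300: float
    converged: bool = True


def _model(t, k, tau, dt, i_max):
    out = k * i_max * (1.0 - np.exp(-np.maximum(t - dt, 0.0) / tau))
    return np.where(t > dt, out, 0.0)


def k_at(fit: ExpFit, t_ms: float = 300.0) -> float:
    """Model value at ``t_ms`` relative to ``i_max`` (0 before the latency)."""
    if t_ms <= fit.dt:
        return 0.0
    return float(fit.k * (1.0 - np.exp(-(t_ms - fit.dt) / fit.tau)))


def fit_exponential(series: InfoSeries, i_max: float) -> ExpFit:
    """Bounded multi-start least squares for (k, tau, dt).

    Uses the defined (finite) bins of *series*; needs at least five.  The
    best of a 3 x 3 x 3 grid of starts is returned together with the mean
    squared error of the fit.
    """
    t = series.times_ms()
    y = series.info
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 5:
        raise ValueError("need at least 5 defined bins to fit 3 parameters")
    window = float(t.max())

    bounds = ([0.0, 1e-6, 0.0], [1.0, 10.0 * window, window])
    starts = [
        (k0, tau0, dt0)
        for k0 in (0.2, 0.5, 0.9)
        for tau0 in (window / 10.0, window / 3.0, window)
        for dt0 in (0.0, window / 10.0, window / 4.0)
    ]
    best = None
    converged = False
    for x0 in starts:
        try:
            res = least_squares(
                lambda x: _model(t, x[0], x[1], x[2], i_max) - y,
                x0=np.asarray(x0),
                bounds=bounds,
                method="trf",
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
            converged = converged or res.success
    if best is None:
        raise RuntimeError("exponential fit failed from every start")
    k, tau, dt = best.x
    mse = float(np.mean((_model(t, k, tau, dt, i_max) - y) ** 2))
    fit = ExpFit(k=float(k), tau=float(tau), dt=float(dt), i_max=float(i_max), mse=mse, k300=0.0, converged=bool(converged))
    fit.k300 = k_at(fit, 300.0)
    return fit
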