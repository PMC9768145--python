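"""Shared nonlinear fitting helpers (saturating-exponential kinetics).

Both the damage-accumulation curves and the lattice-strain relaxation
series follow first-order kinetics toward a plateau,

    y(t) = y0 + (plateau - y0) * (1 - exp(-k t)),

anchored at the known initial value y0 (100 % relative damage, or 0 %
strain).  Fits run through lmfit with a documented multi-start ladder on
the rate constant; non-convergence raises :class:`FitError` carrying the
diagnostics of every attempt.
"""

from __future__ import annotations

import numpy as np
import lmfit


class FitError(RuntimeError):
    """Nonlinear fit failed after all restarts; carries attempt diagnostics."""

    def __init__(self, message: str, attempts=None):
        super().__init__(message)
        self.attempts = attempts or []


_RESTART_FACTORS = (1.0, 0.3, 3.0, 0.1, 10.0)


def _satexp(t, k, plateau, y0):
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def _initial_rate(t, y, y0) -> float:
    """Crude rate guess from the time at which half the total rise occurs."""
    rise = y[-1] - y0
    if abs(rise) < 1e-12:
        return 1.0 / max(t[-1], 1.0)
    frac = np.clip((y - y0) / rise, 1e-6, None)
    half = np.argmax(frac >= 0.5)
    t_half = t[half] if t[half] > 0 else t[-1] / 4.0
    return np.log(2.0) / t_half


def fit_saturating_exponential(t, y, y0: float, weights=None):
    """Fit y(t) = y0 + (plateau - y0)(1 - e^{-kt}); returns an lmfit result.

    Returns
    -------
    lmfit.model.ModelResult with parameters ``k`` and ``plateau``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if t.size != y.size:
        raise ValueError("times and values differ in length")

    model = lmfit.Model(_satexp, independent_vars=["t"])
    k0 = _initial_rate(t, y, y0)
    attempts = []
    best = None
    for factor in _RESTART_FACTORS:
        params = model.make_params(
            k=dict(value=k0 * factor, min=0.0),
            plateau=dict(value=float(y[-1])),
            y0=dict(value=y0, vary=False),
        )
        try:
            res = model.fit(y, params, t=t, weights=weights)
        except Exception as exc:  # keep trying other starts
            attempts.append((factor, repr(exc)))
            continue
        attempts.append((factor, f"success={res.success} redchi={res.redchi:.4g}"))
        if res.success and (best is None or res.redchi < best.redchi):
            best = res
    if best is None:
        raise FitError(
            "saturating-exponential fit did not converge from any restart",
            attempts,
        )
    return best
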