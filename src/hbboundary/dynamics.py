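"""Master-equation propagation of the promoter state distribution.

During mitosis the TF leaves the nuclei, so at the start of each
interphase every operator site is free.  Propagating
``dp/dt = Q^T p`` from the all-free state gives the mean activation
probability ``mu_P(t, X)`` and tells whether the steady-state boundary
can form within the interphase window ``T_full``.

The state spaces here are small (at most 49 states), so the propagator
is computed by matrix exponentials, which are robust to the many-decade
stiffness of randomized rate sets; an implicit BDF integration with the
generator as the analytic Jacobian is kept as a fallback for larger
spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .models import PromoterModel, build_generator
from .units import Position

__all__ = ["ActivityTrace", "propagate", "mu_end", "NC_WINDOWS"]

#: Interphase transcription windows per nuclear cycle, seconds.
#: ``T_full`` is the full interphase transcription window; ``T`` the
#: steady-state expression window (the pattern stabilizes about 2-3
#: minutes after mitosis, here 150 s).  nc11 and nc13 are measured
#: values; nc12 is a figure-level interpolation.
NC_WINDOWS: dict[str, dict[str, float]] = {
    "nc11": {"T_full": 270.0, "T": 120.0},
    "nc12": {"T_full": 400.0, "T": 250.0},
    "nc13": {"T_full": 520.0, "T": 370.0},
}

_EXPM_MAX_STATES = 64


@dataclass(frozen=True)
class ActivityTrace:
    """Mean activation probability ``mu_P(t, X)`` along a time grid."""

    times: np.ndarray
    mu: np.ndarray
    x: Position

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))


def _all_free_index(model: PromoterModel) -> int:
    # state 0 is all-free in every architecture's state ordering
    return 0


def _stochastic_propagator(qt: np.ndarray, dt: float) -> np.ndarray | None:
    """``expm(Q^T dt)`` by scaling and squaring of the stochastic matrix.

    ``expm`` overflows internally when ``||Q|| dt`` spans many decades;
    squaring the (column-)stochastic short-time propagator instead is
    stable because every intermediate has entries in [0, 1].
    """
    norm = np.max(np.abs(np.diag(qt)))
    if norm == 0.0 or not np.isfinite(norm):
        return np.eye(qt.shape[0]) if norm == 0.0 else None
    k = max(0, int(math.ceil(math.log2(norm * dt))))
    with np.errstate(over="ignore", invalid="ignore"):
        prop = expm(qt * (dt / 2.0**k))
        if not np.all(np.isfinite(prop)):
            return None
        for _ in range(k):
            prop = prop @ prop
            # keep the propagator exactly stochastic against roundoff
            prop = np.clip(prop, 0.0, None)
            prop /= prop.sum(axis=0, keepdims=True)
    return prop


def _propagate_expm(q: np.ndarray, p0: np.ndarray, t_grid: np.ndarray):
    """Step the exact propagator along the grid; None on failure."""
    probs = np.empty((len(t_grid), len(p0)))
    probs[0] = p0
    qt = q.T
    cache: dict[float, np.ndarray] = {}
    p = p0
    for i, dt in enumerate(np.diff(t_grid)):
        prop = cache.get(dt)
        if prop is None:
            prop = _stochastic_propagator(qt, dt)
            if prop is None:
                return None
            cache[dt] = prop
        p = prop @ p
        if not np.all(np.isfinite(p)):
            return None
        p = np.clip(p, 0.0, None)
        p = p / p.sum()
        probs[i + 1] = p
    return probs


def propagate(
    model: PromoterModel,
    x: Position | float,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
) -> ActivityTrace:
    """Propagate from the all-free state and record the active mass.

    ``t_grid`` must be increasing and start at 0.  For state spaces up
    to 64 the exact propagator ``expm(Q^T dt)`` is stepped along the
    grid; larger systems fall back to stiff BDF integration with the
    generator as Jacobian.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")
    q = build_generator(model, x)
    n = q.shape[0]
    p0 = np.zeros(n)
    p0[_all_free_index(model)] = 1.0
    a = model.active_indicator()

    probs = None
    if n <= _EXPM_MAX_STATES:
        probs = _propagate_expm(q, p0, t_grid)
    if probs is None:
        # matrix exponentials overflow for rate sets spanning extreme
        # decades; implicit BDF with the generator as Jacobian copes
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(
                lambda t, p: q.T @ p,
                (0.0, t_grid[-1]),
                p0,
                t_eval=t_grid,
                method="BDF",
                jac=lambda t, p: q.T,
                rtol=max(rtol, 1e-10),
                atol=1e-12,
            )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(
                "stiff propagation failed; rate magnitudes: "
                f"[{np.abs(q[q != 0]).min():.2e}, {np.abs(q).max():.2e}]"
            )
        probs = sol.y.T
        sums = probs.sum(axis=1, keepdims=True)
        probs = np.clip(probs, 0.0, None) / np.where(sums > 0, sums, 1.0)

    mu = probs @ a
    return ActivityTrace(times=t_grid, mu=np.clip(mu, 0.0, 1.0), x=Position(float(x)))


def mu_end(model: PromoterModel, x: Position | float, t_full: float) -> float:
    """``mu_P(T_full, x)``: active probability at the end of the window.

    A value below 0.5 at the mid-boundary means the steady-state
    boundary could not form within the interphase.
    """
    if t_full <= 0:
        raise ValueError("t_full must be positive")
    trace = propagate(model, x, np.array([0.0, t_full]))
    return float(trace.mu[-1])
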