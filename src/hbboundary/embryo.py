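"""Synthetic MS2-MCP-like embryo datasets and their boundary analysis.

The live-imaging readout this emulates is, per nucleus, a time-averaged
transcription intensity at a known AP position, for several embryos per
nuclear cycle (8 in nc12, 4 in nc13).  Each synthetic embryo draws its
nucleus readouts by exact simulation of a promoter model at the
nucleus's position, scales them to arbitrary fluorescence units,
applies multiplicative lognormal measurement noise, and shifts its
boundary by an embryo-specific offset — the three features the
experimental analysis has to cope with.

The analysis pipeline mirrors the experimental one: embryos are
aligned at the half-max point of their expression profile, the aligned
nuclei are binned and the Hill steepness fitted (statsmodels-style:
:class:`HillBoundaryModel` ... ``.fit()`` -> results object with
``summary()`` and bootstrap confidence intervals), and the empirical
positional resolution and strip CV are read from binned readouts.

What this generator does *not* emulate: polymerase traffic noise,
mRNA accumulation kinetics, imaging calibration drift, or nucleus
segmentation errors; readouts are abstract normalized intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .models import PromoterModel
from .readout import sample_readouts
from .resolution import ResolutionResult, false_positive_prob
from .units import EL_BOUNDARY, LAMBDA_EL, dist_el_to_ln

__all__ = [
    "SyntheticEmbryo",
    "NC_EMBRYO_CONFIG",
    "generate_embryos",
    "align_embryos",
    "HillBoundaryModel",
    "HillBoundaryResults",
    "fit_hill",
    "empirical_delta_x",
    "strip_cv",
    "embryos_to_frame",
]

#: Per-cycle defaults: number of movies and steady-state window (s).
NC_EMBRYO_CONFIG = {
    "nc12": {"n_embryos": 8, "T": 250.0},
    "nc13": {"n_embryos": 4, "T": 370.0},
}

_MAX_HILL = 64.0


@dataclass(frozen=True)
class SyntheticEmbryo:
    """One embryo's nuclei: AP positions and fluorescence readouts."""

    embryo_id: int
    nc: str
    x_el: np.ndarray
    readout: np.ndarray
    boundary_offset: float
    noise_cv: float
    seed: int
    x_el_aligned: np.ndarray | None = None

    def __post_init__(self):
        x = np.asarray(self.x_el, dtype=float)
        r = np.asarray(self.readout, dtype=float)
        if np.any(x < -50) or np.any(x > 50):
            raise ValueError("positions must lie within [-50, 50] % EL")
        if np.any(r < 0):
            raise ValueError("readouts must be nonnegative")
        object.__setattr__(self, "x_el", x)
        object.__setattr__(self, "readout", r)

    @property
    def positions(self) -> np.ndarray:
        """Aligned positions when available, raw otherwise."""
        return self.x_el if self.x_el_aligned is None else self.x_el_aligned


def generate_embryos(
    model: PromoterModel,
    nc: str = "nc13",
    n_embryos: int | None = None,
    nuclei_per_row: int = 50,
    n_rows: int = 6,
    offset_sd: float = 2.0,
    noise_cv: float = 0.2,
    fluorescence_scale: float = 1000.0,
    M: int = 1,
    T: float | None = None,
    seed: int | None = None,
) -> list[SyntheticEmbryo]:
    """Draw synthetic embryos from a calibrated promoter model.

    Each embryo carries ``n_rows`` AP rows of nuclei on an even grid
    (a live movie images a patch of the blastoderm surface, many nuclei
    per AP position); each nucleus readout is an exact-SSA time average
    of promoter activity over the cycle's steady-state window at the
    nucleus position (shifted by the embryo's boundary offset,
    Normal(0, ``offset_sd`` % EL)), times M gene copies, scaled to
    fluorescence units and perturbed by mean-one lognormal noise of
    coefficient of variation ``noise_cv``.
    """
    if nc not in NC_EMBRYO_CONFIG:
        raise ValueError(f"unknown nuclear cycle {nc!r}; use one of {list(NC_EMBRYO_CONFIG)}")
    cfg = NC_EMBRYO_CONFIG[nc]
    n_embryos = cfg["n_embryos"] if n_embryos is None else n_embryos
    T = cfg["T"] if T is None else T
    if n_embryos < 0:
        raise ValueError("n_embryos must be nonnegative")
    rng = np.random.default_rng(seed)
    x_grid = np.tile(np.linspace(-49.0, 49.0, nuclei_per_row), n_rows)
    n_nuclei = len(x_grid)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    embryos = []
    for e in range(n_embryos):
        offset = rng.normal(0.0, offset_sd) if offset_sd > 0 else 0.0
        vals = np.empty(n_nuclei)
        for i, x_el in enumerate(x_grid[:nuclei_per_row]):
            x_ln = (EL_BOUNDARY + offset - x_el) / LAMBDA_EL
            s = sample_readouts(model, x_ln, T, n_runs=n_rows, M=M, rng=rng)
            vals[i::nuclei_per_row] = s.values
        noise = rng.lognormal(-0.5 * sigma**2, sigma, n_nuclei) if sigma > 0 else 1.0
        embryos.append(
            SyntheticEmbryo(
                embryo_id=e,
                nc=nc,
                x_el=x_grid.copy(),
                readout=vals * fluorescence_scale * noise,
                boundary_offset=float(offset),
                noise_cv=noise_cv,
                seed=-1 if seed is None else int(seed),
            )
        )
    return embryos


def _binned_means(x, y, bin_width):
    # bins anchored to the data so that binning (and everything built
    # on it, e.g. boundary alignment) is translation-equivariant
    lo = x.min()
    edges = np.arange(lo, x.max() + bin_width, bin_width)
    idx = np.digitize(x, edges)
    centers, means = [], []
    for b in np.unique(idx):
        m = idx == b
        centers.append(x[m].mean())
        means.append(y[m].mean())
    return np.asarray(centers), np.asarray(means)


def _half_max_position(x_el, readout, bin_width=2.5):
    """AP position where the smoothed profile crosses half its
    anterior plateau.

    The profile is a moving average over rank-ordered nuclei (window
    sized to span roughly ``bin_width`` % EL), which makes the
    estimate exactly translation-equivariant — aligning already
    aligned embryos is a no-op."""
    order = np.argsort(x_el, kind="stable")
    xs, ys = np.asarray(x_el)[order], np.asarray(readout)[order]
    n = len(xs)
    span = xs[-1] - xs[0]
    w = int(max(3, round(n * bin_width / span))) if span > 0 else n
    w = min(w, n)
    # boxcar with shrinking edge windows (zero-padding would bias the
    # anterior plateau low and shift every alignment posteriorly)
    hw = w // 2
    css = np.concatenate([[0.0], np.cumsum(ys)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - hw)
    hi = np.minimum(n, idx + hw + 1)
    sm = (css[hi] - css[lo]) / (hi - lo)
    plateau = sm[:w].mean()
    half = plateau / 2.0
    below = np.flatnonzero(sm < half)
    above = np.flatnonzero(sm >= half)
    if len(below) == 0 or len(above) == 0:
        raise ValueError("no half-max crossing: degenerate (flat) expression profile")
    j = below[below > above[0]]
    if len(j) == 0:
        raise ValueError("no half-max crossing: profile never drops below half plateau")
    j = j[0]
    x0, x1 = xs[j - 1], xs[j]
    y0, y1 = sm[j - 1], sm[j]
    if y0 == y1:
        return float(x0)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def align_embryos(embryos, bin_width: float = 2.5) -> list[SyntheticEmbryo]:
    """Recenter each embryo at its half-max expression point.

    The detected crossing is mapped to the canonical boundary position
    (-5% EL, X = 0).  Already-aligned embryos are re-aligned from their
    aligned coordinates, making the operation idempotent up to binning
    error.
    """
    out = []
    for e in embryos:
        x = e.positions
        x_half = _half_max_position(x, e.readout, bin_width)
        out.append(replace(e, x_el_aligned=x - (x_half - EL_BOUNDARY)))
    return out


# ---------------------------------------------------------------------------
# Hill boundary fit


def _hill_curve(tf, amplitude, h, tf0):
    return amplitude * tf**h / (tf0**h + tf**h)


@dataclass(frozen=True)
class HillBoundaryResults:
    """Fitted boundary steepness with embryo-level uncertainty.

    ``params`` holds (amplitude, H, TF0).  ``conf_int`` rows follow the
    same order: 95% intervals from a leave-one-embryo-out jackknife
    t-interval (default; robust with the handful of embryos a cycle
    provides) or a percentile bootstrap over embryos.  ``diverged``
    flags fits pinned at the steepness bound (step-like data whose Hill
    coefficient is not identified).
    """

    params: np.ndarray
    conf_int_: np.ndarray
    ci_method: str
    n_reps: int
    n_embryos: int
    diverged: bool

    @property
    def amplitude(self) -> float:
        return float(self.params[0])

    @property
    def hill(self) -> float:
        return float(self.params[1])

    @property
    def tf0(self) -> float:
        return float(self.params[2])

    @property
    def boundary_el(self) -> float:
        """AP position of half-max expression implied by TF0."""
        return EL_BOUNDARY - LAMBDA_EL * math.log(self.tf0)

    def conf_int(self) -> np.ndarray:
        return self.conf_int_

    def summary(self) -> str:
        lines = [
            "Hill boundary fit",
            "=" * 46,
            f"{'':14s}{'estimate':>10s}{'ci low':>10s}{'ci high':>10s}",
        ]
        names = ["amplitude", "H", "TF0"]
        for name, est, (lo, hi) in zip(names, self.params, self.conf_int_):
            lines.append(f"{name:14s}{est:10.4g}{lo:10.4g}{hi:10.4g}")
        lines.append(f"boundary      {self.boundary_el:10.3f} % EL")
        lines.append(f"embryos: {self.n_embryos}   ci: {self.ci_method} ({self.n_reps} reps)")
        if self.diverged:
            lines.append("WARNING: steepness pinned at bound (step-like data)")
        return "\n".join(lines)


class HillBoundaryModel:
    """Hill fit of the mean expression boundary, ``<f_P>`` vs [TF].

    Aligned nuclei are pooled across embryos, binned along the AP axis,
    positions converted to relative TF concentration through the
    exponential gradient, and the bin means fitted with
    ``f = A [TF]^H / (TF0^H + [TF]^H)`` by least squares.  ``fit()``
    returns a :class:`HillBoundaryResults`; uncertainty comes from a
    bootstrap over embryos.
    """

    def __init__(self, x_el, readout, embryo_ids, bin_width: float = 2.5):
        self.x_el = np.asarray(x_el, dtype=float)
        self.readout = np.asarray(readout, dtype=float)
        self.embryo_ids = np.asarray(embryo_ids)
        self.bin_width = float(bin_width)
        if not (len(self.x_el) == len(self.readout) == len(self.embryo_ids)):
            raise ValueError("x_el, readout and embryo_ids must have equal length")

    @classmethod
    def from_embryos(cls, embryos, bin_width: float = 2.5) -> "HillBoundaryModel":
        x = np.concatenate([e.positions for e in embryos])
        y = np.concatenate([e.readout for e in embryos])
        ids = np.concatenate([np.full(len(e.x_el), e.embryo_id) for e in embryos])
        return cls(x, y, ids, bin_width=bin_width)

    def _fit_once(self, mask) -> np.ndarray:
        x, y = self.x_el[mask], self.readout[mask]
        centers, means = _binned_means(x, y, self.bin_width)
        if len(centers) < 4:
            raise ValueError("fewer than 4 informative bins: cannot fit the boundary")
        tf = np.exp((EL_BOUNDARY - centers) / LAMBDA_EL)
        amp0 = max(means.max(), 1e-12)
        p0 = (amp0, 4.0, 1.0)
        popt, _ = curve_fit(
            _hill_curve,
            tf,
            means,
            p0=p0,
            bounds=([1e-12, 0.1, 1e-6], [np.inf, _MAX_HILL, 1e6]),
            maxfev=20000,
        )
        return popt

    def fit(
        self,
        ci_method: str = "jackknife",
        n_boot: int = 200,
        seed: int | None = 0,
    ) -> HillBoundaryResults:
        """Fit the boundary; 95% CIs over embryos.

        ``ci_method='jackknife'`` (default) uses leave-one-embryo-out
        estimates with a t(n_embryos - 1) interval — with the 4-8
        embryos of one nuclear cycle this has close-to-nominal
        coverage, where the percentile bootstrap runs anti-
        conservative.  ``ci_method='bootstrap'`` gives the percentile
        interval over ``n_boot`` embryo resamples.
        """
        from scipy import stats as _stats

        all_mask = np.ones(len(self.x_el), dtype=bool)
        params = self._fit_once(all_mask)
        ids = np.unique(self.embryo_ids)
        if ci_method == "jackknife":
            if len(ids) < 2:
                ci = np.column_stack([params, params])
                n_reps = 0
            else:
                thetas = []
                for leave in ids:
                    try:
                        thetas.append(self._fit_once(self.embryo_ids != leave))
                    except (ValueError, RuntimeError):
                        continue
                thetas = np.asarray(thetas)
                nn = len(thetas)
                se = np.sqrt((nn - 1) / nn * np.sum((thetas - thetas.mean(0)) ** 2, axis=0))
                tcrit = _stats.t.ppf(0.975, nn - 1)
                ci = np.column_stack([params - tcrit * se, params + tcrit * se])
                n_reps = nn
        elif ci_method == "bootstrap":
            rng = np.random.default_rng(seed)
            boots = []
            for _ in range(n_boot):
                chosen = rng.choice(ids, size=len(ids), replace=True)
                mask_idx = np.concatenate(
                    [np.flatnonzero(self.embryo_ids == c) for c in chosen]
                )
                m = np.zeros(len(self.x_el), dtype=bool)
                m[mask_idx] = True
                try:
                    boots.append(self._fit_once(m))
                except (ValueError, RuntimeError):
                    continue
            if boots:
                ci = np.percentile(np.asarray(boots), [2.5, 97.5], axis=0).T
            else:
                ci = np.column_stack([params, params])
            n_reps = len(boots)
        else:
            raise ValueError("ci_method must be 'jackknife' or 'bootstrap'")
        diverged = bool(params[1] >= 0.98 * _MAX_HILL)
        return HillBoundaryResults(
            params=params,
            conf_int_=ci,
            ci_method=ci_method,
            n_reps=n_reps,
            n_embryos=len(ids),
            diverged=diverged,
        )


def fit_hill(
    embryos,
    bin_width: float = 2.5,
    ci_method: str = "jackknife",
    n_boot: int = 200,
    seed: int | None = 0,
):
    """Convenience wrapper: Hill boundary fit from aligned embryos."""
    return HillBoundaryModel.from_embryos(embryos, bin_width=bin_width).fit(
        ci_method=ci_method, n_boot=n_boot, seed=seed
    )


# ---------------------------------------------------------------------------
# Empirical resolution and strip error


def empirical_delta_x(
    embryos,
    bin_width: float = 5.0,
    alpha: float = 0.05,
    max_sep_el: float = 40.0,
) -> ResolutionResult:
    """Positional resolution from binned nucleus readouts.

    ``F_+`` / ``F_-`` pool the readouts of all nuclei within
    ``bin_width`` % EL bins centered at ``+/- DeltaW / 2`` around the
    aligned boundary; the smallest ``DeltaW`` (stepped by the bin
    width) with ``P(F_+ <= F_-) <= alpha`` is reported.
    """
    x = np.concatenate([e.positions for e in embryos]) - EL_BOUNDARY
    y = np.concatenate([e.readout for e in embryos])
    probed = []
    result_ln = math.inf
    for dw in np.arange(bin_width, max_sep_el + 1e-9, bin_width):
        lo_p, hi_p = -dw / 2 - bin_width / 2, -dw / 2 + bin_width / 2
        lo_a, hi_a = dw / 2 - bin_width / 2, dw / 2 + bin_width / 2
        # anterior (high TF) nuclei sit at negative % EL
        f_plus = y[(x >= lo_p) & (x < hi_p)]
        f_minus = y[(x >= lo_a) & (x < hi_a)]
        if len(f_plus) == 0 or len(f_minus) == 0:
            continue
        p_hat = false_positive_prob(f_plus, f_minus)
        probed.append((float(dw), p_hat))
        if p_hat <= alpha:
            result_ln = dist_el_to_ln(dw)
            break
    return ResolutionResult(
        delta_x_ln=result_ln,
        alpha=alpha,
        n_runs=0,
        grid_step_el=bin_width,
        probed=tuple(probed),
    )


def strip_cv(embryos, centre_el: float = EL_BOUNDARY, width: float = 5.0) -> float:
    """Readout CV across all nuclei in a strip of the AP axis."""
    x = np.concatenate([e.positions for e in embryos])
    y = np.concatenate([e.readout for e in embryos])
    m = (x >= centre_el - width / 2) & (x < centre_el + width / 2)
    if not np.any(m):
        raise ValueError("no nuclei in the requested strip")
    vals = y[m]
    mean = vals.mean()
    if mean == 0:
        raise ValueError("strip CV undefined: zero mean readout")
    return float(vals.std(ddof=1) / mean)


def embryos_to_frame(embryos) -> pd.DataFrame:
    """Flat table (embryo_id, nc, nucleus_id, x_el_raw, x_el_aligned,
    readout) for CSV export."""
    rows = []
    for e in embryos:
        aligned = e.x_el_aligned if e.x_el_aligned is not None else np.full(len(e.x_el), np.nan)
        for i, (x, xa, r) in enumerate(zip(e.x_el, aligned, e.readout)):
            rows.append(
                {
                    "embryo_id": e.embryo_id,
                    "nc": e.nc,
                    "nucleus_id": i,
                    "x_el_raw": x,
                    "x_el_aligned": xa,
                    "readout": r,
                }
            )
    return pd.DataFrame(rows)
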