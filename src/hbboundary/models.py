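"""Promoter occupancy models as continuous-time Markov chains.

A promoter with ``N`` operator sites (OS) is described by a CTMC over
its occupancy states.  Binding transitions scale with the local
transcription-factor concentration ``[TF] = exp(X)`` where ``X`` is the
position along the AP axis in gradient decay lengths (``X = 0`` at the
mid-boundary).  The promoter is transcriptionally active on a subset of
states fixed by the activation rule, and the expression boundary is the
curve ``P_active(X)``.

Architectures
-------------
``eq_chain``
    N identical sites; occupancy count is a birth-death chain
    ``P_0 <-> P_1 <-> ... <-> P_N`` (always an equilibrium model).
``neq_graph``
    Full occupancy graph over ``2^N`` subsets of N = 3 distinguishable
    sites, an independent rate on every directed edge; zero rates
    encode irreversible (non-equilibrium) steps.
``hybrid``
    Six sites: a 3-site non-equilibrium occupancy graph that loads
    first, then a 3-site equilibrium chain that completes activation
    once the graph is full (sequential wiring; see docs/methods.md).
``two_gradient``
    An activating gradient ``exp(X)`` with N sites and a mirrored
    repressing gradient ``exp(-X)`` with L sites, two independent
    chains; active = activator full and repressor empty.
``plus_repressor``
    An eq_chain plus one repressor site whose occupancy is driven by a
    position-independent concentration profile (Capicua-like); active =
    activator rule satisfied and repressor site free.

Steepness is measured by the Hill coefficient ``H = 4 dP/dX`` at the
half-max point, exact for the Hill family ``e^{HX} / (1 + e^{HX})``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from ._trees import N_NEQ_SITES, TreeTable, hybrid_table, neq_edge_order, neq_graph_table
from .units import Position

__all__ = [
    "RateSet",
    "PromoterModel",
    "EffectiveConstants",
    "CalibrationError",
    "DegenerateChainError",
    "ARCHITECTURES",
    "DEFAULT_TAU_BIND",
    "DEFAULT_DIFFUSION",
    "DEFAULT_SITE_SIZE",
    "DEFAULT_TF_CONC",
    "build_generator",
    "steady_state",
    "stationary_log_probs",
    "activation_probability",
    "log_activation_probability",
    "calibrate_boundary",
    "effective_constants",
    "hill_analytic",
    "hill_numeric",
    "steepness_bound",
    "compute_tau_bind",
]

ARCHITECTURES = ("eq_chain", "neq_graph", "hybrid", "two_gradient", "plus_repressor")

N_NEQ_EDGES = len(neq_edge_order())  # 12 for three sites

#: Diffusion-limited search time for one TF to find an operator site,
#: tau_bind = 1 / (D a c): ~4 s with the standard Bcd estimates.
DEFAULT_DIFFUSION = 7.4  # um^2 / s
DEFAULT_SITE_SIZE = 0.003  # um
DEFAULT_TF_CONC = 1.0 / (DEFAULT_DIFFUSION * DEFAULT_SITE_SIZE * 4.0)  # 1 / um^3
DEFAULT_TAU_BIND = 4.0  # s

_HILL_STEP = 1e-3
_X_MAX = 4000.0  # bracket limit for boundary root-finding (log-concentration units)


class CalibrationError(ValueError):
    """The activation probability cannot be brought to 0.5 at X = 0."""


class DegenerateChainError(ValueError):
    """The chain has no unique stationary distribution."""


def compute_tau_bind(
    diffusion: float = DEFAULT_DIFFUSION,
    site_size: float = DEFAULT_SITE_SIZE,
    tf_conc: float = DEFAULT_TF_CONC,
) -> float:
    """Berg-Purcell diffusion-limited binding time ``1 / (D a c)`` in s."""
    if diffusion <= 0 or site_size <= 0 or tf_conc <= 0:
        raise ValueError("diffusion, site size and concentration must be positive")
    return 1.0 / (diffusion * site_size * tf_conc)


def steepness_bound(n_sites: int, tau_bind: float, tau_active: float) -> float:
    """Upper bound on the Hill coefficient of an all-or-nothing chain.

    A steep boundary requires a long active dwell time:
    ``H <= N - (N - 1) tau_bind / tau_active``.
    """
    if n_sites <= 0 or tau_bind <= 0 or tau_active <= 0:
        raise ValueError("all arguments must be positive")
    return n_sites - (n_sites - 1) * tau_bind / tau_active


# ---------------------------------------------------------------------------
# Rate sets


@dataclass(frozen=True)
class RateSet:
    """Kinetic parameters of one promoter architecture.

    ``binding_rates`` have units 1/(s * relative concentration) and are
    multiplied by ``[TF] = exp(X)`` (or ``exp(-X)`` for the mirrored
    repressor chain); ``unbinding_rates`` have units 1/s.  The layout of
    the rate vectors depends on the architecture:

    - ``eq_chain``: length N, entry i-1 is the step ``P_{i-1} -> P_i``.
    - ``neq_graph``: length 12, canonical edge order of the 3-site
      occupancy graph (see :func:`hbboundary._trees.neq_edge_order`).
    - ``hybrid``: length 15 = 3 chain steps + 12 graph edges.
    - ``two_gradient``: length N + L, activator chain then repressor.
    - ``plus_repressor``: length N + 1, the last entry is the repressor
      site.
    """

    architecture: str
    binding_rates: np.ndarray
    unbinding_rates: np.ndarray
    N: int
    K: int | None = None
    L: int | None = None
    tau_bind: float = DEFAULT_TAU_BIND

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        b = np.asarray(self.binding_rates, dtype=float)
        u = np.asarray(self.unbinding_rates, dtype=float)
        object.__setattr__(self, "binding_rates", b)
        object.__setattr__(self, "unbinding_rates", u)
        n_expected = self._expected_len()
        if b.shape != (n_expected,) or u.shape != (n_expected,):
            raise ValueError(
                f"{self.architecture}: expected {n_expected} binding and "
                f"unbinding rates, got {b.shape} / {u.shape}"
            )
        if np.any(b < 0) or np.any(u < 0):
            raise ValueError("rates must be nonnegative")
        if self.architecture in ("eq_chain", "two_gradient", "plus_repressor") and (
            np.any(b == 0) or np.any(u == 0)
        ):
            raise ValueError("equilibrium architectures require strictly positive rates")
        if self.tau_bind <= 0:
            raise ValueError("tau_bind must be positive")

    def _expected_len(self) -> int:
        if self.architecture == "eq_chain":
            return self.N
        if self.architecture == "neq_graph":
            if self.N != N_NEQ_SITES:
                raise ValueError("neq_graph is implemented for N = 3 sites")
            return N_NEQ_EDGES
        if self.architecture == "hybrid":
            if self.N != 6:
                raise ValueError("hybrid is implemented for N = 6 (3 eq + 3 neq sites)")
            return 3 + N_NEQ_EDGES
        if self.architecture == "two_gradient":
            if self.L is None:
                raise ValueError("two_gradient needs a repressor site count L")
            return self.N + self.L
        if self.architecture == "plus_repressor":
            return self.N + 1
        raise AssertionError

    def binding_caps(self) -> np.ndarray:
        """Diffusion-limited caps on the binding rate constants.

        Chain step i binds one of ``N - i + 1`` remaining free sites, so
        its rate constant is capped at ``(N - i + 1) / tau_bind``;
        occupancy-graph edges address a single site and cap at
        ``1 / tau_bind``.
        """
        inv = 1.0 / self.tau_bind

        def chain_caps(n):
            return (n - np.arange(1, n + 1) + 1) * inv

        if self.architecture == "eq_chain":
            return chain_caps(self.N)
        if self.architecture == "neq_graph":
            return np.full(N_NEQ_EDGES, inv)
        if self.architecture == "hybrid":
            return np.concatenate([chain_caps(3), np.full(N_NEQ_EDGES, inv)])
        if self.architecture == "two_gradient":
            return np.concatenate([chain_caps(self.N), chain_caps(self.L)])
        if self.architecture == "plus_repressor":
            return np.concatenate([chain_caps(self.N), [inv]])
        raise AssertionError

    def check_caps(self, rtol: float = 1e-9) -> bool:
        return bool(np.all(self.binding_rates <= self.binding_caps() * (1.0 + rtol)))

    @property
    def tau_active(self) -> float:
        """Mean active-state dwell time ``1 / k_{-N}`` (eq_chain)."""
        if self.architecture != "eq_chain":
            raise ValueError("tau_active is defined for the eq_chain architecture")
        return 1.0 / self.unbinding_rates[-1]

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "N": self.N,
            "K": self.K,
            "L": self.L,
            "binding_rates": self.binding_rates.tolist(),
            "unbinding_rates": self.unbinding_rates.tolist(),
            "tau_bind": self.tau_bind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        return cls(
            architecture=d["architecture"],
            binding_rates=np.asarray(d["binding_rates"], dtype=float),
            unbinding_rates=np.asarray(d["unbinding_rates"], dtype=float),
            N=d["N"],
            K=d.get("K"),
            L=d.get("L"),
            tau_bind=d.get("tau_bind", DEFAULT_TAU_BIND),
        )


# ---------------------------------------------------------------------------
# Promoter models


@dataclass(frozen=True)
class PromoterModel:
    """Architecture + rates + activation rule.

    ``activation_rule`` is ``"all_or_nothing"`` (active only when every
    activator site is bound) or ``"k_or_more"`` (eq_chain only: active
    when at least K sites are bound).  Architectures with a repressor
    additionally require the repressor side to be vacant.
    """

    rates: RateSet
    activation_rule: str = "all_or_nothing"
    boundary_calibrated: bool = False
    repressor_profile: Callable[[float], float] | None = None

    def __post_init__(self):
        if self.activation_rule not in ("all_or_nothing", "k_or_more"):
            raise ValueError(f"unknown activation rule {self.activation_rule!r}")
        if self.activation_rule == "k_or_more":
            if self.rates.architecture != "eq_chain":
                raise ValueError("k_or_more is supported for the eq_chain architecture")
            if self.rates.K is None or not (1 <= self.rates.K <= self.rates.N):
                raise ValueError("k_or_more needs 1 <= K <= N")

    # -- state space ------------------------------------------------------

    @property
    def architecture(self) -> str:
        return self.rates.architecture

    @property
    def n_states(self) -> int:
        r = self.rates
        if r.architecture == "eq_chain":
            return r.N + 1
        if r.architecture == "neq_graph":
            return 1 << N_NEQ_SITES
        if r.architecture == "hybrid":
            return 3 + (1 << N_NEQ_SITES)
        if r.architecture == "two_gradient":
            return (r.N + 1) * (r.L + 1)
        if r.architecture == "plus_repressor":
            return (r.N + 1) * 2
        raise AssertionError

    def active_states(self) -> np.ndarray:
        """Indices of transcriptionally active states."""
        r = self.rates
        if r.architecture == "eq_chain":
            lo = r.K if self.activation_rule == "k_or_more" else r.N
            return np.arange(lo, r.N + 1)
        if r.architecture == "neq_graph":
            return np.array([(1 << N_NEQ_SITES) - 1])
        if r.architecture == "hybrid":
            return np.array([3 + (1 << N_NEQ_SITES) - 1])
        if r.architecture == "two_gradient":
            # index = a * (L + 1) + l; active: a = N, l = 0
            return np.array([r.N * (r.L + 1)])
        if r.architecture == "plus_repressor":
            # index = a * 2 + bound; active: a = N, repressor free
            return np.array([r.N * 2])
        raise AssertionError

    def active_indicator(self) -> np.ndarray:
        a = np.zeros(self.n_states)
        a[self.active_states()] = 1.0
        return a

    def _repressor_conc(self, x_ln: float) -> float:
        if self.repressor_profile is None:
            return 1.0
        return float(self.repressor_profile(x_ln))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = self.rates.to_dict()
        d["activation_rule"] = self.activation_rule
        d["boundary_calibrated"] = self.boundary_calibrated
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "PromoterModel":
        return cls(
            rates=RateSet.from_dict(d),
            activation_rule=d.get("activation_rule", "all_or_nothing"),
            boundary_calibrated=d.get("boundary_calibrated", False),
        )

    @classmethod
    def from_json(cls, s: str) -> "PromoterModel":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Generator matrices


def _chain_generator(binding: np.ndarray, unbinding: np.ndarray, conc: float) -> np.ndarray:
    n = len(binding)
    q = np.zeros((n + 1, n + 1))
    idx = np.arange(n)
    q[idx, idx + 1] = binding * conc
    q[idx + 1, idx] = unbinding
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _neq_generator(binding: np.ndarray, unbinding: np.ndarray, conc: float) -> np.ndarray:
    n = 1 << N_NEQ_SITES
    q = np.zeros((n, n))
    for e, (s, j) in enumerate(neq_edge_order()):
        hi = s | (1 << j)
        q[s, hi] = binding[e] * conc
        q[hi, s] = unbinding[e]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _hybrid_generator(binding: np.ndarray, unbinding: np.ndarray, conc: float) -> np.ndarray:
    # states 0..7: occupancy-graph bitmasks; 8, 9, 10: equilibrium
    # chain occupancy 1..3 at graph-full (sequential loading)
    n_cube = 1 << N_NEQ_SITES
    n = n_cube + 3
    q = np.zeros((n, n))
    for e, (s, j) in enumerate(neq_edge_order()):
        hi = s | (1 << j)
        q[s, hi] = binding[3 + e] * conc
        q[hi, s] = unbinding[3 + e]
    full = n_cube - 1
    for i in range(3):
        lo = full if i == 0 else n_cube + i - 1
        q[lo, n_cube + i] = binding[i] * conc
        q[n_cube + i, lo] = unbinding[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _kron_sum(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Generator of two independent chains on the product space."""
    return np.kron(q1, np.eye(q2.shape[0])) + np.kron(np.eye(q1.shape[0]), q2)


def build_generator(model: PromoterModel, x: Position | float) -> np.ndarray:
    """Dense generator matrix at position ``x`` (rows sum to zero).

    Binding entries are scaled by the local relative concentration
    ``[TF] = exp(x_ln)`` of the gradient each site reads.
    """
    x_ln = float(x)
    r = model.rates
    conc = math.exp(x_ln)
    if r.architecture == "eq_chain":
        return _chain_generator(r.binding_rates, r.unbinding_rates, conc)
    if r.architecture == "neq_graph":
        return _neq_generator(r.binding_rates, r.unbinding_rates, conc)
    if r.architecture == "hybrid":
        return _hybrid_generator(r.binding_rates, r.unbinding_rates, conc)
    if r.architecture == "two_gradient":
        qa = _chain_generator(r.binding_rates[: r.N], r.unbinding_rates[: r.N], conc)
        qr = _chain_generator(r.binding_rates[r.N:], r.unbinding_rates[r.N:], math.exp(-x_ln))
        return _kron_sum(qa, qr)
    if r.architecture == "plus_repressor":
        qa = _chain_generator(r.binding_rates[:-1], r.unbinding_rates[:-1], conc)
        c_rep = model._repressor_conc(x_ln)
        qr = np.array(
            [
                [-r.binding_rates[-1] * c_rep, r.binding_rates[-1] * c_rep],
                [r.unbinding_rates[-1], -r.unbinding_rates[-1]],
            ]
        )
        return _kron_sum(qa, qr)
    raise ValueError(f"unknown architecture {r.architecture!r}")


def steady_state(generator: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Stationary distribution of a generator by direct linear solve.

    Solves ``pi Q = 0`` with the normalization ``sum pi = 1``.  Raises
    :class:`DegenerateChainError` when the chain has no unique
    stationary vector on its support (e.g. disconnected graphs).
    """
    q = np.asarray(generator, dtype=float)
    n = q.shape[0]
    a = q.T.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateChainError("no unique stationary distribution") from exc
    if not np.all(np.isfinite(pi)) or np.any(pi < -atol) or abs(pi.sum() - 1.0) > 1e-6:
        raise DegenerateChainError("stationary solve failed (reducible or ill-conditioned chain)")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Stable activation probabilities (log domain)


def _log_ktilde(binding: np.ndarray, unbinding: np.ndarray) -> np.ndarray:
    """log effective equilibrium constants of a chain, K~_0 = 1."""
    with np.errstate(divide="ignore"):
        steps = np.log(binding) - np.log(unbinding)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _chain_terms(binding, unbinding, mirror: bool = False):
    """Exp-polynomial terms (log-coeff, exponent) of a chain's weights."""
    a = _log_ktilde(binding, unbinding)
    c = np.arange(len(a), dtype=float)
    if mirror:
        c = -c
    return a, c


def _table_terms(table: TreeTable, binding, unbinding):
    w = table.log_tree_weights(np.log(binding, where=binding > 0,
                                      out=np.full_like(binding, -np.inf)),
                               np.log(unbinding, where=unbinding > 0,
                                      out=np.full_like(unbinding, -np.inf)))
    lw = table.group_logsumexp(np.asarray(w).reshape(-1))
    return lw, table.group_bcount.astype(float), table.group_root


def _activation_logterms(model: PromoterModel):
    """List of (a_num, c_num, a_den, c_den) exp-poly factors plus an
    optional extra callable factor returning log P on an X array."""
    r = model.rates
    factors = []
    extra = None
    if r.architecture == "eq_chain":
        a, c = _chain_terms(r.binding_rates, r.unbinding_rates)
        act = model.active_states()
        factors.append((a[act], c[act], a, c))
    elif r.architecture in ("neq_graph", "hybrid"):
        table = neq_graph_table() if r.architecture == "neq_graph" else hybrid_table()
        lw, c, root = _table_terms(table, r.binding_rates, r.unbinding_rates)
        mask = root == table.active_node
        factors.append((lw[mask], c[mask], lw, c))
    elif r.architecture == "two_gradient":
        a, c = _chain_terms(r.binding_rates[: r.N], r.unbinding_rates[: r.N])
        factors.append((a[-1:], c[-1:], a, c))
        ar, cr = _chain_terms(r.binding_rates[r.N:], r.unbinding_rates[r.N:], mirror=True)
        factors.append((ar[:1], cr[:1], ar, cr))
    elif r.architecture == "plus_repressor":
        a, c = _chain_terms(r.binding_rates[:-1], r.unbinding_rates[:-1])
        act = model.active_states() // 2
        factors.append((a[act], c[act], a, c))
        kb, ku = r.binding_rates[-1], r.unbinding_rates[-1]

        def extra(x_arr):
            conc = np.array([model._repressor_conc(float(x)) for x in np.atleast_1d(x_arr)])
            return np.log(ku) - np.logaddexp(np.log(ku), np.log(kb) + np.log(conc))

    else:
        raise ValueError(f"unknown architecture {r.architecture!r}")
    return factors, extra


def log_activation_probability(model: PromoterModel, x) -> np.ndarray | float:
    """``log P_active`` evaluated stably for scalar or array ``x``."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if isinstance(x, Position):
        x_arr = np.atleast_1d(float(x))
    factors, extra = _activation_logterms(model)
    out = np.zeros_like(x_arr)
    for a_num, c_num, a_den, c_den in factors:
        num = logsumexp(a_num[None, :] + c_num[None, :] * x_arr[:, None], axis=1)
        den = logsumexp(a_den[None, :] + c_den[None, :] * x_arr[:, None], axis=1)
        out += num - den
    if extra is not None:
        out += extra(x_arr)
    if np.isscalar(x) or isinstance(x, Position):
        return float(out[0])
    return out


def activation_probability(model: PromoterModel, x) -> np.ndarray | float:
    """Steady-state probability that the promoter is active at ``x``."""
    return np.exp(log_activation_probability(model, x))


def stationary_log_probs(model: PromoterModel, x: Position | float) -> np.ndarray:
    """log stationary distribution over the model's state space.

    Uses the chain closed form / matrix-tree tables, so it is accurate
    even when the generator is too badly scaled for a linear solve.
    """
    x_ln = float(x)
    r = model.rates

    def chain_logpi(binding, unbinding, x_val):
        a, c = _chain_terms(binding, unbinding)
        w = a + c * x_val
        return w - logsumexp(w)

    if r.architecture == "eq_chain":
        return chain_logpi(r.binding_rates, r.unbinding_rates, x_ln)
    if r.architecture in ("neq_graph", "hybrid"):
        table = neq_graph_table() if r.architecture == "neq_graph" else hybrid_table()
        lw, c, root = _table_terms(table, r.binding_rates, r.unbinding_rates)
        w = lw + c * x_ln
        logpi = np.full(table.n_nodes, -np.inf)
        for node in range(table.n_nodes):
            m = root == node
            if np.any(m):
                logpi[node] = logsumexp(w[m])
        return logpi - logsumexp(logpi)
    if r.architecture == "two_gradient":
        la = chain_logpi(r.binding_rates[: r.N], r.unbinding_rates[: r.N], x_ln)
        lr = chain_logpi(r.binding_rates[r.N:], r.unbinding_rates[r.N:], -x_ln)
        return (la[:, None] + lr[None, :]).reshape(-1)
    if r.architecture == "plus_repressor":
        la = chain_logpi(r.binding_rates[:-1], r.unbinding_rates[:-1], x_ln)
        kb = r.binding_rates[-1] * model._repressor_conc(x_ln)
        ku = r.unbinding_rates[-1]
        z = np.logaddexp(np.log(ku), np.log(kb))
        lr = np.array([np.log(ku) - z, np.log(kb) - z])
        return (la[:, None] + lr[None, :]).reshape(-1)
    raise ValueError(f"unknown architecture {r.architecture!r}")


# ---------------------------------------------------------------------------
# Boundary calibration


def _find_half_max(model: PromoterModel) -> float:
    """Root ``X_half`` of ``P_active(X) = 0.5`` by bracket expansion."""
    log_half = math.log(0.5)

    def g(x):
        return log_activation_probability(model, float(x)) - log_half

    g0 = g(0.0)
    if g0 == 0.0:
        return 0.0
    lo = hi = 0.0
    glo = ghi = g0
    step = 1.0
    # expand in the direction that moves P toward 0.5: P increases with
    # X for every activator-dominated architecture here
    while glo > 0 or ghi < 0:
        if ghi < 0:
            hi += step
            ghi = g(hi)
        if glo > 0:
            lo -= step
            glo = g(lo)
        step *= 2.0
        if hi > _X_MAX or lo < -_X_MAX:
            raise CalibrationError(
                "activation probability does not cross 0.5 on the searched range"
            )
    if glo == 0:
        return lo
    if ghi == 0:
        return hi
    return brentq(g, lo, hi, xtol=1e-13, rtol=8.882e-16, maxiter=200)


def _shift_rates(rates: RateSet, x_half: float) -> RateSet:
    """Recenter the boundary by rescaling unbinding rates.

    Multiplying every unbinding rate of a single-gradient model by
    ``exp(-X_half)`` translates ``P_active`` so that the half-max moves
    to ``X = 0`` (the stationary distribution depends on the rates only
    through ``binding * exp(X) / unbinding`` up to a global time scale).
    The mirrored repressor chain of ``two_gradient`` is shifted the
    opposite way; a constant-profile repressor site is left untouched.
    Binding rates (and so their diffusion caps) are never modified.
    """
    u = rates.unbinding_rates.copy()
    f = math.exp(-x_half)
    if rates.architecture == "two_gradient":
        u[: rates.N] *= f
        u[rates.N:] /= f
    elif rates.architecture == "plus_repressor":
        u[:-1] *= f
    else:
        u *= f
    if not np.all(np.isfinite(u)):
        raise CalibrationError("boundary shift overflows the unbinding rates")
    return replace(rates, unbinding_rates=u)


def calibrate_boundary(
    model: PromoterModel, tol: float = 1e-9, _depth: int = 0
) -> PromoterModel:
    """Rescale rates so that ``P_active(0) = 0.5`` (mid-boundary).

    Raises :class:`CalibrationError` when the activation probability
    saturates below 0.5 everywhere (e.g. a repressor that never
    vacates) or the required shift overflows.
    """
    x_half = _find_half_max(model)
    new = replace(model, rates=_shift_rates(model.rates, x_half), boundary_calibrated=True)
    err = activation_probability(new, 0.0) - 0.5
    if abs(err) > tol:
        if _depth < 3:
            return calibrate_boundary(new, tol=tol, _depth=_depth + 1)
        raise CalibrationError(f"calibration residual {err:.2e} exceeds {tol}")
    return new


# ---------------------------------------------------------------------------
# Hill coefficients


@dataclass(frozen=True)
class EffectiveConstants:
    """Effective equilibrium constants ``K~_i`` of a chain (log stored).

    ``K~_i = prod_{j<=i} k_j / prod_{j<=i} k_{-j}``; ``K~_0 = 1``.  The
    linear-space view may overflow for extreme rate sets; computations
    use the logs.
    """

    log_ktilde: np.ndarray

    def __post_init__(self):
        lk = np.asarray(self.log_ktilde, dtype=float)
        object.__setattr__(self, "log_ktilde", lk)
        if lk[0] != 0.0:
            raise ValueError("K~_0 must equal 1")

    @property
    def ktilde(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.log_ktilde)

    @property
    def n_sites(self) -> int:
        return len(self.log_ktilde) - 1

    @classmethod
    def from_ktilde(cls, ktilde: Sequence[float]) -> "EffectiveConstants":
        kt = np.asarray(ktilde, dtype=float)
        if np.any(kt < 0):
            raise ValueError("effective constants must be nonnegative")
        with np.errstate(divide="ignore"):
            return cls(np.log(kt))


def effective_constants(rates: RateSet) -> EffectiveConstants:
    if rates.architecture != "eq_chain":
        raise ValueError("effective constants are defined for the eq_chain architecture")
    return EffectiveConstants(_log_ktilde(rates.binding_rates, rates.unbinding_rates))


def hill_analytic(ktilde: EffectiveConstants, calib_tol: float = 1e-6) -> float:
    """Hill coefficient of a calibrated all-or-nothing chain.

    ``H = N - (sum_{i=1}^{N-1} i K~_i) / K~_N``, which equals four times
    the mid-boundary slope of ``P_active`` and lies in ``[1, N]``.
    Requires the calibration identity ``sum_{i<N} K~_i = K~_N``.
    """
    lk = ktilde.log_ktilde
    n = ktilde.n_sites
    if not np.isfinite(lk[-1]):
        raise ValueError("K~_N must be positive and finite")
    if abs(logsumexp(lk[:-1]) - lk[-1]) > calib_tol:
        raise ValueError("effective constants are not boundary-calibrated")
    if n == 1:
        return 1.0
    i = np.arange(1, n, dtype=float)
    s = logsumexp(lk[1:-1] + np.log(i)) if n > 1 else -np.inf
    return n - math.exp(s - lk[-1])


def hill_numeric(model: PromoterModel, step: float = _HILL_STEP) -> float:
    """Hill coefficient ``4 dP/dX`` at X = 0 by central difference.

    A Hill sigmoid ``e^{HX} / (1 + e^{HX})`` has mid-boundary slope
    ``H / 4``, so this convention matches the Hill-fit steepness
    exactly for the Hill family.
    """
    if not model.boundary_calibrated:
        raise ValueError("hill_numeric requires a boundary-calibrated model")
    # fourth-order central stencil: truncation well below 1e-6 at h=1e-3
    p = activation_probability(model, np.array([2 * step, step, -step, -2 * step]))
    slope = (-p[0] + 8 * p[1] - 8 * p[2] + p[3]) / (12.0 * step)
    return float(4.0 * slope)
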