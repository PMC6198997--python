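# hbboundary

Promoter-occupancy models of the *hunchback* (*hb*) expression boundary
in the early *Drosophila* embryo, and the trade-off between how **steep**
that boundary can be and how **reproducibly** individual nuclei can read
it out within the few minutes of a nuclear-cycle interphase.

## The problem

In nuclear cycles (nc) 11–13 the Bicoid (Bcd) morphogen gradient decays
exponentially along the anterior–posterior axis, and the *hb* promoter
converts the local Bcd concentration `[TF]` into a steep, almost binary
transcription pattern. Writing the position in gradient decay lengths,
`X = ln [TF]` (0 at the half-max boundary, ≈ −5 % egg length), the mean
readout is summarized by a Hill curve

    ⟨f_P⟩ ≈ [TF]^H / (TF0^H + [TF]^H),        H ≡ 4 · dP_active/dX |_{X=0}

This package models the promoter as a continuous-time Markov chain over
the occupancy states of its N Bicoid operator sites — an equilibrium
identical-site chain (`P_0 ⇌ … ⇌ P_N`, steady state
`π_i ∝ K̃_i e^{iX}` with effective constants
`K̃_i = Π k_j / Π k_{-j}`), a full non-equilibrium occupancy graph
(N = 3, every directed edge its own rate), a sequential hybrid with
3 equilibrium + 3 non-equilibrium sites, a mirrored
activator–repressor two-gradient model, and a chain plus one
constant-concentration repressor site. Binding rates are capped by the
Berg–Purcell diffusion limit `τ_bind = 1/(D a c) ≈ 4 s`, which ties
steepness to switching kinetics:

    H ≤ N − (N − 1) · τ_bind / τ_active

Against these models it computes three observables

- the **formation diagnostic** μ_P(T_full, 0) — can the steady-state
  boundary even form in an interphase of length T_full?
- the **readout error** CV_P = δf_P/⟨f_P⟩ of the time-averaged activity
  f_P = (1/T)∫ n(t) dt across nuclei (exact Gillespie simulation, and
  an analytic autocovariance twin);
- the **positional resolution** ΔX — the smallest distance between two
  nuclei straddling the boundary whose readouts satisfy
  P(F₊ ≤ F₋) ≤ 0.05 — reported in ln-concentration units, % egg length
  (× 20) and nucleus widths (% EL / 2).

A synthetic-embryo module generates MS2-MCP-like per-nucleus datasets
(AP position + noisy fluorescence readout, several embryos per cycle
with embryo-specific boundary offsets) and implements the experimental
analysis: half-max alignment, binned Hill fitting with embryo-level
confidence intervals, empirical ΔX and strip CV.

## Worked example

```python
import numpy as np
from hbboundary.scan import random_scan
from hbboundary.readout import cv_p_analytic
from hbboundary.resolution import delta_x, bernoulli_delta_x

# 20 000 random rate sets of the 3-site non-equilibrium promoter,
# boundary-calibrated, with diffusion-capped binding
pool = random_scan("neq_graph", 20_000, rng=1)
print(f"max Hill coefficient: {pool.hill.max():.3f}")   # 4.759

# the frozen-switching resolution floor of a maximally steep N=6 chain
print(f"{bernoulli_delta_x(6.0).delta_x_el:.2f} % EL")  # 24.34 % EL

# readout error and resolution of one calibrated set at the nc13 window
m = pool.models[int(np.argmax(pool.hill))]
print(f"CV_P = {cv_p_analytic(m, 0.0, 370.0):.2f}")     # 1.00
print(f"DeltaX = {delta_x(m, 370.0, rng=0).delta_x_el:.1f} % EL")  # 28.0
```

The numbers tell the story in miniature: the steepest random
non-equilibrium set (H ≈ 4.8, close to the 2N − 1 = 5 ceiling for
three sites) switches so slowly that its mid-boundary readout is a
coin flip (CV_P ≈ 1), and two nuclei need 28 % EL of separation —
about 14 nucleus widths — before the posterior one reliably reads
less than the anterior one.

A command-line interface exposes the same stages
(`hbboundary steady | dynamics | scan | resolve | synth | fit`), each
writing CSV/JSON with unit-annotated columns; see `hbboundary --help`.

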