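# Methods

## Model family

The promoter is a continuous-time Markov chain (CTMC) over occupancy
states of its operator sites (OS). Binding transitions scale with the
local relative TF concentration `[TF] = e^X`, where `X` is the AP
position in gradient decay lengths (λ ≈ 100 µm ≈ 20 % egg length;
`X = 0` at the half-max boundary, ≈ −5 % EL; one nucleus ≈ 2 % EL).
Transcription is all-or-nothing — the promoter is active only in the
fully bound state — except where noted.

Architectures:

- **`eq_chain`** — N identical sites; the occupancy count is a
  birth–death chain, always reversible. Steady state
  `π_i ∝ K̃_i e^{iX}` with `K̃_i = Π_{j≤i} k_j / k_{−j}`. For a
  calibrated chain the steepness has the closed form
  `H = N − (Σ_{i<N} i·K̃_i)/K̃_N ∈ [1, N]`. A `k_or_more` activation
  rule (active when ≥ K sites bound) is supported.
- **`neq_graph`** — all 2³ occupancy subsets of N = 3 distinguishable
  sites; every directed edge carries an independent rate; zero rates
  encode irreversible steps. Ceiling `H ≤ 2N − 1 = 5`.
- **`hybrid`** — six sites: the 3-site non-equilibrium occupancy graph
  loads first; once it is full, a 3-site equilibrium chain completes
  activation (chain binding requires the graph full, graph unbinding
  out of the full state requires the chain empty). The reachable state
  space is 11 states. This *sequential* wiring is a deliberate design
  choice among the readings of "3 equilibrium + 3 non-equilibrium
  sites": with the two groups instead independent (active = both
  full), the mid-boundary slope decomposes as `H = 2(s_A + s_B)` with
  each factor's log-slope bounded by `N_f (1 − P_f)` and
  `P_A P_B = ½`, which caps H near 4 (measured max 3.997 over 3000
  randomized calibrated sets) — too shallow to reach the
  experimentally observed H ≈ 7. The reverse order (chain loads
  first) over-drives, with randomized scans reaching H ≈ 9. The
  graph-first wiring approaches the ceiling `H ≤ 8 = 3 + (2·3 − 1)`
  from below at the study's scan scale (measured max 7.7–8.2 at
  5·10⁴ sets) while producing parameter sets across 1 ≤ H ≤ 8;
  its strict supremum lies slightly above 8 (rare excursions to ~8.4
  were observed at 2·10⁵ sets), so the ceiling is a scan-scale
  property here rather than an exact bound.
- **`two_gradient`** — an activating gradient `e^X` (N sites) and a
  mirrored repressing gradient `e^{−X}` (L sites), two independent
  chains; active ⇔ activator full and repressor empty.
- **`plus_repressor`** — an activator chain plus one repressor site
  driven by a position-independent concentration profile (Capicua-like;
  configurable callable, default constant 1); active ⇔ activator rule
  satisfied and repressor site free. A repressor that never vacates
  makes the model uncalibratable, and calibration rejects it.

## Numerical core

**Stationary distributions.** Randomized rates span 1e−20…1e20 s⁻¹, so
`π Q = 0` in floating point is hopeless for the tails. Occupancy-graph
steady states are computed by the Markov chain tree theorem: `π_i` is a
sum over spanning arborescences rooted at `i` of products of edge
rates; each arborescence is a monomial in `e^X` whose degree is its
binding-edge count. The tables (384 spanning trees for the 3-cube) are
enumerated once per architecture and evaluated by log-sum-exp, giving
`P_active(X)` as a ratio of exponential polynomials that is exact for
any rate magnitudes and any `X`. The dense null-space solve is retained
(`steady_state`) and serves as the independent oracle in tests.

**Calibration.** Each rate set is recentered so `P_active(0) = ½`:
the half-max `X_half` is found by bracket expansion + Brent (batched
bisection in scans, |residual| ≤ 1e−9), then all unbinding rates are
multiplied by `e^{−X_half}` (the mirrored repressor chain by
`e^{+X_half}`). Because the stationary law depends on rates only
through `binding·e^X/unbinding` up to a global time scale, this is an
exact translation of the boundary for every architecture here, and it
never touches the binding rates, so the diffusion caps
`k_{+i} ≤ (N−i+1)/τ_bind` (chains) and `1/τ_bind` (graph edges) are
preserved by construction. Sets with no half-max crossing on
`|X| ≤ 4000` or whose shift overflows are discarded and counted.

**Steepness.** `H = 4·dP/dX` at `X = 0` by a fourth-order central
stencil with step 1e−3 (truncation ≪ 1e−6; exact for the Hill family,
whose mid-slope is H/4). The chain closed form and the stencil agree to
1e−6 on calibrated chains.

**Master-equation propagation** starts from the all-free state (Bcd
re-enters nuclei after mitosis). For ≤ 64 states the propagator
`e^{Qᵀdt}` is built by scaling-and-squaring of the *stochastic* matrix
(squaring a column-stochastic matrix cannot overflow, unlike plain
`expm` on 40-decade generators), renormalizing columns each squaring;
an implicit BDF integration with the generator as analytic Jacobian is
the fallback. Interphase windows: T_full = 270 s (nc11), 400 s (nc12,
interpolated), 520 s (nc13); steady-state windows T = T_full − 150 s
(the pattern stabilizes 2–3 min after mitosis). These are configurable.

**Stochastic readouts.** Exact Gillespie paths (numba kernel) with the
initial state drawn from the stationary law (steady-state regime;
`init="all_free"` connects to the formation-time analysis). The readout
is the exact piecewise-constant time average of the activity indicator.
When the expected jump count per run exceeds 5·10⁵ the time average has
converged to its Gaussian limit and samples are drawn from the analytic
mean/variance instead (with diffusion-capped, calibrated models near
the boundary this is rare — net binding flows are capped, so expected
event counts stay ~10³–10⁴).

**Analytic readout error.** `Var(f_P) = (2/T²)∫₀ᵀ(T−τ)C(τ)dτ` with
`C` the stationary autocovariance of the activity indicator. Primary
route: spectral decomposition of the generator, skipping exactly the
one eigenvalue nearest zero (the stationary mode, which cancels `p²`).
The mode split is validated by requiring the remaining coefficients to
reconstruct `C(0) = p(1−p)`; rate sets whose eigenbasis is too
ill-conditioned (exit-rate spread > 1e12, cond(V) > 1e10, or a failed
validation) fall back to a stiff BDF quadrature of the autocovariance
with the generator as Jacobian. Averaging M gene copies divides the
variance by M (effective treatment of spatial mRNA averaging).
Sample CV uses n−1 normalization.

**Positional resolution.** `P(F₊ ≤ F₋)` is estimated over the full
empirical product of the two marginal samples (n² pairs, ties counted
toward the event — this matters for Bernoulli-like samples and is
fixed, not configurable); ΔW is scanned from 0.5 to 40 % EL in 0.5 %
steps and the smallest qualifying separation reported (grid-quantized;
unresolvable → ∞ sentinel). No Gaussian approximation is used — the
readout distributions are strongly non-Gaussian at short T. In the
frozen-switching limit the closed form is
`ΔX = (2/H)·ln(q/(1−q))`, `q = √(1−α)` (exact binomial enumeration for
M > 1); at α = 0.05, H = 6 this gives 24.34 % EL. Note that the
first-crossing rule on a noisy P̂ has ~1–2 % EL of statistical jitter
at 500 runs per side near the threshold; oracle comparisons therefore
use 4000 frozen runs (free — frozen loci generate no events).

**Scans.** All rates log-uniform on [1e−20, 1e20] s⁻¹, binding clipped
to caps, ~5·10⁴ sets per architecture (tests use smaller pools with
wider tolerances; the acceptance script states its pool sizes in its
output). Binned bound surfaces use H-bins of width 0.25. Within each
bin the minimum-CV set is selected for SSA ΔX (readout error and
resolution are tightly correlated; CV is orders of magnitude cheaper).
`H*` is the bin minimizing ΔX; its tolerance interval collects bins
within 2 % EL (≈ one nucleus) of the optimum, and `H_robust` is the
minimum over steady-state windows of the interval's upper end.
`tau_bind` enters only as the global time scale: mapping every rate by
1/c and (τ_bind, T) → (c·τ_bind, c·T) is an exact invariance, which
`rescale_time_axis` implements and the sensitivity table demonstrates.

## Synthetic embryos

Each embryo carries `n_rows = 6` AP rows × 50 nuclei on an even grid
(a live-imaging field shows hundreds of nuclei; analyses that need
tighter binned statistics pass `n_rows=12`), readouts drawn by exact
SSA at each nucleus's position, scaled to arbitrary fluorescence units
(default 1000), multiplied by mean-one lognormal noise (default
CV 0.2 — the measurement-noise knob; the source experiments publish no
value) and shifted by an embryo-specific boundary offset
~ Normal(0, 2 % EL), about one nucleus of embryo-to-embryo variability.
Default counts: 8 embryos in nc12, 4 in nc13. The generator does *not*
emulate polymerase-traffic noise, mRNA accumulation/degradation
kinetics, imaging calibration drift or segmentation errors — so
passing pipeline tests demonstrate statistical self-consistency of the
analysis chain, not instrument realism.

**Alignment** finds where a rank-based moving-average profile (window
≈ 2.5 % EL of nuclei, shrinking at the edges) crosses half its
anterior-plateau value, and recenters that crossing to −5 % EL. The
rank-based smoother is exactly translation-equivariant, which makes
alignment idempotent to machine precision (an absolute binning grid is
not, because grid-edge membership flips under float shifts).

**Hill fit.** Aligned nuclei are pooled, binned (2.5 % EL), positions
converted to `[TF]` through the exponential gradient and the bin means
fitted with `A·[TF]^H/(TF0^H + [TF]^H)` (bounded least squares,
H ∈ [0.1, 64]; fits pinned at the upper bound are flagged as
"diverged" — step-like data do not identify H). Uncertainty is at the
embryo level: the default 95 % interval is a leave-one-embryo-out
jackknife t-interval. The percentile bootstrap over embryos is also
available (`ci_method="bootstrap"`), but with the 4–8 embryos of one
cycle its cluster standard error is biased low and measured coverage
of the generating steepness drops to ~82 %, versus ~92–97 % for the
jackknife — which is why the jackknife is the default.

**Empirical ΔX and strip CV** pool nuclei within 5 % EL bins centred
at ±ΔW/2 (the anterior, high-TF side supplies F₊) and apply the same
false-positive criterion; strip CV is std/mean of readouts in a 5 % EL
strip.

## Problem sizes and defaults

| Quantity | Default | Why |
| --- | --- | --- |
| τ_bind | 4 s (D = 7.4 µm²/s, a = 3 nm, c chosen accordingly) | diffusion-limited Berg–Purcell estimate for Bcd |
| rate range | 1e−20…1e20 s⁻¹, log-uniform | unconstrained prior over kinetic space |
| scan size | 5·10⁴ sets | stabilizes binned extrema |
| SSA runs | 500 per side | matches the resolution procedure's replication |
| α | 0.05 | false-positive tolerance defining ΔX |
| ΔW grid | 0.5–40 % EL, step 0.5 | quarter-nucleus resolution |
| H bins | 0.25 | fine enough to localize H* |
| windows | T_full 270/400/520 s; T = T_full − 150 s | nc11–13 interphases |

## Known limitations

- The hybrid wiring is one defensible reading of "3 equilibrium +
  3 non-equilibrium OS"; alternatives (independent product, shared
  activation) are possible, and the product variant measurably cannot
  exceed H ≈ 4.
- The analytic CV on extreme rate sets relies on a stiff quadrature
  whose accuracy degrades in the deep tails; scans only use it for
  pre-ranking, and every reported ΔX comes from exact SSA.
- mRNA-level noise sources (polymerase loading, elongation traffic)
  are outside the model: promoter-activity statistics are taken as
  proportional to the mRNA readout.
- ΔX is grid-quantized and, near the threshold, carries the sampling
  jitter of the first-crossing rule discussed above.
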