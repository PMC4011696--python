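# Methods

## Model

`periflow` implements a coarse-grained model of translation elongation: an
mRNA is divided into `n` consecutive sites, and `x_i(t) ∈ [0, 1]` is the
normalized ribosome occupancy of site `i`.  Flow between sites is governed
by `n + 1` positive rates — the initiation rate `λ0` and transition rates
`λ1 … λn` — with soft exclusion: flow into a site is throttled by `1 − x`
of the target site,

    dx1/dt = λ0(t)(1 − x1) − λ1(t)·x1·(1 − x2)
    dxi/dt = λ_{i−1}(t)·x_{i−1}·(1 − x_i) − λ_i(t)·x_i·(1 − x_{i+1})
    dxn/dt = λ_{n−1}(t)·x_{n−1}·(1 − x_n) − λn(t)·x_n,

with translation rate (protein output flux) `R(t) = λn(t)·x_n(t)`.  This
is the mean-field reduction of the totally asymmetric simple exclusion
process (TASEP), which the package also simulates directly for comparison.

The periodic variant assumes every rate is continuous (or
piecewise-constant for the noise wrapper), strictly positive, uniformly
bounded (`0 < δ1 ≤ λ_i(t) ≤ δ2`), and that all non-constant rates share a
minimal common period `T`.  Biologically the periodic forcing stands in
for oscillating tRNA abundances, initiation/elongation factor levels, or
other cell-cycle-coupled resources.  Three structural facts carry all the
analysis and are asserted numerically throughout the test suite:

1. the closed unit cube is forward invariant;
2. the flow is cooperative (tridiagonal Jacobian, Metzler on the cube) and
   hence monotone;
3. the Jacobian has column sums `(−λ0, 0, …, 0, −λn)`, so the ℓ1 matrix
   measure is ≤ 0 everywhere: the ℓ1 distance between any two trajectories
   never increases.

Plain non-expansiveness is not contraction — the interior column sums are
exactly zero — so uniqueness of the entrained orbit rests on two further
ingredients implemented here: trajectories enter strict subcubes
`Ω_ε = {ε ≤ x_i ≤ 1 − ε}` in finite time and stay there (the positivity
floor `δ1 > 0` is essential: a rate that vanishes identically pins
trajectories to cube faces, which is why schedules reject non-positive
rates at construction), and on each `Ω_ε` a *weighted* ℓ1 norm makes the
flow strictly contracting (below).

## Rates and scenario presets

Supported rate shapes: constant, sinusoid
(`b + a·sin(2π(t − φ)/T)`, `a < b`), square wave (`b + a` on
`[kT, kT + T/2)`, `b − a` on the second half; half-open so evaluation at a
discontinuity is unambiguous), and a noise wrapper adding a uniform draw
on `[−h, h]` held constant over windows of length `refresh_step`.  The
draw for window `k` is a pure function of `(seed, k)`, making noisy paths
reproducible and random-access; `h` must stay below the inner rate's
minimum so positivity survives.

The minimal common period is computed exactly by rational arithmetic:
each period ratio is approximated by a fraction with denominator ≤ 10⁴ at
relative error ≤ 1e−9 (else the periods are declared incommensurate), and
`T = p_ref · lcm(numerators)/gcd(denominators)`.  Constant rates are
periodic with every period and never constrain `T`.

Four presets fix the study conditions (all concrete values are the
package's own choices):

- **entrain_demo** — all `n+1` rates sinusoidal with periods drawn from
  `{T, T/2, T/3}` (`T = 6`), baselines `U(0.8, 1.4)`, relative amplitudes
  20–45 %: generic multi-harmonic forcing with minimal common period `T`.
- **rate_limited_elongation** — sinusoidal initiation `1 ± 0.5` (`T = 10`)
  feeding constant transition rates `0.3`, below the initiation minimum,
  so elongation is the bottleneck and the oscillation attenuates site by
  site.
- **noisy_rates** — entrain_demo wrapped in noise with half-width 25 % of
  each rate's minimum, refresh `T/20`.
- **tasep_demo** — square-wave initiation `1.2 ± 0.9` against constant
  transition rates `2.0` (`T = 20`).  Hopping is deliberately fast
  relative to the forcing (site relaxation ≈ 0.5 time units vs `T = 20`):
  the stochastic occupancies must track the modulation faster than
  segment averaging washes it out, otherwise entrainment is present but
  invisible at realistic sample sizes.

## Equilibrium (constant rates)

At the unique equilibrium all bond fluxes equal a common `R`:
`λ0(1 − e1) = λ_i e_i(1 − e_{i+1}) = λn e_n`.  Given `R`, the profile
back-substitutes uniquely from the exit side; the entry mismatch
`g(R) = λ0(1 − e1(R)) − R` is strictly decreasing on the feasible
interval, so bisection on `R ∈ (0, min_i λ_i)` finds the root.  A
candidate whose back-substitution pushes any occupancy to ≥ 1 lies above
the root and is treated as the negative branch.  Bisection runs to
floating-point resolution rather than stopping at the nominal `tol`
(default 1e−12 on `R`), because near-saturated occupancies amplify `dR`
by orders of magnitude in the profile; the flux-balance residual of the
returned profile is typically ≤ 1e−12.

Closed forms used as oracles: `n = 1` gives `e = λ0/(λ0 + λ1)`; `n = 2`
with equal rates gives `R² − 3R + 1 = 0`, i.e. `R = (3 − √5)/2` and
`e = ((√5 − 1)/2, (3 − √5)/2)`.

## Entrained periodic orbit

The flow over one period maps the cube into itself continuously, so a
fixed point of the period (Poincaré) map exists; subcube entry plus
contraction make it unique and globally attracting.  `find_periodic_orbit`
uses plain Picard iteration of the period map — geometric convergence is
guaranteed, so Anderson-style acceleration is unnecessary — implemented as
chunked long integrations (16 periods per ODE solve) checking successive
period states in ℓ1.

Numerics: the period map is integrated at rtol 1e−11 / atol 1e−13, tighter
than the general-purpose default (1e−8/1e−10), because the fixed-point
iteration must resolve differences at its own tolerance (default 1e−10
ℓ1); with the looser default the iterate distances plateau at the
integrator's noise floor near 1e−9 and convergence stalls.  Orbit
waveforms are sampled at 400 points per period (configurable); halving
the spacing changes reported peak-to-peak amplitudes by well under 1 %.

Degenerate case: proportional rates `λ_i(t) = c_i·g(t)` reduce to the
constant-rate model under the time change `s = ∫g`, so the "orbit" is the
constant equilibrium of `c` and all amplitudes vanish; this is used as an
exact oracle (amplitudes ≤ 1e−8 in the tests) and contrasted with a
non-proportional preset whose amplitudes exceed 1e−4.

`entrainment_report` tracks `d_k = ‖x((k+1)T) − x(kT)‖₁` per start and
pairwise matched-time distances across starts.  For noiseless schedules
both fall below 1e−6 within tens of periods; for noisy schedules `d_k`
settles at a floor set by the noise half-width — reported, not asserted,
since noise makes the exact periodic orbit only an idealization.

Integration is `scipy.integrate.solve_ivp` RK45.  States are clipped into
`[0, 1]` after the solve; an excursion beyond 1e−9 raises instead of
clipping silently, since the exact flow cannot leave the cube.  Schedules
with piecewise-constant noise are integrated window by window so the RHS
discontinuities coincide with solver restarts — without this the adaptive
error control is not honest across a jump and pairwise distances acquire
spurious 1e−6-scale increments.

## Contraction certificates

On `Ω_ε` the off-diagonal Jacobian entries `λ_i x_i` and
`λ_i(1 − x_{i+1})` lie in `[δ1·ε, δ2]`, and columns 1 and n carry extra
diagonal terms `−λ0, −λn ≤ −δ1`.  `construct_scaling` builds a weight
vector `d` (`d_1 = 1`, gaps `g_2 = ρ·end_low/off_high`,
`g_{j+1} = ρ·(off_low/off_high)·g_j`, default `ρ = 1/2`) for the whole
matrix class {tridiagonal, Metzler, zero column sums, off-diagonals in
`[off_low, off_high]`, end-column deficit ≥ `end_low`} and returns the
analytic worst-case scaled column bound `c`.  Increasing `d` is the right
direction because columns 1 and n own the strictly negative slack that
must absorb the positive `off_high·(d_{j+1}/d_j − 1)` terms; the
column-1 bound is exactly `−(1 − ρ)·end_low` and the interior bounds are
negative because the gap ratio undercuts `off_low/off_high`.  The
column-n worst case is attained at the *smallest* admissible off-diagonal
entry (its weight ratio is below one), and is dominated by the column-1
bound in all regimes.  For long chains the geometric gaps can underflow
float spacing, in which case `d` saturates; all bounds are computed from
the returned floating-point `d`, so `c` remains valid for
`scaled_measure` with that `d`.

`certify_contraction` instantiates the class bounds from `(δ1, δ2, ε)` —
so the certificate is grid-free in space and conservative in time — and
then verifies independently: scaled column sums of the actual Jacobian
are affine in each coordinate, hence maximized at a subcube vertex; all
`2^n` vertices are enumerated on a 64-point time grid over `[0, T]`
(vertex enumeration is capped at `n ≤ 20`; beyond that interval
arithmetic would be required).  A Monte-Carlo sweep over random class
members and a least-squares fit of the observed log scaled-distance decay
(contract: fitted rate ≤ `c/2`) close the loop in the test suite.  The
certified `c` is deliberately conservative — observed decay rates are
typically two orders of magnitude faster.

## Stochastic lattice simulation

`simulate_tasep` runs TASEP with time-varying rates on a rounded clock:
waiting times are exponential with the rate evaluated at the draw moment
(quenched per event — the simplest convention that is well defined under
time-varying rates), rounded *up* to the `dt` grid; a blocked hop or
entry redraws at the current rate.  Ties within a slot resolve in
increasing site order with entry last, giving bit-reproducible traces.
The rounding bias vanishes as `dt → 0`; the default `dt = 1/(100·δ2)`
keeps it far below Monte-Carlo noise, and a `dt` coarser than
`1/(10·δ2)` triggers a warning.  Ribosome footprints `ℓ ≥ 1` are
supported (entry needs the first `ℓ` sites empty; a hop needs the site
past the footprint free); the mean-field comparison requires `ℓ = 1`,
where the site-wise correspondence with the ODE model holds.

Segment averaging divides the horizon into windows of length `L` and
averages each site's binary occupancy per window.  The periodicity score
of a per-segment series is the RMS difference between consecutive
period-long blocks divided by the series' peak-to-peak range (0 for an
exactly periodic series, order 1 for white noise); significance is
assessed against a permutation null that shuffles the same segments.
Stationary and periodic statistics discard the first quarter of the
horizon as burn-in.  The `n = 1` lattice is a two-state Markov chain with
stationary occupancy `λ0/(λ0 + λ1)`, used as an exact oracle with batch-
means standard errors.

## Problem sizes

Defaults used by the test suite and the results script: chains of
3–10 sites; orbit convergence over ≲ 200 periods; certificates at
`ε = 0.1` on 3-site chains (64 time points × 8 vertices); TASEP runs of
1e5 time units at `n = 1` and 100 forcing periods at `n = 8`; 1e4-draw
Monte-Carlo sweeps.  These sizes resolve every asserted property with
comfortable margins while keeping a full run in the low minutes on one
core.

## Limitations

- The synthetic presets emulate the *structure* of interesting regimes
  (common-period forcing, rate-limited elongation, noisy forcing), not
  any measured gene's rates; passing tests demonstrate properties of the
  model class, not fits to data.
- The contraction certificate is sufficient, not tight: `c` shrinks
  linearly with `ε·δ1/δ2` and is far from the observed decay rate.
- Entrainment under noise is demonstrated by simulation only; no
  stochastic entrainment theory is implemented.
- No ribosome drop-off, initiation feedback (ribosome recycling), or
  Langmuir attachment/detachment kinetics; forcing must be periodic —
  quasi-periodic or chirped schedules are rejected by the period
  arithmetic.
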