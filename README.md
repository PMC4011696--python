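# periflow

Ribosome flow dynamics under periodic initiation and elongation rates:
simulation, entrained-orbit computation, contraction certification, and a
stochastic exclusion-process cross-check.

## What this is for

During periodic cellular programs such as the cell cycle, the resources
that drive mRNA translation — tRNA pools, initiation and elongation
factors, ribosome availability — oscillate.  A basic question for anyone
modelling translation (or designing synthetic circuits that should lock to
a clock) is whether the translation machinery *entrains*: does the
ribosome density profile, and with it the protein synthesis rate, converge
to a periodic pattern with the forcing period, from any starting state?

`periflow` answers this computationally for the ribosome flow model (RFM),
the mean-field reduction of TASEP.  The chain has `n` site occupancies
`x_i ∈ [0, 1]` coupled by positive rates `λ0(t), …, λn(t)`:

    ẋ1 = λ0(1 − x1) − λ1 x1 (1 − x2)
    ẋi = λ_{i−1} x_{i−1} (1 − x_i) − λ_i x_i (1 − x_{i+1})
    ẋn = λ_{n−1} x_{n−1} (1 − x_n) − λn x_n,

with translation rate `R(t) = λn(t) x_n(t)`.  When all rates are
`T`-periodic with a common minimal period (constants count as periodic
with every period), the flow has a unique attracting `T`-periodic orbit.
The package

- integrates trajectories with invariant-cube and ℓ1-non-expansiveness
  guarantees (`periflow.simulate`),
- computes the unique constant-rate steady state by flux-balance bisection
  (`periflow.steady_state`),
- locates the entrained orbit as the fixed point of the period map and
  reports per-site waveform amplitudes (`periflow.find_periodic_orbit`),
- certifies contraction on strict subcubes `{ε ≤ x_i ≤ 1 − ε}` via
  diagonally weighted ℓ1 matrix measures, with an exact vertex-enumeration
  verification (`periflow.certify_contraction`),
- and simulates TASEP with time-varying rates for the stochastic picture,
  including segment-averaged occupancy analysis and mean-field comparison
  (`periflow.simulate_tasep`, `periflow.compare_tasep_rfm`).

## Worked example

```python
import numpy as np
import periflow as pf

# 3-site chain, all four rates sinusoidal with minimal common period T = 6
schedule, x0 = pf.make_scenario("entrain_demo", 3, seed=1)
spec = pf.ModelSpec(3, schedule)

orbit = pf.find_periodic_orbit(spec, x0)
print("T =", schedule.T)
print("x_star =", np.round(orbit.x_star, 6))
print("amplitudes =", np.round(orbit.amplitudes, 6))

cert = pf.certify_contraction(spec, epsilon=0.1)
print("c =", round(cert.c, 6), " vertex max =", round(cert.verification_max, 6))
```

prints

```
T = 6.0
x_star = [0.509729 0.497821 0.451073]
amplitudes = [0.250156 0.18395  0.180346]
c = -0.003118  vertex max = -0.010113
```

`x_star` is the state the chain passes through at phase 0 of the entrained
cycle — every initial condition converges to the same orbit (rerun
`find_periodic_orbit` from `np.zeros(3)` and compare).  `amplitudes` are
per-site peak-to-peak occupancy swings over one period.  The certificate
says: on the subcube `0.1 ≤ x_i ≤ 0.9`, distances measured in the weighted
ℓ1 norm with weights `d` shrink at exponential rate at least
`|c| ≈ 0.0031` per time unit, and the brute-force maximum of the scaled
Jacobian measure over all subcube vertices and a period-covering time grid
(−0.0101) indeed stays below `c`.

Constant rates instead give a unique steady profile, e.g.

```python
pf.steady_state([1.0, 1.0, 1.0])   # e = (0.618034, 0.381966), flux = 0.381966
```

## Command line

```bash
periflow scenario --name entrain_demo --n 3 --seed 1 --out runs/
periflow find-orbit --config runs/entrain_demo.yaml --out runs/
periflow certify    --config runs/entrain_demo.yaml --out runs/
periflow tasep      --config runs/entrain_demo.yaml --out runs/
```

Subcommands: `simulate`, `equilibrium`, `find-orbit`, `entrain-report`,
`certify`, `tasep`, `compare`, `scenario`.  Each writes CSV/JSON artifacts
that embed the exact configuration used.

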