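"""Locating the entrained periodic orbit via the period map.

With rates that are T-periodic (and not all constant), the flow over one
period maps the unit cube continuously into itself, so a fixed point exists;
trajectories enter a strict subcube where the dynamics are contracting, so
the fixed point is unique and globally attracting.  Iterating the period map
therefore converges to the entrained orbit from any start, and the sampled
orbit over one period gives the steady periodic waveform of every site
occupancy and of the translation rate.

A degenerate but instructive special case: when all rates share one time
profile, ``lambda_i(t) = c_i g(t)``, the periodic orbit collapses to the
constant-rate equilibrium of the coefficients ``c`` (time reparametrization
leaves the phase portrait unchanged), so all waveform amplitudes vanish.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .model import ModelSpec, Trajectory, simulate, DEFAULT_RTOL, DEFAULT_ATOL

__all__ = [
    "PeriodicOrbit",
    "EntrainmentReport",
    "poincare_map",
    "find_periodic_orbit",
    "entrainment_report",
    "amplitude_profile",
    "subcube_entry",
]

DEFAULT_ORBIT_TOL = 1e-10
DEFAULT_SAMPLES_PER_PERIOD = 400
#: Periods integrated per ODE solve while iterating the period map.
_CHUNK = 16
#: Integration tolerances for the period map must sit well below the
#: fixed-point tolerance, else the iterate distances plateau at the
#: integrator's noise floor instead of contracting below tol.
ORBIT_RTOL = 1e-11
ORBIT_ATOL = 1e-13


def _require_periodic(spec: ModelSpec) -> float:
    T = spec.schedule.T
    if T is None:
        raise ValueError(
            "schedule is constant (no finite common period); use the "
            "equilibrium module for the autonomous steady state"
        )
    return T


@dataclass
class PeriodicOrbit:
    """The entrained T-periodic solution and its sampled waveform."""

    T: float
    x_star: np.ndarray
    times: np.ndarray  # phase grid over [0, T]
    waveform: np.ndarray  # shape (samples+1, n); endpoints close the orbit
    rate_waveform: np.ndarray
    amplitudes: np.ndarray  # per-site peak-to-peak
    residual: float  # l1 distance between map(x_star) and x_star
    iterations: int

    def to_csv(self, path) -> None:
        import pandas as pd

        n = self.waveform.shape[1]
        df = pd.DataFrame(
            np.column_stack([self.times, self.waveform, self.rate_waveform]),
            columns=["t"] + [f"x{i + 1}" for i in range(n)] + ["R"],
        )
        df.to_csv(path, index=False, float_format="%.12g")

    def summary_json(self, path=None) -> str:
        rec = {
            "T": self.T,
            "x_star": list(map(float, self.x_star)),
            "amplitudes": list(map(float, self.amplitudes)),
            "residual": self.residual,
            "iterations": self.iterations,
        }
        text = json.dumps(rec, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def poincare_map(
    spec: ModelSpec,
    x0: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """State one forcing period after ``x0`` (the time-T flow map).

    Maps the closed unit cube into itself; its unique fixed point is the
    initial state of the entrained orbit.
    """
    T = _require_periodic(spec)
    traj = simulate(spec, x0, 0.0, T, rtol=rtol, atol=atol, t_eval=[0.0, T])
    return traj.final_state


def find_periodic_orbit(
    spec: ModelSpec,
    x0: Optional[np.ndarray] = None,
    tol: float = DEFAULT_ORBIT_TOL,
    max_iter: int = 500,
    samples_per_period: int = DEFAULT_SAMPLES_PER_PERIOD,
    rtol: float = ORBIT_RTOL,
    atol: float = ORBIT_ATOL,
) -> PeriodicOrbit:
    """Iterate the period map from ``x0`` until it reaches its fixed point.

    Plain Picard iteration: contraction inside the strict subcube that every
    trajectory enters guarantees geometric convergence, so no acceleration
    is needed.  Successive period-map iterates are obtained from long
    integrations in chunks (cheaper than one ODE solve per period).  Raises
    if ``max_iter`` period maps do not bring successive iterates below
    ``tol`` in l1.
    """
    T = _require_periodic(spec)
    n = spec.n
    if x0 is None:
        x0 = np.full(n, 0.5)
    x = np.asarray(x0, dtype=float)
    if tol <= 0:
        raise ValueError("tol must be positive")

    iterations = 0
    converged = False
    diffs: list[float] = []
    while iterations < max_iter and not converged:
        k = min(_CHUNK, max_iter - iterations)
        traj = simulate(
            spec, x, 0.0, k * T, rtol=rtol, atol=atol,
            t_eval=np.arange(k + 1) * T,
        )
        period_states = traj.states
        step_diffs = np.abs(np.diff(period_states, axis=0)).sum(axis=1)
        diffs.extend(step_diffs.tolist())
        for j, d in enumerate(step_diffs):
            iterations += 1
            if d < tol:
                x = period_states[j + 1]
                converged = True
                break
        else:
            x = period_states[-1]
    if not converged:
        raise RuntimeError(
            f"period map did not converge below {tol} in {max_iter} "
            f"iterations; last iterate distances: {diffs[-5:]}"
        )

    x_star = x
    t_grid = np.linspace(0.0, T, samples_per_period + 1)
    orbit_traj = simulate(spec, x_star, 0.0, T, rtol=rtol, atol=atol, t_eval=t_grid)
    residual = float(np.abs(orbit_traj.final_state - x_star).sum())
    amplitudes = orbit_traj.states.max(axis=0) - orbit_traj.states.min(axis=0)
    return PeriodicOrbit(
        T=T,
        x_star=x_star,
        times=t_grid,
        waveform=orbit_traj.states,
        rate_waveform=orbit_traj.rate_output,
        amplitudes=amplitudes,
        residual=residual,
        iterations=iterations,
    )


@dataclass
class EntrainmentReport:
    """Convergence diagnostics for several starts under one periodic schedule."""

    T: float
    starts: np.ndarray  # (n_starts, n)
    period_mismatch: np.ndarray  # (n_starts, n_periods): ||x((k+1)T) - x(kT)||_1
    pairwise_final: float  # max pairwise l1 distance at the final period
    pairwise_nonincreasing: bool  # Birkhoff-style non-expansiveness check
    pairwise_series: np.ndarray  # (n_pairs, n_periods+1)

    @property
    def entrained(self) -> bool:
        return bool(self.period_mismatch[:, -1].max() < 1e-6)


def entrainment_report(
    spec: ModelSpec,
    starts: Sequence[np.ndarray],
    horizon_periods: int = 50,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> EntrainmentReport:
    """Track period-to-period mismatch and pairwise contraction for several starts.

    For each start the series ``d_k = ||x((k+1)T) - x(kT)||_1`` quantifies
    how far the trajectory still is from period-T repetition; entrainment
    drives it to zero (to a noise floor, for schedules with added noise).
    Pairwise l1 distances between trajectories at matched times must never
    increase — the flow is non-expanding in l1 — and contraction inside the
    strict subcube drives them to zero as well.
    """
    T = _require_periodic(spec)
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    if starts.shape[0] < 2:
        raise ValueError("need at least 2 starts")
    if horizon_periods < 2:
        raise ValueError("horizon must cover at least 2 periods")

    t_eval = np.arange(horizon_periods + 1) * T
    period_states = []
    for s in starts:
        traj = simulate(spec, s, 0.0, horizon_periods * T,
                        rtol=rtol, atol=atol, t_eval=t_eval)
        period_states.append(traj.states)
    period_states = np.array(period_states)  # (starts, periods+1, n)

    mism = np.abs(np.diff(period_states, axis=1)).sum(axis=2)

    m = starts.shape[0]
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    pair_series = np.array(
        [np.abs(period_states[i] - period_states[j]).sum(axis=1) for i, j in pairs]
    )
    # non-increase up to integrator tolerance
    slack = 10 * max(rtol, 1e-8)
    nonincreasing = bool(np.all(np.diff(pair_series, axis=1) <= slack))
    return EntrainmentReport(
        T=T,
        starts=starts,
        period_mismatch=mism,
        pairwise_final=float(pair_series[:, -1].max()),
        pairwise_nonincreasing=nonincreasing,
        pairwise_series=pair_series,
    )


def amplitude_profile(orbit: PeriodicOrbit) -> np.ndarray:
    """Per-site peak-to-peak amplitude of the orbit waveform."""
    return orbit.waveform.max(axis=0) - orbit.waveform.min(axis=0)


def subcube_entry(
    traj: Trajectory, epsilon: float
) -> Union[float, str]:
    """Earliest sampled time after which the state stays in the epsilon-subcube.

    The subcube is ``{x : epsilon <= x_i <= 1 - epsilon for all i}``.
    Returns the entry time, or the string ``"not entered"`` when no suffix
    of the sampled trajectory is confined to the subcube.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must lie in (0, 1/2)")
    inside = np.all(
        (traj.states >= epsilon) & (traj.states <= 1.0 - epsilon), axis=1
    )
    if not inside[-1]:
        return "not entered"
    # last index where the state is outside; entry is the sample after it
    outside = np.nonzero(~inside)[0]
    idx = 0 if outside.size == 0 else outside[-1] + 1
    if idx >= len(traj.times):
        return "not entered"
    return float(traj.times[idx])
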