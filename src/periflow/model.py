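"""The ribosome-flow vector field, its Jacobian, and trajectory integration.

The model tracks ``n`` normalized site occupancies ``x_i(t) in [0, 1]``
along an mRNA chain.  Ribosomes bind at the first site with initiation rate
``lambda_0(t)``, throttled by how full that site is, hop from site ``i`` to
``i + 1`` at rate ``lambda_i(t)`` throttled by the occupancy of the target
site, and exit from the last site at rate ``lambda_n(t)``:

    dx_1/dt = lambda_0 (1 - x_1)           - lambda_1 x_1 (1 - x_2)
    dx_i/dt = lambda_{i-1} x_{i-1} (1-x_i) - lambda_i x_i (1 - x_{i+1})
    dx_n/dt = lambda_{n-1} x_{n-1} (1-x_n) - lambda_n x_n

The translation rate (protein production proxy) is the exit flux
``R(t) = lambda_n(t) x_n(t)``.  The closed unit cube is forward invariant,
the flow is monotone (cooperative, tridiagonal), and the l1 distance between
any two trajectories is non-increasing; those structural facts are what the
downstream entrainment and contraction analyses rest on, and the test suite
asserts them numerically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .rates import RateSchedule

__all__ = [
    "ModelSpec",
    "Trajectory",
    "vector_field",
    "jacobian",
    "translation_rate",
    "simulate",
    "CUBE_GUARD",
]

logger = logging.getLogger(__name__)

#: States are clipped into [0, 1] after integration; excursions beyond this
#: tolerance are treated as integrator failures rather than round-off.
CUBE_GUARD = 1e-9

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """An n-site chain together with its rate schedule."""

    n: int
    schedule: RateSchedule

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.schedule.n != self.n:
            raise ValueError(
                f"schedule is for n = {self.schedule.n} sites, model has n = {self.n}"
            )


@dataclass
class Trajectory:
    """Sampled solution of the model: times, states, and translation rate."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n)
    rate_output: np.ndarray  # R(t) = lambda_n(t) x_n(t)
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    max_cube_excursion: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_csv(self, path) -> None:
        """Write ``t,x1,...,xn,R`` with 12 significant digits."""
        import pandas as pd

        n = self.states.shape[1]
        df = pd.DataFrame(
            np.column_stack([self.times, self.states, self.rate_output]),
            columns=["t"] + [f"x{i + 1}" for i in range(n)] + ["R"],
        )
        df.to_csv(path, index=False, float_format="%.12g")


def _check_state(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"state has shape {x.shape}, expected ({n},)")
    if np.any(x < -CUBE_GUARD) or np.any(x > 1 + CUBE_GUARD):
        raise ValueError("state outside the closed unit cube")
    return x


def vector_field(t: float, x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Right-hand side dx/dt at time ``t`` and state ``x`` in the cube."""
    n = spec.n
    x = _check_state(x, n)
    lam = spec.schedule(t)
    # flux[i] = flow across the bond between site i and site i+1
    # (flux[0] = entry flow, flux[n] = exit flow).
    flux = np.empty(n + 1)
    flux[0] = lam[0] * (1.0 - x[0])
    if n > 1:
        flux[1:n] = lam[1:n] * x[:-1] * (1.0 - x[1:])
    flux[n] = lam[n] * x[-1]
    return flux[:-1] - flux[1:]


def jacobian(t: float, x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Tridiagonal Jacobian of the vector field at ``(t, x)``.

    Off-diagonal entries are non-negative on the cube (the flow is
    cooperative/Metzler) and column sums equal
    ``(-lambda_0, 0, ..., 0, -lambda_n)``.
    """
    n = spec.n
    x = _check_state(x, n)
    lam = spec.schedule(t)
    J = np.zeros((n, n))
    for i in range(n):
        # inflow bond i (from site i-1 or entry), outflow bond i+1
        out_rate = lam[i + 1]
        if i == 0:
            d_in = -lam[0]
        else:
            J[i, i - 1] = lam[i] * (1.0 - x[i])
            d_in = -lam[i] * x[i - 1]
        if i == n - 1:
            d_out = -lam[n]
        else:
            J[i, i + 1] = out_rate * x[i]
            d_out = -out_rate * (1.0 - x[i + 1])
        J[i, i] = d_in + d_out
    return J


def translation_rate(t: float, x: np.ndarray, spec: ModelSpec) -> float:
    """Exit flux from the last site, ``lambda_n(t) x_n(t)``."""
    x = _check_state(x, spec.n)
    return float(spec.schedule.specs[-1](t) * x[-1])


def simulate(
    spec: ModelSpec,
    x0: np.ndarray,
    t0: float = 0.0,
    t_final: float = 100.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    t_eval: Optional[Sequence[float]] = None,
    sample_spacing: Optional[float] = None,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the model from ``x0`` over ``[t0, t_final]``.

    Adaptive Runge-Kutta with tight default tolerances; dense output at
    ``t_eval`` if given, else at uniform spacing ``sample_spacing``
    (default ``T/200`` for a periodic schedule, ``(t_final - t0)/200``
    otherwise).  States are clipped into the unit cube and the maximum
    excursion is recorded on the returned :class:`Trajectory`; an excursion
    beyond :data:`CUBE_GUARD` raises, since the cube is invariant for the
    exact flow and a larger violation signals an integration failure.

    Schedules with piecewise-constant noise are integrated window by
    window, restarting the solver at every refresh boundary, so the
    discontinuous rate changes never fall inside an adaptive step.
    """
    n = spec.n
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (n,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({n},)")
    if np.any(x0 < 0) or np.any(x0 > 1):
        raise ValueError("x0 must lie in the closed unit cube")
    if t_final <= t0:
        raise ValueError("t_final must exceed t0")

    if t_eval is None:
        if sample_spacing is None:
            T = spec.schedule.T
            sample_spacing = (T / 200.0) if T else (t_final - t0) / 200.0
        m = max(2, int(round((t_final - t0) / sample_spacing)) + 1)
        t_eval = np.linspace(t0, t_final, m)
    else:
        t_eval = np.asarray(t_eval, dtype=float)

    def rhs(t, x):
        # solve_ivp may probe marginally outside the cube; evaluate the
        # polynomial form as-is (it is defined everywhere).
        lam = spec.schedule(t)
        flux = np.empty(n + 1)
        flux[0] = lam[0] * (1.0 - x[0])
        if n > 1:
            flux[1:n] = lam[1:n] * x[:-1] * (1.0 - x[1:])
        flux[n] = lam[n] * x[-1]
        if not np.all(np.isfinite(flux)):
            raise FloatingPointError("non-finite rate evaluation")
        return flux[:-1] - flux[1:]

    refresh = spec.schedule.min_refresh_step()
    if refresh is None:
        sol = solve_ivp(
            rhs, (t0, t_final), x0, method=method,
            t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        times, states = sol.t, sol.y.T
    else:
        # Piecewise-constant noise makes the RHS discontinuous at window
        # boundaries; integrate window by window so each solve sees a
        # smooth RHS and the error control stays honest.
        edges = np.arange(
            np.floor(t0 / refresh), np.ceil(t_final / refresh) + 1
        ) * refresh
        breaks = np.unique(np.clip(edges, t0, t_final))
        breaks = np.concatenate([[t0], breaks, [t_final]])
        breaks = np.unique(breaks)
        states_list = []
        x = x0
        for a, b in zip(breaks[:-1], breaks[1:]):
            inner = t_eval[(t_eval > a) & (t_eval < b)]
            pts = np.unique(np.concatenate([[a], inner, [b]]))
            sol = solve_ivp(
                rhs, (a, b), x, method=method,
                t_eval=pts, rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"integration failed: {sol.message}")
            x = sol.y[:, -1]
            for tt, xx in zip(sol.t, sol.y.T):
                states_list.append((tt, xx))
        samples = dict()
        grid = {round(float(t), 12): None for t in t_eval}
        for tt, xx in states_list:
            key = round(float(tt), 12)
            if key in grid:
                samples[key] = xx
        times = np.asarray(t_eval, dtype=float)
        states = np.array([samples[round(float(t), 12)] for t in times])
    excursion = float(max(np.max(states - 1.0, initial=0.0),
                          np.max(-states, initial=0.0)))
    if excursion > CUBE_GUARD:
        raise RuntimeError(
            f"trajectory left the unit cube by {excursion:.3e} "
            f"(> guard {CUBE_GUARD:.0e}); tighten tolerances"
        )
    if excursion > 0:
        logger.debug("clipped cube excursion of %.3e", excursion)
        states = np.clip(states, 0.0, 1.0)

    lam_n = spec.schedule.specs[-1]
    R = np.array([lam_n(t) for t in times]) * states[:, -1]
    return Trajectory(
        times=times,
        states=states,
        rate_output=R,
        rtol=rtol,
        atol=atol,
        max_cube_excursion=excursion,
    )
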