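"""Time-varying initiation/elongation rates and scenario presets.

The ribosome flow model couples ``n`` site occupancies through ``n + 1``
positive rates: the initiation rate ``lambda_0`` and the transition rates
``lambda_1 .. lambda_n``.  In the periodically forced variant every rate is a
continuous (or piecewise-constant, for the noisy wrapper), strictly positive,
uniformly bounded function of time, and all non-constant rates share one
minimal common period ``T``.  Rates uniformly separated from zero are a hard
requirement: a rate that can reach zero destroys the boundary-repelling
property that keeps trajectories away from the cube faces, so bounds are
validated at construction time.

This module defines the rate primitives (:class:`RateSpec`,
:class:`RateSchedule`), period arithmetic (:func:`common_period`), bound
computation (:func:`rate_bounds`), a reproducible piecewise-constant noise
wrapper (:func:`make_noisy`) and the four scenario presets used throughout
the package (:func:`make_scenario`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "RateSpec",
    "RateSchedule",
    "IncommensurateError",
    "constant",
    "sinusoid",
    "square_wave",
    "make_noisy",
    "common_period",
    "evaluate_rates",
    "rate_bounds",
    "make_scenario",
    "SCENARIO_NAMES",
]

#: Largest denominator tried when expressing a ratio of two periods as a
#: rational number.  Ratios that cannot be matched at relative error 1e-9
#: with a denominator this small are declared incommensurate.
MAX_PERIOD_DENOMINATOR = 10_000
PERIOD_REL_TOL = 1e-9

SCENARIO_NAMES = (
    "entrain_demo",
    "rate_limited_elongation",
    "noisy_rates",
    "tasep_demo",
)


class IncommensurateError(ValueError):
    """Raised when a set of periods admits no common period."""


@lru_cache(maxsize=4096)
def _uniform_draw(seed: int, window: int, half_width: float) -> float:
    """Deterministic uniform draw on [-half_width, half_width] for one window."""
    rng = np.random.default_rng([int(seed), int(window)])
    return float(rng.uniform(-half_width, half_width))


@dataclass(frozen=True)
class RateSpec:
    """One time-varying rate function.

    Parameters
    ----------
    kind:
        ``"constant"``, ``"sinusoid"``, ``"square_wave"`` or
        ``"noisy_wrapper"``.
    baseline:
        Mean level, in events per unit time.  Must be positive.  Unused for
        the noisy wrapper (the inner spec carries it).
    amplitude:
        Peak deviation from baseline; must be strictly smaller than the
        baseline so the rate stays positive.
    period:
        Forcing period, or ``None`` for a constant rate.
    phase:
        Time offset: the waveform is evaluated at ``t - phase``.
    inner, half_width, refresh_step, seed:
        Noisy-wrapper fields: the wrapped spec, the half-width of the
        additive uniform noise, the length of the hold window over which a
        single draw is kept constant, and the RNG seed.

    The square-wave convention is ``baseline + amplitude`` on the first
    half-period ``[kT, kT + T/2)`` and ``baseline - amplitude`` on the
    second, with half-open intervals so evaluation at a discontinuity is
    unambiguous.
    """

    kind: str
    baseline: float = 1.0
    amplitude: float = 0.0
    period: Optional[float] = None
    phase: float = 0.0
    inner: Optional["RateSpec"] = None
    half_width: float = 0.0
    refresh_step: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid", "square_wave", "noisy_wrapper"):
            raise ValueError(f"unknown rate kind {self.kind!r}")
        if self.kind == "noisy_wrapper":
            if self.inner is None:
                raise ValueError("noisy_wrapper requires an inner spec")
            if self.inner.kind == "noisy_wrapper":
                raise ValueError("noisy wrappers do not nest")
            if self.half_width < 0:
                raise ValueError("noise half-width must be non-negative")
            inner_lo, _ = self.inner.bounds()
            if self.half_width >= inner_lo:
                raise ValueError(
                    f"noise half-width {self.half_width} >= inner minimum "
                    f"{inner_lo}; the rate could reach zero, which is not "
                    "allowed (rates must stay uniformly separated from zero)"
                )
            if self.refresh_step is None or self.refresh_step <= 0:
                raise ValueError("noisy_wrapper requires a positive refresh_step")
            if self.seed is None:
                raise ValueError("noisy_wrapper requires a seed")
            return
        if not np.isfinite(self.baseline) or self.baseline <= 0:
            raise ValueError(f"baseline must be positive, got {self.baseline}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.amplitude >= self.baseline:
            raise ValueError(
                f"amplitude {self.amplitude} >= baseline {self.baseline}: "
                "the rate would touch or cross zero"
            )
        if self.kind == "constant":
            if self.period is not None:
                raise ValueError("a constant spec must report period None")
        else:
            if self.period is None or self.period <= 0:
                raise ValueError(f"{self.kind} requires a positive period")

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Evaluate the rate at time(s) ``t >= 0``."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("rates are defined for t >= 0 only")
        if self.kind == "constant":
            out = np.full_like(t_arr, self.baseline)
        elif self.kind == "sinusoid":
            out = self.baseline + self.amplitude * np.sin(
                2.0 * np.pi * (t_arr - self.phase) / self.period
            )
        elif self.kind == "square_wave":
            frac = np.mod(t_arr - self.phase, self.period) / self.period
            out = np.where(
                frac < 0.5,
                self.baseline + self.amplitude,
                self.baseline - self.amplitude,
            )
        else:  # noisy_wrapper
            base = np.asarray(self.inner(t_arr), dtype=float)
            windows = np.floor(t_arr / self.refresh_step).astype(np.int64)
            noise = np.vectorize(
                lambda w: _uniform_draw(self.seed, w, self.half_width)
            )(windows) if windows.size else windows.astype(float)
            out = base + noise
        if np.isscalar(t) or np.ndim(t) == 0:
            return float(out)
        return out

    def bounds(self) -> tuple[float, float]:
        """Closed-form (infimum, supremum) of the rate over all t >= 0."""
        if self.kind == "noisy_wrapper":
            lo, hi = self.inner.bounds()
            return lo - self.half_width, hi + self.half_width
        return self.baseline - self.amplitude, self.baseline + self.amplitude

    def period_or_none(self) -> Optional[float]:
        if self.kind == "noisy_wrapper":
            return self.inner.period_or_none()
        return self.period

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        if self.kind == "noisy_wrapper":
            d = self.inner.to_dict()
            d["noise"] = {
                "half_width": self.half_width,
                "refresh_step": self.refresh_step,
                "seed": self.seed,
            }
            return d
        return {
            "kind": self.kind,
            "baseline": self.baseline,
            "amplitude": self.amplitude,
            "period": self.period,
            "phase": self.phase,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateSpec":
        allowed = {"kind", "baseline", "amplitude", "period", "phase", "noise"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown rate-spec keys: {sorted(unknown)}")
        noise = d.get("noise")
        inner = cls(
            kind=d["kind"],
            baseline=float(d.get("baseline", 1.0)),
            amplitude=float(d.get("amplitude", 0.0)),
            period=None if d.get("period") in (None, "none") else float(d["period"]),
            phase=float(d.get("phase", 0.0)),
        )
        if noise is None:
            return inner
        extra = set(noise) - {"half_width", "refresh_step", "seed"}
        if extra:
            raise ValueError(f"unknown noise keys: {sorted(extra)}")
        return make_noisy(
            inner,
            half_width=float(noise["half_width"]),
            refresh_step=float(noise["refresh_step"]),
            seed=int(noise["seed"]),
        )


def constant(baseline: float) -> RateSpec:
    return RateSpec(kind="constant", baseline=baseline)


def sinusoid(
    baseline: float, amplitude: float, period: float, phase: float = 0.0
) -> RateSpec:
    return RateSpec(
        kind="sinusoid",
        baseline=baseline,
        amplitude=amplitude,
        period=period,
        phase=phase,
    )


def square_wave(
    baseline: float, amplitude: float, period: float, phase: float = 0.0
) -> RateSpec:
    return RateSpec(
        kind="square_wave",
        baseline=baseline,
        amplitude=amplitude,
        period=period,
        phase=phase,
    )


def make_noisy(
    inner: RateSpec, half_width: float, refresh_step: float, seed: int
) -> RateSpec:
    """Wrap ``inner`` with additive uniform noise on [-half_width, half_width].

    The draw is held piecewise-constant over consecutive windows of length
    ``refresh_step`` so the ODE right-hand side stays well defined, and the
    draw for window ``k`` depends only on ``(seed, k)``, which makes sample
    paths reproducible and random-access.
    """
    return RateSpec(
        kind="noisy_wrapper",
        inner=inner,
        half_width=half_width,
        refresh_step=refresh_step,
        seed=seed,
    )


# -- period arithmetic ------------------------------------------------------


def common_period(
    periods: Sequence[Optional[float]],
    max_denominator: int = MAX_PERIOD_DENOMINATOR,
    rel_tol: float = PERIOD_REL_TOL,
) -> Optional[float]:
    """Minimal common period of the given periods.

    ``None`` entries denote constant rates, which are periodic with every
    period and therefore never constrain the result.  Returns ``None`` iff
    every entry is ``None``.  Pairs of finite periods whose ratio has no
    rational approximation with denominator <= ``max_denominator`` at
    relative error <= ``rel_tol`` raise :class:`IncommensurateError`.
    """
    finite = [p for p in periods if p is not None]
    if not periods:
        raise ValueError("need at least one period entry")
    if any(p is not None and p <= 0 for p in periods):
        raise ValueError("periods must be positive")
    if not finite:
        return None
    ref = finite[0]
    nums: list[int] = []
    dens: list[int] = []
    for p in finite:
        ratio = p / ref
        frac = Fraction(ratio).limit_denominator(max_denominator)
        if frac == 0 or abs(float(frac) - ratio) > rel_tol * ratio:
            raise IncommensurateError(
                f"periods {ref} and {p} have no rational ratio with "
                f"denominator <= {max_denominator}"
            )
        nums.append(frac.numerator)
        dens.append(frac.denominator)
    # p_i = ref * a_i / b_i; the minimal common multiple of the p_i in units
    # of ref is lcm(a_i) / gcd(b_i).
    lcm_num = 1
    for a in nums:
        lcm_num = lcm_num * a // math.gcd(lcm_num, a)
    gcd_den = dens[0]
    for b in dens[1:]:
        gcd_den = math.gcd(gcd_den, b)
    return ref * lcm_num / gcd_den


# -- schedules --------------------------------------------------------------


@dataclass(frozen=True)
class RateSchedule:
    """The n+1 rates of an n-site chain, with their common period and bounds.

    ``T`` is the minimal common period of the non-constant specs (``None``
    when all rates are constant); ``delta1``/``delta2`` are the infimum and
    supremum of all rates over one period.  Both are computed and validated
    at construction: ``delta1 > 0`` is required.
    """

    n: int
    specs: tuple[RateSpec, ...]
    T: Optional[float] = field(init=False)
    delta1: float = field(init=False)
    delta2: float = field(init=False)

    def __init__(self, n: int, specs: Sequence[RateSpec]):
        if n < 1:
            raise ValueError("need at least one site")
        specs = tuple(specs)
        if len(specs) != n + 1:
            raise ValueError(
                f"need n+1 = {n + 1} rate specs for n = {n} sites, got {len(specs)}"
            )
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "specs", specs)
        object.__setattr__(
            self, "T", common_period([s.period_or_none() for s in specs])
        )
        lo = min(s.bounds()[0] for s in specs)
        hi = max(s.bounds()[1] for s in specs)
        if lo <= 0:
            raise ValueError(
                "schedule infimum is not positive; rates must be uniformly "
                "separated from zero"
            )
        object.__setattr__(self, "delta1", float(lo))
        object.__setattr__(self, "delta2", float(hi))

    @property
    def is_periodic(self) -> bool:
        return self.T is not None

    @property
    def has_noise(self) -> bool:
        return any(s.kind == "noisy_wrapper" for s in self.specs)

    def min_refresh_step(self) -> Optional[float]:
        steps = [s.refresh_step for s in self.specs if s.kind == "noisy_wrapper"]
        return min(steps) if steps else None

    def __call__(self, t: float) -> np.ndarray:
        return evaluate_rates(self, t)

    def to_dict(self) -> dict:
        return {"n": self.n, "rates": [s.to_dict() for s in self.specs]}

    @classmethod
    def from_dict(cls, d: dict) -> "RateSchedule":
        unknown = set(d) - {"n", "rates"}
        if unknown:
            raise ValueError(f"unknown schedule keys: {sorted(unknown)}")
        return cls(int(d["n"]), [RateSpec.from_dict(r) for r in d["rates"]])


def evaluate_rates(schedule: RateSchedule, t: float) -> np.ndarray:
    """All n+1 rates at time ``t >= 0``, as a vector (lambda_0 .. lambda_n)."""
    if t < 0:
        raise ValueError("rates are defined for t >= 0 only")
    return np.array([s(t) for s in schedule.specs], dtype=float)


def rate_bounds(
    schedule: RateSchedule, grid_points: Optional[int] = None
) -> tuple[float, float]:
    """Uniform bounds (delta1, delta2) over all rates of the schedule.

    Bounds are closed-form for every supported rate kind.  When
    ``grid_points`` is given the closed-form bounds are cross-checked
    against a dense time grid over one period (or the noise refresh horizon)
    and an assertion error is raised on disagreement beyond containment;
    this exists as a belt-and-braces verification hook.
    """
    if grid_points is not None and grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    lo, hi = schedule.delta1, schedule.delta2
    if grid_points is not None:
        horizon = schedule.T if schedule.T is not None else 1.0
        ts = np.linspace(0.0, horizon, grid_points)
        vals = np.array([[s(t) for t in ts] for s in schedule.specs])
        if vals.min() < lo - 1e-12 or vals.max() > hi + 1e-12:
            raise AssertionError("grid evaluation escaped the closed-form bounds")
    return lo, hi


# -- scenario presets -------------------------------------------------------


def make_scenario(
    name: str, n: int, seed: int = 0
) -> tuple[RateSchedule, np.ndarray]:
    """A preset (schedule, initial state) pair.

    Every preset is deterministic given ``(name, n, seed)``.  The presets
    mirror four study conditions: fully periodic forcing with a common
    period (``entrain_demo``); a large periodic initiation rate feeding
    small constant, rate-limiting transition rates
    (``rate_limited_elongation``); the periodic forcing with added uniform
    noise (``noisy_rates``); and a schedule sized for the stochastic lattice
    simulator (``tasep_demo``).
    """
    if n < 2:
        raise ValueError("scenarios require n >= 2")
    rng = np.random.default_rng([int(seed), SCENARIO_NAMES.index(name)]
                                if name in SCENARIO_NAMES else [0])

    if name == "entrain_demo":
        # All rates periodic; periods drawn from divisors of T so the
        # minimal common period is exactly T.
        T = 6.0
        specs = []
        for i in range(n + 1):
            baseline = float(rng.uniform(0.8, 1.4))
            amplitude = float(rng.uniform(0.2, 0.45)) * baseline
            sub = T if i % 2 == 0 else T / 2.0
            phase = float(rng.uniform(0.0, sub))
            specs.append(sinusoid(baseline, amplitude, sub, phase))
        # Guarantee the minimal common period is T, not T/2.
        if all(abs(s.period - T) > 1e-12 for s in specs):
            specs[0] = replace(specs[0], period=T)
        x0 = rng.uniform(0.2, 0.8, size=n)
        return RateSchedule(n, specs), x0

    if name == "rate_limited_elongation":
        # Periodic initiation much faster than the constant, rate-limiting
        # transition rates; the bottleneck attenuates the oscillation as it
        # propagates down the chain.
        T = 10.0
        lam0 = sinusoid(baseline=1.0, amplitude=0.5, period=T)
        small = [constant(0.3) for _ in range(n)]
        x0 = np.full(n, 0.5)
        return RateSchedule(n, [lam0] + small), x0

    if name == "noisy_rates":
        base_sched, x0 = make_scenario("entrain_demo", n, seed)
        T = base_sched.T
        specs = [
            make_noisy(
                s,
                half_width=0.25 * s.bounds()[0],
                refresh_step=T / 20.0,
                seed=int(seed) * 1000 + i,
            )
            for i, s in enumerate(base_sched.specs)
        ]
        return RateSchedule(n, specs), x0

    if name == "tasep_demo":
        # Square-wave initiation against constant transition rates.  Hopping
        # is kept fast relative to the forcing period (site relaxation time
        # ~1/2 time unit vs T = 20) so the segment-averaged occupancies can
        # track the modulation instead of drowning it in shot noise.
        T = 20.0
        lam0 = square_wave(baseline=1.2, amplitude=0.9, period=T)
        rest = [constant(2.0) for _ in range(n)]
        x0 = np.zeros(n)
        return RateSchedule(n, [lam0] + rest), x0

    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
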