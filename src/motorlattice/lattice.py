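"""Fixed-time-step Monte Carlo simulation of motor clusters on a lattice.

The simulator advances ``N`` motors on a one-dimensional lattice with simple
exclusion under a leading-motor load.  Three modes are supported:

* ``processive`` - all motors bound for the whole run; velocity is measured
  end to end from the leading motor displacement;
* scenario ``A`` - motors bind/unbind inside a fixed window of ``M_fixed``
  sites and may swap order on rebinding;
* scenario ``B`` - the binding window tracks the cluster extent (leading
  and trailing bound motor positions plus one site either side) and the
  motor sequence is preserved on rebinding.

Observables follow the estimators used for this class of model: the
occupancy histogram of the number bound, leading-motor *episode* velocities
(displacement over one motor's tenure as leader), signed cargo run lengths
per contiguous attachment period, and the time-averaged window size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .analytic import leading_motor_rates
from .parameters import MotorParameters

__all__ = [
    "SimulationConfig",
    "LatticeState",
    "ObservableSet",
    "SimulationResult",
    "initial_width_rule",
    "initialize",
    "step",
    "run",
    "estimate_stall_force",
    "StallNotReachedError",
    "dump_trajectory",
]

_SCEN_CODE = {"processive": _kernels.PROCESSIVE, "A": _kernels.SCENARIO_A, "B": _kernels.SCENARIO_B}

#: default simulation controls: processive runs equilibrate quickly,
#: non-processive runs need longer because of the binding dynamics
_DEFAULT_STEPS = {"processive": 5_000_000, "A": 50_000_000, "B": 50_000_000}


class StallNotReachedError(RuntimeError):
    """The stall threshold was never met on the supplied force grid."""

    def __init__(self, message: str, last_velocity: float):
        super().__init__(message)
        self.last_velocity = last_velocity


def initial_width_rule(N: int) -> int:
    """Initial cargo width in lattice sites: 10 for N < 10, N + 10 above."""
    return 10 if N < 10 else N + 10


@dataclass(frozen=True)
class SimulationConfig:
    """Controls of one simulation campaign.

    ``n_steps``/``burn_in`` default to the long-run values appropriate for
    the mode (5e6 steps, 1000 burn-in for processive runs; 5e7 steps with
    2500, or 25 000 for N >= 100, for non-processive runs); tests and quick
    scans override them.
    """

    scenario: str  # "processive" | "A" | "B"
    N: int
    f: float = 0.0
    M_fixed: Optional[int] = None
    dt: float = 1e-3
    n_steps: Optional[int] = None
    burn_in: Optional[int] = None
    n_runs: int = 100
    seed: int = 0
    initial_width: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scenario not in _SCEN_CODE:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of "
                f"{sorted(_SCEN_CODE)}"
            )
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.scenario == "A" and (self.M_fixed is None or self.M_fixed < 1):
            raise ValueError("scenario A requires a window size M_fixed >= 1")

    def resolved(self) -> "SimulationConfig":
        """Fill in derived defaults (step counts, burn-in, initial width)."""
        n_steps = self.n_steps
        if n_steps is None:
            n_steps = _DEFAULT_STEPS[self.scenario]
        burn_in = self.burn_in
        if burn_in is None:
            if self.scenario == "processive":
                burn_in = 1000
            else:
                burn_in = 25_000 if self.N >= 100 else 2500
        if burn_in >= n_steps:
            raise ValueError("burn_in must be smaller than n_steps")
        width = self.initial_width
        if width is None:
            width = self.M_fixed if self.scenario == "A" else initial_width_rule(self.N)
        return replace(self, n_steps=n_steps, burn_in=burn_in, initial_width=width)

    def validate_rates(self, params: MotorParameters) -> None:
        """Check the first-order discretization condition ``rate * dt <= 0.1``.

        A product above 0.1 triggers a warning; above 1.0 the step
        probabilities are no longer probabilities and the configuration is
        rejected.
        """
        p1, q1 = leading_motor_rates(params, self.f)
        rates = {
            "p": params.p,
            "q": params.q,
            "k_on": params.k_on,
            "k_off": params.k_off,
            "p1": p1,
            "q1": q1,
        }
        worst_name = max(rates, key=lambda k: rates[k])
        worst = rates[worst_name] * self.dt
        if worst > 1.0:
            raise ValueError(
                f"rate*dt = {worst:.3g} for {worst_name} exceeds 1; reduce dt"
            )
        if worst > 0.1 + 1e-12:
            warnings.warn(
                f"rate*dt = {worst:.3g} for {worst_name} exceeds 0.1; "
                "first-order time-step bias may be noticeable",
                stacklevel=2,
            )


@dataclass
class LatticeState:
    """Instantaneous state of the lattice.

    ``positions`` are integer lattice sites per motor (motor-index order);
    unbound motors retain their last position.  ``window`` is the inclusive
    site interval currently accessible for binding; while every motor is
    detached it retains the extent from when motors were last attached.
    ``leader`` is the index of the forwardmost bound motor, or ``None``.
    """

    positions: np.ndarray
    bound: np.ndarray
    window: Tuple[int, int]
    leader: Optional[int] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.bound = np.asarray(self.bound, dtype=np.bool_)

    @property
    def n_bound(self) -> int:
        return int(self.bound.sum())

    def bound_positions(self) -> np.ndarray:
        return np.sort(self.positions[self.bound])

    def check_invariants(self, scenario: str) -> None:
        """Assert simple exclusion and (scenario B) sequence preservation."""
        bp = self.positions[self.bound]
        if np.unique(bp).size != bp.size:
            raise AssertionError("exclusion violated: two bound motors share a site")
        if scenario == "B" and bp.size > 1 and np.any(np.diff(bp) <= 0):
            raise AssertionError("sequence preservation violated")
        left, right = self.window
        if right - left + 1 < bp.size and scenario == "A":
            raise AssertionError("window shorter than the number bound")


@dataclass
class ObservableSet:
    """Observables of one replicate.

    ``episode_velocities`` are leading-motor episode velocities in steps/s
    with their durations in s; ``occupancy_counts`` the per-step histogram
    over the number bound (time-weighted for the event-driven engine, hence
    float); ``run_lengths`` signed cargo displacements per attachment period
    in sites with durations in s; ``mean_window`` the time-averaged window
    size; ``steady_state_velocity`` the end-to-end leading-motor velocity in
    steps/s.  Estimators with no completed samples are ``None``.
    """

    episode_velocities: np.ndarray
    occupancy_counts: np.ndarray
    run_lengths: np.ndarray
    mean_window: Optional[float]
    steady_state_velocity: Optional[float]
    episode_durations: Optional[np.ndarray] = None
    run_durations: Optional[np.ndarray] = None

    @property
    def episode_velocity_mean(self) -> Optional[float]:
        if self.episode_velocities.size == 0:
            return None
        return float(self.episode_velocities.mean())

    @property
    def bound_velocity(self) -> Optional[float]:
        """Duration-weighted episode velocity: leader displacement while the
        cluster is bound divided by the total bound time."""
        if self.episode_velocities.size == 0 or self.episode_durations is None:
            return None
        return float(
            (self.episode_velocities * self.episode_durations).sum()
            / self.episode_durations.sum()
        )

    @property
    def run_length_mean(self) -> Optional[float]:
        if self.run_lengths.size == 0:
            return None
        return float(self.run_lengths.mean())

    def run_velocities(self) -> np.ndarray:
        """Net cargo velocity of each attachment period (steps/s)."""
        if self.run_durations is None or self.run_lengths.size == 0:
            return np.empty(0)
        ok = self.run_durations > 0
        return self.run_lengths[ok] / self.run_durations[ok]

    @property
    def run_velocity_mean(self) -> Optional[float]:
        rv = self.run_velocities()
        if rv.size == 0:
            return None
        return float(rv.mean())

    def occupancy_probs(self) -> np.ndarray:
        total = self.occupancy_counts.sum()
        if total <= 0:
            raise ValueError("no occupancy samples recorded")
        return self.occupancy_counts / total


def _stat(values: Sequence[float]) -> Tuple[float, float, int]:
    """Mean, standard error and count of the finite entries."""
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    n = arr.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, se, n


@dataclass
class SimulationResult:
    """Replicate observables plus convenience aggregation."""

    config: SimulationConfig
    params: MotorParameters
    replicates: List[ObservableSet] = field(default_factory=list)

    # -- velocity -----------------------------------------------------------
    def episode_velocity(self) -> Tuple[float, float, int]:
        """(mean, SE, replicates used) of the replicate-mean episode velocity
        in steps/s."""
        return _stat([r.episode_velocity_mean for r in self.replicates])

    def steady_velocity(self) -> Tuple[float, float, int]:
        """(mean, SE, replicates used) of the end-to-end velocity, steps/s."""
        return _stat([r.steady_state_velocity for r in self.replicates])

    def bound_velocity(self) -> Tuple[float, float, int]:
        """(mean, SE, replicates used) of the duration-weighted episode
        velocity, steps/s."""
        return _stat([r.bound_velocity for r in self.replicates])

    def velocity(self) -> Tuple[float, float, int]:
        """Mode-appropriate cluster velocity estimator: end-to-end leader
        displacement for processive runs; for non-processive runs the
        duration-weighted episode velocity, i.e. the time average of the
        leading motor's velocity while at least one motor is bound (an
        unweighted mean over episodes down-weights long fast episodes and
        underestimates the cargo velocity)."""
        if self.config.scenario == "processive":
            return self.steady_velocity()
        return self.bound_velocity()

    # -- run length ---------------------------------------------------------
    def run_length(self) -> Tuple[float, float, int]:
        """(mean, SE, replicates used) of the replicate-mean run length, sites."""
        return _stat([r.run_length_mean for r in self.replicates])

    def run_velocity(self) -> Tuple[float, float, int]:
        """(mean, SE, replicates used) of the replicate-mean net velocity per
        attachment period, steps/s."""
        return _stat([r.run_velocity_mean for r in self.replicates])

    def run_velocity_values(self) -> np.ndarray:
        return np.concatenate([r.run_velocities() for r in self.replicates]) \
            if self.replicates else np.empty(0)

    # -- pooled distributions ----------------------------------------------
    def episode_values(self) -> np.ndarray:
        return np.concatenate([r.episode_velocities for r in self.replicates]) \
            if self.replicates else np.empty(0)

    def run_values(self) -> np.ndarray:
        return np.concatenate([r.run_lengths for r in self.replicates]) \
            if self.replicates else np.empty(0)

    def occupancy(self) -> Tuple[np.ndarray, np.ndarray]:
        """Pooled occupancy probabilities and their across-replicate SE."""
        mat = np.stack([r.occupancy_probs() for r in self.replicates])
        pooled = np.sum([r.occupancy_counts for r in self.replicates], axis=0)
        probs = pooled / pooled.sum()
        if mat.shape[0] > 1:
            se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        else:
            se = np.full(mat.shape[1], np.nan)
        return probs, se

    def mean_window(self) -> Tuple[float, float, int]:
        return _stat([r.mean_window for r in self.replicates])

    # -- unit conversion ----------------------------------------------------
    def to_um_per_s(self, steps_per_s: float) -> float:
        return steps_per_s * self.params.dx * 1e-3

    def to_um(self, sites: float) -> float:
        return sites * self.params.dx * 1e-3


def initialize(
    config: SimulationConfig, params: MotorParameters, rng: np.random.Generator
) -> LatticeState:
    """Initial lattice state.

    Processive runs start with all ``N`` motors bound at distinct uniformly
    sampled sites inside the initial cargo width; non-processive runs start
    with every motor unbound and a binding window of the configured width
    anchored at the origin.
    """
    cfg = config.resolved()
    width = int(cfg.initial_width)
    N = cfg.N
    if cfg.scenario == "processive":
        if N > width:
            raise ValueError(
                f"cannot place {N} motors at distinct sites in a width of {width}"
            )
        sites = rng.permutation(width)[:N]
        positions = np.sort(sites).astype(np.int64)
        bound = np.ones(N, dtype=np.bool_)
        leader = int(np.argmax(positions))
        return LatticeState(positions, bound, (0, width - 1), leader)
    positions = np.zeros(N, dtype=np.int64)
    bound = np.zeros(N, dtype=np.bool_)
    return LatticeState(positions, bound, (0, width - 1), None)


def step(
    state: LatticeState,
    params: MotorParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> LatticeState:
    """Advance one time step and return the new state.

    This is the same compiled kernel the long-run driver uses, exposed one
    step at a time for inspection and testing.
    """
    cfg = config.resolved()
    scen = _SCEN_CODE[cfg.scenario]
    p1, q1 = leading_motor_rates(params, cfg.f)
    pos = state.positions.copy()
    bound = state.bound.copy()
    order, rank, nb = _kernels.build_order(pos, bound)
    perm = np.empty(cfg.N, np.int64)
    cur_leader = state.leader if state.leader is not None else -1
    _kernels.seed_rng(int(rng.integers(0, 2**31 - 1)))
    wl, wr = state.window
    M_fixed = cfg.M_fixed if cfg.M_fixed is not None else 0
    nb, wl, wr, leader, *_ = _kernels._step_once(
        pos, bound, order, rank, nb, wl, wr, scen, M_fixed,
        params.p * cfg.dt, params.q * cfg.dt, p1 * cfg.dt, q1 * cfg.dt,
        params.k_on * cfg.dt, params.k_off * cfg.dt, perm, cur_leader,
    )
    return LatticeState(pos, bound, (int(wl), int(wr)),
                        int(leader) if leader >= 0 else None)


def _event_cap(cfg: SimulationConfig, params: MotorParameters) -> int:
    expected = cfg.n_steps * cfg.dt * cfg.N * (params.k_on + params.k_off)
    return int(min(2 * expected + 2000, 2e7))


def _replicate_seeds(cfg: SimulationConfig):
    root = np.random.SeedSequence(cfg.seed)
    for child in root.spawn(cfg.n_runs):
        init_seed, kern_seed = (int(s) for s in child.generate_state(2) % (2**31 - 1))
        yield init_seed, kern_seed


def run(
    config: SimulationConfig,
    params: MotorParameters,
    engine: str = "fixed",
) -> SimulationResult:
    """Run ``n_runs`` independent replicates and collect observables.

    ``engine`` selects the fixed time-step kernel (default) or the
    event-driven sampler (``"gillespie"``), which simulates the identical
    Markov process in continuous time; for the latter ``n_steps`` is
    interpreted as a total simulated time of ``n_steps * dt`` seconds.
    """
    cfg = config.resolved()
    cfg.validate_rates(params)
    if engine == "gillespie":
        from .gillespie import gillespie_run

        return gillespie_run(cfg, params)
    if engine != "fixed":
        raise ValueError(f"unknown engine {engine!r}; expected 'fixed' or 'gillespie'")

    scen = _SCEN_CODE[cfg.scenario]
    p1, q1 = leading_motor_rates(params, cfg.f)
    cap = _event_cap(cfg, params)
    result = SimulationResult(cfg, params)
    duration = (cfg.n_steps - 1 - cfg.burn_in) * cfg.dt
    for init_seed, kern_seed in _replicate_seeds(cfg):
        rng = np.random.default_rng(init_seed)
        state = initialize(cfg, params, rng)
        wl, wr = state.window
        (occ, eps, ep_durs, runs, run_durs, win_sum, measured, x_mark, x_last,
         ep_lost, run_lost) = _kernels.simulate(
            state.positions, state.bound, wl, wr, scen,
            cfg.M_fixed if cfg.M_fixed is not None else 0,
            params.p, params.q, p1, q1, params.k_on, params.k_off,
            cfg.dt, cfg.n_steps, cfg.burn_in, kern_seed, cap, cap,
        )
        if ep_lost or run_lost:
            warnings.warn(
                f"observable buffers overflowed ({ep_lost} episodes, "
                f"{run_lost} runs dropped)", stacklevel=2
            )
        steady = (x_last - x_mark) / duration if duration > 0 else None
        mean_window = win_sum / measured if measured > 0 else None
        if cfg.scenario == "processive":
            mean_window = None
        result.replicates.append(
            ObservableSet(eps, occ.astype(float), runs, mean_window, steady,
                          ep_durs, run_durs)
        )
    return result


def estimate_stall_force(
    params: MotorParameters,
    config: SimulationConfig,
    f_grid: Sequence[float],
    threshold: float = 1e-5,
    resolution: float = 0.05,
) -> float:
    """Stall force from simulation: smallest force whose measured velocity
    satisfies ``|V_f / V_0| <= threshold`` (a measured velocity at or below
    zero also qualifies - past stall the mean velocity is negative), refined
    by bisection to ``resolution`` in f.

    At large forces the backward rate of the loaded leader grows as
    ``exp(f (1-delta))``; the time step is shrunk automatically to keep
    ``rate * dt <= 0.1`` and the step count is raised to preserve the total
    simulated time.
    """
    f_grid = np.asarray(sorted(f_grid), dtype=float)
    if f_grid.size < 2 or f_grid[0] != 0.0:
        raise ValueError("f_grid must start at 0 and contain at least two forces")

    base = config.resolved()
    T_total = base.n_steps * base.dt
    T_burn = base.burn_in * base.dt

    def measure(f: float) -> float:
        p1, q1 = leading_motor_rates(params, f)
        max_rate = max(params.p, params.q, params.k_on, params.k_off, p1, q1)
        dt = min(base.dt, 0.1 / max_rate)
        n_steps = min(int(np.ceil(T_total / dt)), 100_000_000)
        burn_in = int(np.ceil(T_burn / dt))
        cfg = replace(base, f=f, dt=dt, n_steps=n_steps, burn_in=burn_in)
        v, _, _ = run(cfg, params).velocity()
        return v

    v0 = measure(0.0)
    if not np.isfinite(v0) or v0 <= 0:
        raise RuntimeError("zero-force velocity is not positive; cannot normalize")

    def stalled(v: float) -> bool:
        return v <= 0.0 or abs(v / v0) <= threshold

    v_last = v0
    hit = None
    for i, f in enumerate(f_grid[1:], start=1):
        v_last = measure(f)
        if stalled(v_last):
            hit = i
            break
    if hit is None:
        raise StallNotReachedError(
            f"stall threshold not met on the grid (last velocity {v_last:.4g} steps/s)",
            v_last,
        )
    lo, hi = f_grid[hit - 1], f_grid[hit]
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if stalled(measure(mid)):
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))


def dump_trajectory(
    config: SimulationConfig,
    params: MotorParameters,
    path: str,
    n_steps: Optional[int] = None,
) -> None:
    """Write a per-step trajectory as a gzip-compressed TSV.

    Columns: step, time_s, motor_index, position_site, bound_flag,
    is_leader.  Intended for short diagnostic runs.
    """
    import gzip

    cfg = config.resolved()
    if n_steps is not None:
        cfg = replace(cfg, n_steps=n_steps, burn_in=0)
    rng = np.random.default_rng(cfg.seed)
    state = initialize(cfg, params, rng)
    with gzip.open(path, "wt") as fh:
        fh.write("step\ttime_s\tmotor_index\tposition_site\tbound_flag\tis_leader\n")
        for t in range(cfg.n_steps):
            state = step(state, params, cfg, rng)
            for mu in range(cfg.N):
                fh.write(
                    f"{t}\t{t * cfg.dt:.6g}\t{mu}\t{state.positions[mu]}\t"
                    f"{int(state.bound[mu])}\t{int(state.leader == mu)}\n"
                )
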