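"""Event-driven (exact continuous-time) sampler of the motor-cluster chain.

This engine simulates the same Markov process as the fixed time-step
kernel - identical admissibility rules (simple exclusion, scenario A/B
binding kernels, leading-motor load) and identical observable definitions -
by drawing exponential waiting times from the total admissible rate and
selecting events proportionally to their rates.  It is the correctness
oracle for the fixed-step engine: the fixed-step method carries an O(dt)
discretization bias, the event-driven method none.

The rate table is rebuilt after every event.  That is O(N) work per event
and entirely adequate at the cluster sizes where the oracle is used; the
production engine remains the compiled fixed-step kernel.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .analytic import leading_motor_rates
from .lattice import (
    LatticeState,
    ObservableSet,
    SimulationConfig,
    SimulationResult,
    _replicate_seeds,
    initialize,
)
from .parameters import MotorParameters

__all__ = ["gillespie_run"]

# event kinds
_UNBIND, _FWD, _BWD, _BIND = 0, 1, 2, 3


def _admissible_bind(pos, bound, mu, wl, wr, scenario) -> Tuple[int, int, float]:
    """Return (lo, hi, weight) for motor mu's binding attempt.

    ``weight`` multiplies k_on: scenario A scales by the fraction of free
    window sites (per-site binding); scenario B succeeds at full rate when
    an admissible site exists.  ``(lo, hi)`` is the interval to draw the
    site from; scenario A draws from the free window sites instead.
    """
    N = pos.shape[0]
    if scenario == "A":
        M = wr - wl + 1
        n = int(bound.sum())
        return wl, wr, max(M - n, 0) / M
    lidx = -1
    for k in range(mu - 1, -1, -1):
        if bound[k]:
            lidx = k
            break
    uidx = -1
    for k in range(mu + 1, N):
        if bound[k]:
            uidx = k
            break
    if lidx >= 0 and uidx >= 0:
        lo, hi = pos[lidx] + 1, pos[uidx] - 1
    elif uidx >= 0:
        lo = hi = pos[uidx] - 1
    elif lidx >= 0:
        lo = hi = pos[lidx] + 1
    else:
        lo, hi = wl, wr
    return int(lo), int(hi), 1.0 if hi >= lo else 0.0


def _draw_site_A(pos, bound, wl, wr, rng) -> Optional[int]:
    occupied = {int(p) for p in pos[bound]}
    free = [s for s in range(wl, wr + 1) if s not in occupied]
    if not free:
        return None
    return int(free[rng.integers(0, len(free))])


def _gillespie_replicate(
    cfg: SimulationConfig,
    params: MotorParameters,
    state: LatticeState,
    rng: np.random.Generator,
    record_times: bool = False,
) -> Tuple[ObservableSet, Optional[np.ndarray]]:
    scenario = cfg.scenario
    N = cfg.N
    p1, q1 = leading_motor_rates(params, cfg.f)
    T = cfg.n_steps * cfg.dt
    t_burn = cfg.burn_in * cfg.dt
    pos = state.positions.copy()
    bound = state.bound.copy()
    wl, wr = state.window

    occ = np.zeros(N + 1, dtype=float)
    win_time = 0.0
    meas_time = 0.0
    episodes: List[float] = []
    episode_durs: List[float] = []
    run_lengths: List[float] = []
    run_durs: List[float] = []
    times: List[float] = []

    def leader_of() -> int:
        if not bound.any():
            return -1
        idx = np.flatnonzero(bound)
        return int(idx[np.argmax(pos[idx])])

    cur_leader = leader_of()
    ep_t = 0.0
    ep_x = pos[cur_leader] if cur_leader >= 0 else 0
    run_open = bound.any()
    run_x = int(pos[bound].min()) if run_open else 0
    run_t = 0.0
    x_last = pos[cur_leader] if cur_leader >= 0 else 0
    x_mark = x_last
    marked = False

    t = 0.0
    while t < T:
        # ---- build rate table -------------------------------------------
        kinds: List[Tuple[int, int, int, int]] = []  # (kind, mu, lo, hi)
        rates: List[float] = []
        occupied = {int(p) for p in pos[bound]}
        leader = cur_leader
        for mu in range(N):
            if bound[mu]:
                pf, pb = (p1, q1) if mu == leader else (params.p, params.q)
                if scenario != "processive" and params.k_off > 0:
                    kinds.append((_UNBIND, mu, 0, 0))
                    rates.append(params.k_off)
                if pf > 0 and (pos[mu] + 1) not in occupied:
                    kinds.append((_FWD, mu, 0, 0))
                    rates.append(pf)
                if pb > 0 and (pos[mu] - 1) not in occupied:
                    kinds.append((_BWD, mu, 0, 0))
                    rates.append(pb)
            elif scenario != "processive" and params.k_on > 0:
                lo, hi, w = _admissible_bind(pos, bound, mu, wl, wr, scenario)
                if w > 0:
                    kinds.append((_BIND, mu, lo, hi))
                    rates.append(params.k_on * w)
        total = float(sum(rates))
        if total <= 0.0:
            # frozen state: advance to the horizon, record partial observables
            lo_t, hi_t = max(t, t_burn), T
            if hi_t > lo_t:
                occ[int(bound.sum())] += hi_t - lo_t
                win_time += (wr - wl + 1) * (hi_t - lo_t)
                meas_time += hi_t - lo_t
            if not marked and cur_leader >= 0:
                x_mark = pos[cur_leader]
                marked = True
            t = T
            break
        tau = rng.exponential(1.0 / total)
        t_next = t + tau
        # time-weighted accumulation over [t, min(t_next, T)] within window
        hi_t = min(t_next, T)
        lo_t = max(t, t_burn)
        if hi_t > lo_t:
            occ[int(bound.sum())] += hi_t - lo_t
            win_time += (wr - wl + 1) * (hi_t - lo_t)
            meas_time += hi_t - lo_t
        if not marked and t_next >= t_burn:
            x_mark = pos[cur_leader] if cur_leader >= 0 else x_last
            marked = True
        if t_next >= T:
            t = T
            break
        t = t_next
        if record_times:
            times.append(t)

        # ---- select and apply an event ----------------------------------
        u = rng.random() * total
        acc = 0.0
        idx = len(rates) - 1
        for i, r in enumerate(rates):
            acc += r
            if u < acc:
                idx = i
                break
        kind, mu, lo, hi = kinds[idx]
        if kind == _FWD:
            pos[mu] += 1
        elif kind == _BWD:
            pos[mu] -= 1
        elif kind == _UNBIND:
            bound[mu] = False
            if not bound.any() and run_open:
                if t >= t_burn:
                    run_lengths.append(float(pos[mu] - run_x))
                    run_durs.append(t - run_t)
                run_open = False
        else:  # _BIND
            if scenario == "A":
                site = _draw_site_A(pos, bound, wl, wr, rng)
                if site is None:
                    continue
            else:
                site = int(rng.integers(lo, hi + 1))
            was_empty = not bound.any()
            pos[mu] = site
            bound[mu] = True
            if was_empty:
                run_open = True
                run_x = site
                run_t = t

        # ---- post-event updates (window, leader, episodes) --------------
        if bound.any():
            bp = pos[bound]
            if scenario == "A":
                wl = int(bp.min())
                if int(bp.max()) - wl >= cfg.M_fixed:
                    wl = int(bp.max()) - cfg.M_fixed + 1
                wr = wl + cfg.M_fixed - 1
            elif scenario == "B":
                wl, wr = int(bp.min()) - 1, int(bp.max()) + 1
        new_leader = leader_of()
        if new_leader != cur_leader:
            if cur_leader >= 0 and t > ep_t and t >= t_burn:
                episodes.append(float((pos[cur_leader] - ep_x) / (t - ep_t)))
                episode_durs.append(t - ep_t)
            cur_leader = new_leader
            ep_t = t
            ep_x = pos[cur_leader] if cur_leader >= 0 else 0
        if cur_leader >= 0:
            x_last = pos[cur_leader]

    steady = None
    if T > t_burn:
        steady = float((x_last - x_mark) / (T - t_burn))
    mean_window = win_time / meas_time if meas_time > 0 else None
    if scenario == "processive":
        mean_window = None
    obs = ObservableSet(
        np.asarray(episodes, dtype=float),
        occ,
        np.asarray(run_lengths, dtype=float),
        mean_window,
        steady,
        np.asarray(episode_durs, dtype=float),
        np.asarray(run_durs, dtype=float),
    )
    return obs, (np.asarray(times) if record_times else None)


def gillespie_run(config: SimulationConfig, params: MotorParameters) -> SimulationResult:
    """Event-driven counterpart of :func:`motorlattice.lattice.run`.

    ``n_steps`` is interpreted as a total simulated time of
    ``n_steps * dt`` seconds so configurations are directly comparable
    between engines.
    """
    cfg = config.resolved()
    result = SimulationResult(cfg, params)
    for init_seed, kern_seed in _replicate_seeds(cfg):
        rng_init = np.random.default_rng(init_seed)
        state = initialize(cfg, params, rng_init)
        rng = np.random.default_rng(kern_seed)
        obs, _ = _gillespie_replicate(cfg, params, state, rng)
        result.replicates.append(obs)
    return result
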