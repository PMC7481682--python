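"""Compiled fixed-time-step Monte Carlo kernels.

One simulation step has two phases.  Phase 1 (non-processive runs only)
visits every motor in a fresh random order: a bound motor unbinds with
probability ``k_off dt``; an unbound motor attempts to bind with
probability ``k_on dt`` and, if the attempt succeeds, is placed on an
admissible lattice site.  Phase 2 visits the motors again in a fresh random
order and lets each bound motor try a forward step (``p dt``) or, mutually
exclusively, a backward step (``q dt``); the leading motor - the
forwardmost bound motor, fixed for the duration of the phase - uses the
load-modified rates.  Moves onto occupied sites fail silently (simple
exclusion).

Binding kernels:

* scenario A (fixed window of ``M`` sites, swapping allowed): the attempt
  succeeds with probability ``(M - n)/M`` - the per-motor rate of the
  limited-binding-site master equation with per-site binding ``k_on/M`` -
  and the motor lands uniformly on one of the free window sites;
* scenario B (variable window, sequence preserved): the attempt succeeds
  whenever the motor has at least one admissible site - an unoccupied site
  strictly between its nearest bound neighbours by motor index, or the
  single site just behind (ahead of) the rearmost (forwardmost) bound motor
  for motors at the ends - and the site is drawn uniformly from those.  With
  no motor bound, the attempt targets the window retained from when motors
  were last attached.

Bound motors are kept in an order/rank index sorted by position, which
exclusion preserves under stepping; binding and unbinding maintain it by
insertion.  The kernel RNG is numba's internal generator, seeded per
replicate.
"""

import numpy as np
from numba import njit

# scenario codes
PROCESSIVE = 0
SCENARIO_A = 1
SCENARIO_B = 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _permute(perm):
    n = perm.shape[0]
    for i in range(n):
        perm[i] = i
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = perm[i]
        perm[i] = perm[j]
        perm[j] = tmp


@njit(cache=True)
def _insert_bound(pos, order, rank, nb, mu):
    """Insert motor mu into the position-sorted bound order; returns new nb."""
    x = pos[mu]
    lo = 0
    hi = nb
    while lo < hi:
        mid = (lo + hi) // 2
        if pos[order[mid]] < x:
            lo = mid + 1
        else:
            hi = mid
    for k in range(nb, lo, -1):
        order[k] = order[k - 1]
        rank[order[k]] = k
    order[lo] = mu
    rank[mu] = lo
    return nb + 1


@njit(cache=True)
def _remove_bound(order, rank, nb, mu):
    k = rank[mu]
    for i in range(k, nb - 1):
        order[i] = order[i + 1]
        rank[order[i]] = i
    rank[mu] = -1
    return nb - 1


@njit(cache=True)
def _site_occupied(pos, order, nb, site):
    lo = 0
    hi = nb - 1
    while lo <= hi:
        mid = (lo + hi) // 2
        x = pos[order[mid]]
        if x == site:
            return True
        if x < site:
            lo = mid + 1
        else:
            hi = mid - 1
    return False


@njit(cache=True)
def _binding_phase(pos, bound, order, rank, nb, wl, wr, scen,
                   kon_dt, koff_dt, perm):
    """Visit all motors in random order for binding/unbinding.

    Returns (nb, attach, attach_pos, detach, detach_pos) where attach/detach
    flag transitions of the bound count through zero (opening/closing an
    attachment period).  Within one phase at most one detachment-to-zero can
    precede at most one re-attachment.
    """
    N = pos.shape[0]
    attach = False
    attach_pos = 0
    detach = False
    detach_pos = 0
    _permute(perm)
    for idx in range(N):
        mu = perm[idx]
        u = np.random.random()
        if bound[mu]:
            if u < koff_dt:
                bound[mu] = False
                nb = _remove_bound(order, rank, nb, mu)
                if nb == 0:
                    detach = True
                    detach_pos = pos[mu]
        elif u < kon_dt:
            if scen == SCENARIO_A:
                # per-site binding: the attempt succeeds with probability
                # (M - n)/M and lands uniformly on a free window site
                M = wr - wl + 1
                if nb < M and u < kon_dt * (M - nb) / M:
                    in_win = 0
                    for k in range(nb):
                        if wl <= pos[order[k]] <= wr:
                            in_win += 1
                    free = M - in_win
                    if free > 0:
                        pick = np.random.randint(0, free)
                        site = wl - 1
                        seen = -1
                        while seen < pick:
                            site += 1
                            if not _site_occupied(pos, order, nb, site):
                                seen += 1
                        pos[mu] = site
                        bound[mu] = True
                        if nb == 0 and not attach:
                            attach = True
                            attach_pos = site
                        nb = _insert_bound(pos, order, rank, nb, mu)
            else:  # scenario B: sequence-preserving binding
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
                    lo = pos[lidx] + 1
                    hi = pos[uidx] - 1
                elif uidx >= 0:
                    lo = pos[uidx] - 1
                    hi = lo
                elif lidx >= 0:
                    lo = pos[lidx] + 1
                    hi = lo
                else:
                    lo = wl
                    hi = wr
                cnt = hi - lo + 1
                if cnt > 0:
                    site = lo + np.random.randint(0, cnt)
                    pos[mu] = site
                    bound[mu] = True
                    if nb == 0 and not attach:
                        attach = True
                        attach_pos = site
                    nb = _insert_bound(pos, order, rank, nb, mu)
    return nb, attach, attach_pos, detach, detach_pos


@njit(cache=True)
def _stepping_phase(pos, bound, order, rank, nb, leader,
                    p_dt, q_dt, p1_dt, q1_dt, perm):
    N = pos.shape[0]
    _permute(perm)
    for idx in range(N):
        mu = perm[idx]
        if not bound[mu]:
            continue
        if mu == leader:
            pf = p1_dt
            pb = q1_dt
        else:
            pf = p_dt
            pb = q_dt
        u = np.random.random()
        if u < pf:
            r = rank[mu]
            tgt = pos[mu] + 1
            if r == nb - 1 or pos[order[r + 1]] != tgt:
                pos[mu] = tgt
        elif u < pf + pb:
            r = rank[mu]
            tgt = pos[mu] - 1
            if r == 0 or pos[order[r - 1]] != tgt:
                pos[mu] = tgt


@njit(cache=True)
def _update_window(pos, order, nb, wl, wr, scen, M_fixed):
    """End-of-step window update; retained unchanged while all are unbound."""
    if nb == 0 or scen == PROCESSIVE:
        return wl, wr
    if scen == SCENARIO_A:
        # co-moving window: left edge tracks the rearmost bound motor but
        # shifts forward as needed to keep the leading bound motor inside,
        # so all n bound motors occupy window sites and the per-motor
        # binding rate is exactly k_on (M - n)/M
        left = pos[order[0]]
        lead = pos[order[nb - 1]]
        if lead - left >= M_fixed:
            left = lead - M_fixed + 1
        return left, left + M_fixed - 1
    return pos[order[0]] - 1, pos[order[nb - 1]] + 1


@njit(cache=True)
def _step_once(pos, bound, order, rank, nb, wl, wr, scen, M_fixed,
               p_dt, q_dt, p1_dt, q1_dt, kon_dt, koff_dt, perm, cur_leader):
    """Advance one time step.

    Returns (nb, wl, wr, leader, x_close, x_open, attach, attach_pos,
    detach, detach_pos).  ``x_close``/``x_open`` are the positions of the
    outgoing/incoming leading motor sampled at the phase boundary (-1 when
    leadership did not change on that side).
    """
    attach = False
    attach_pos = 0
    detach = False
    detach_pos = 0
    if scen != PROCESSIVE:
        nb, attach, attach_pos, detach, detach_pos = _binding_phase(
            pos, bound, order, rank, nb, wl, wr, scen, kon_dt, koff_dt, perm
        )
    leader = order[nb - 1] if nb > 0 else -1
    x_close = -1
    x_open = -1
    if leader != cur_leader:
        if cur_leader >= 0:
            x_close = pos[cur_leader]
        if leader >= 0:
            x_open = pos[leader]
    if nb > 0:
        _stepping_phase(pos, bound, order, rank, nb, leader,
                        p_dt, q_dt, p1_dt, q1_dt, perm)
    wl, wr = _update_window(pos, order, nb, wl, wr, scen, M_fixed)
    return nb, wl, wr, leader, x_close, x_open, attach, attach_pos, detach, detach_pos


@njit(cache=True)
def simulate(pos, bound, wl, wr, scen, M_fixed,
             p, q, p1, q1, kon, koff, dt, n_steps, burn_in, seed,
             ep_cap, run_cap):
    """Run the fixed-step chain and accumulate observables.

    Returns (occ, episode_velocities, run_lengths, window_sum,
    measured_steps, x_mark, x_last, ep_lost, run_lost).  Velocities are in
    steps/s, run lengths in sites; ``x_mark``/``x_last`` are the leading
    motor positions at the burn-in boundary and at the end (for the
    end-to-end steady-state velocity estimator).
    """
    np.random.seed(seed)
    N = pos.shape[0]
    order = np.empty(N, np.int64)
    rank = np.full(N, -1, np.int64)
    nb = 0
    for mu in range(N):
        if bound[mu]:
            nb = _insert_bound(pos, order, rank, nb, mu)
    perm = np.empty(N, np.int64)
    p_dt = p * dt
    q_dt = q * dt
    p1_dt = p1 * dt
    q1_dt = q1 * dt
    kon_dt = kon * dt
    koff_dt = koff * dt

    occ = np.zeros(N + 1, np.int64)
    ep_vals = np.empty(ep_cap, np.float64)
    ep_durs = np.empty(ep_cap, np.float64)
    ep_n = 0
    ep_lost = 0
    run_vals = np.empty(run_cap, np.float64)
    run_durs = np.empty(run_cap, np.float64)
    run_n = 0
    run_lost = 0
    win_sum = 0.0
    measured = 0

    cur_leader = order[nb - 1] if nb > 0 else -1
    ep_t = 0
    ep_x = pos[cur_leader] if cur_leader >= 0 else 0
    run_open = nb > 0
    run_x = pos[order[0]] if nb > 0 else 0
    run_t = 0
    x_last = pos[cur_leader] if cur_leader >= 0 else 0
    x_mark = x_last

    for t in range(n_steps):
        (nb, wl, wr, leader, x_close, x_open,
         attach, a_pos, detach, d_pos) = _step_once(
            pos, bound, order, rank, nb, wl, wr, scen, M_fixed,
            p_dt, q_dt, p1_dt, q1_dt, kon_dt, koff_dt, perm, cur_leader)
        if leader != cur_leader:
            if cur_leader >= 0 and t > ep_t and t >= burn_in:
                dur = (t - ep_t) * dt
                if ep_n < ep_cap:
                    ep_vals[ep_n] = (x_close - ep_x) / dur
                    ep_durs[ep_n] = dur
                    ep_n += 1
                else:
                    ep_lost += 1
            cur_leader = leader
            ep_t = t
            ep_x = x_open
        if detach:
            if run_open and t >= burn_in:
                if run_n < run_cap:
                    run_vals[run_n] = d_pos - run_x
                    run_durs[run_n] = (t - run_t) * dt
                    run_n += 1
                else:
                    run_lost += 1
            run_open = False
        if attach:
            run_open = True
            run_x = a_pos
            run_t = t
        if cur_leader >= 0:
            x_last = pos[cur_leader]
        if t >= burn_in:
            occ[nb] += 1
            win_sum += wr - wl + 1
            measured += 1
        if t == burn_in:
            x_mark = x_last
    return (occ, ep_vals[:ep_n].copy(), ep_durs[:ep_n].copy(),
            run_vals[:run_n].copy(), run_durs[:run_n].copy(),
            win_sum, measured, x_mark, x_last, ep_lost, run_lost)


def build_order(pos, bound):
    """Python helper: position-sorted order/rank arrays for a state."""
    N = pos.shape[0]
    order = np.empty(N, np.int64)
    rank = np.full(N, -1, np.int64)
    idx = np.flatnonzero(bound)
    srt = idx[np.argsort(pos[idx], kind="stable")]
    nb = srt.size
    order[:nb] = srt
    for r, mu in enumerate(srt):
        rank[mu] = r
    return order, rank, nb
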