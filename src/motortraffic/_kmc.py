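"""Event-driven kinetic Monte Carlo core for the multi-lane exclusion process.

The hot loop is numba-compiled and works purely on primitive arrays; all
object construction happens in :mod:`motortraffic.lattice_sim`.

Algorithm: rejection-based exact continuous-time kinetic Monte Carlo.  The
total event rate is bounded by

    R = ka_site * n_lanes * n_sites  +  n_bound * (p + max(w_d, w_dc))

Waiting times are exponential with rate R; each event is then an attachment
attempt at a uniformly chosen (lane, site), or an action attempt of a
uniformly chosen bound motor.  Attempts that are not allowed in the current
configuration (footprint occupied, step blocked, wrong detachment channel)
are resolved as null events, which leaves the sampled continuous-time
process exact.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by run_kmc
OK = 0
RUN_OVERFLOW = 1
SNAP_OVERFLOW = 2


@njit(cache=True)
def run_kmc(
    seed,
    n_lanes,
    n_sites,
    foot,
    block,
    p,
    w_d,
    w_dc,
    ka_site,
    duration,
    ring,
    langmuir,
    n_fixed_per_lane,
    snap_times,
    run_lane,
    run_bt,
    run_ut,
    run_bs,
    run_us,
    run_cens,
    snap_idx,
    snap_lane,
    snap_site,
):
    """Simulate the lattice gas; fill run/snapshot arrays in place.

    A motor's footprint covers ``foot`` consecutive sites; ``m_front`` holds
    the physical front site (wrapped on a ring) while ``m_steps`` counts net
    steps so displacements stay well defined across the ring seam.  ``block``
    is the number of sites beyond the target that must also be empty
    (interaction range in sites).

    Returns (n_runs, n_snap_entries, status).
    """
    np.random.seed(seed)
    occ = np.zeros((n_lanes, n_sites), np.uint8)
    max_m = (n_lanes * n_sites) // foot + 1
    m_lane = np.zeros(max_m, np.int64)
    m_front = np.zeros(max_m, np.int64)
    m_steps = np.zeros(max_m, np.int64)
    m_bt = np.zeros(max_m, np.float64)
    m_bs = np.zeros(max_m, np.int64)
    n_m = 0
    run_n = 0
    snap_n = 0
    run_cap = run_lane.shape[0]
    snap_cap = snap_idx.shape[0]
    n_snaps = snap_times.shape[0]
    next_snap = 0

    # fixed initial motors (ring ensembles without Langmuir exchange),
    # evenly spaced per lane
    if n_fixed_per_lane > 0:
        for lane in range(n_lanes):
            for k in range(n_fixed_per_lane):
                rear = (k * n_sites) // n_fixed_per_lane
                front = rear + foot - 1
                if ring:
                    front = front % n_sites
                for j in range(foot):
                    s = rear + j
                    if ring:
                        s = s % n_sites
                    occ[lane, s] = 1
                m_lane[n_m] = lane
                m_front[n_m] = front
                m_steps[n_m] = 0
                m_bt[n_m] = 0.0
                m_bs[n_m] = front
                n_m += 1

    w_max = max(w_d, w_dc) if langmuir else 0.0
    bound_rate = p + w_max
    r_att = ka_site * n_lanes * n_sites if langmuir else 0.0

    t = 0.0
    while True:
        total = r_att + n_m * bound_rate
        if total <= 0.0:
            t = duration
        else:
            t += np.random.exponential(1.0 / total)

        # emit snapshots scheduled before the next event time: the state is
        # constant on the inter-event interval
        while next_snap < n_snaps and snap_times[next_snap] <= t:
            if snap_n + n_m > snap_cap:
                return run_n, snap_n, SNAP_OVERFLOW
            for i in range(n_m):
                snap_idx[snap_n] = next_snap
                snap_lane[snap_n] = m_lane[i]
                snap_site[snap_n] = m_front[i]
                snap_n += 1
            next_snap += 1

        if t >= duration:
            break

        u = np.random.random() * total
        if u < r_att:
            # attachment attempt at a uniformly chosen footprint rear site
            lane = np.random.randint(n_lanes)
            rear = np.random.randint(n_sites)
            ok = True
            if not ring and rear + foot > n_sites:
                ok = False
            else:
                for j in range(foot):
                    s = rear + j
                    if ring:
                        s = s % n_sites
                    if occ[lane, s] != 0:
                        ok = False
                        break
            if ok:
                front = rear + foot - 1
                if ring:
                    front = front % n_sites
                for j in range(foot):
                    s = rear + j
                    if ring:
                        s = s % n_sites
                    occ[lane, s] = 1
                m_lane[n_m] = lane
                m_front[n_m] = front
                m_steps[n_m] = 0
                m_bt[n_m] = t
                m_bs[n_m] = front
                n_m += 1
            continue

        if n_m == 0:
            continue
        k = int((u - r_att) / bound_rate)
        if k >= n_m:
            k = n_m - 1
        lane = m_lane[k]
        front = m_front[k]

        # constrained test: the target site plus `block` further sites must
        # be empty (sites beyond an open end count as empty)
        can_step = True
        for j in range(1, block + 2):
            s = front + j
            if ring:
                s = s % n_sites
            elif s >= n_sites:
                break
            if occ[lane, s] != 0:
                can_step = False
                break

        r2 = np.random.random() * bound_rate
        detach = False
        censored = False
        if can_step:
            if r2 < p:
                if not ring and front + 1 >= n_sites:
                    # front leaves the lattice: remove, censored run
                    detach = True
                    censored = True
                else:
                    rear = front - foot + 1
                    if ring:
                        occ[lane, rear % n_sites] = 0
                        front = (front + 1) % n_sites
                        occ[lane, front] = 1
                    else:
                        occ[lane, rear] = 0
                        front = front + 1
                        occ[lane, front] = 1
                    m_front[k] = front
                    m_steps[k] += 1
            elif langmuir and r2 < p + w_d:
                detach = True
        else:
            if langmuir and r2 < w_dc:
                detach = True

        if detach:
            if run_n >= run_cap:
                return run_n, snap_n, RUN_OVERFLOW
            run_lane[run_n] = lane
            run_bt[run_n] = m_bt[k]
            run_ut[run_n] = t
            run_bs[run_n] = m_bs[k]
            run_us[run_n] = m_bs[k] + m_steps[k]
            run_cens[run_n] = 1 if censored else 0
            run_n += 1
            for j in range(foot):
                s = m_front[k] - j
                if ring:
                    s = s % n_sites
                occ[lane, s] = 0
            n_m -= 1
            if k != n_m:
                m_lane[k] = m_lane[n_m]
                m_front[k] = m_front[n_m]
                m_steps[k] = m_steps[n_m]
                m_bt[k] = m_bt[n_m]
                m_bs[k] = m_bs[n_m]

    # motors still bound at the end of the observation window
    for i in range(n_m):
        if run_n >= run_cap:
            return run_n, snap_n, RUN_OVERFLOW
        run_lane[run_n] = m_lane[i]
        run_bt[run_n] = m_bt[i]
        run_ut[run_n] = duration
        run_bs[run_n] = m_bs[i]
        run_us[run_n] = m_bs[i] + m_steps[i]
        run_cens[run_n] = 1
        run_n += 1

    return run_n, snap_n, OK
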