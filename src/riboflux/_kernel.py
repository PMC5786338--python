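"""Numba event loop for the exclusion-process translation simulator.

The kernel implements a continuous-time Markov jump process over ribosome
configurations on a single transcript, using per-ribosome exponential
clocks (next-reaction bookkeeping).  A blocked ribosome carries a
suspended clock (+inf) that is redrawn the moment the site ahead opens;
by memorylessness of the exponential distribution the redraw is exact.

Snapshots are taken on a regular *time* grid so that they are unbiased
draws from the time-stationary distribution (states sampled at event
boundaries would instead follow the jump-chain law, which overweights
fast-exiting configurations).  The grid spacing is ``interval`` times
the mean inter-event time measured during burn-in, preserving the
"one snapshot per ~interval reaction events" thinning intent.

All randomness flows through ``np.random.seed(seed)`` inside the jitted
function, so a (model, config, seed) triple reproduces the identical
event stream.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_tasep(
    seed,
    alpha,
    lam,            # float64[L + 1]; lam[i] = rate at A-site position i (1-based)
    ell,            # exclusion length in codons
    dropoff,        # per-elongation-event unbinding probability
    burn_in,        # reaction events discarded before statistics start
    n_snap,         # snapshots to record
    interval,       # target reaction events between snapshots
    max_ribs,
):
    L = lam.shape[0] - 1
    np.random.seed(seed)

    pos = np.zeros(max_ribs, dtype=np.int64)      # ascending A-site positions
    tnext = np.zeros(max_ribs, dtype=np.float64)  # pending event time; inf = blocked
    entry = np.zeros(max_ribs, dtype=np.float64)  # time the A-site entered pos[j]
    n = 0
    t = 0.0
    INF = np.inf

    snapshots = np.zeros((n_snap, max_ribs), dtype=np.int32)
    snap_n = np.zeros(n_snap, dtype=np.int32)
    dwell_sum = np.zeros(L + 1, dtype=np.float64)
    dwell_cnt = np.zeros(L + 1, dtype=np.int64)

    t_init = np.random.exponential(1.0 / alpha)

    n_term = 0
    n_init = 0
    n_drop = 0
    t_stats_start = 0.0
    collecting = False
    dt_snap = 0.0
    next_snap = INF
    n_collected = 0

    events = 0
    max_events = burn_in + 200 * n_snap * interval + 1000

    while events < max_events:
        # --- find next reaction -------------------------------------------
        tmin = t_init
        jmin = -1                      # -1 encodes initiation
        for j in range(n):
            if tnext[j] < tmin:
                tmin = tnext[j]
                jmin = j
        if not np.isfinite(tmin):
            break                      # alpha == 0 and lattice empty

        # --- emit any snapshots due before this event ---------------------
        if collecting:
            while next_snap <= tmin and n_collected < n_snap:
                for j in range(n):
                    snapshots[n_collected, j] = pos[j]
                snap_n[n_collected] = n
                n_collected += 1
                next_snap += dt_snap
            if n_collected >= n_snap:
                t = next_snap - dt_snap  # end of the sampled window
                break

        t = tmin

        if jmin == -1:
            # --- initiation: A-site lands on codon 2 ----------------------
            for j in range(n, 0, -1):
                pos[j] = pos[j - 1]
                tnext[j] = tnext[j - 1]
                entry[j] = entry[j - 1]
            pos[0] = 2
            entry[0] = t
            n += 1
            if collecting:
                n_init += 1
            if n > 1 and pos[1] - 2 <= ell:
                tnext[0] = INF
            else:
                tnext[0] = t + np.random.exponential(1.0 / lam[2])
            # re-arm only once codon 2 clears the incoming footprint
            t_init = INF
        else:
            j = jmin
            i = pos[j]
            if collecting:
                dwell_sum[i] += t - entry[j]
                dwell_cnt[i] += 1
            if i == L:
                # --- termination (ribosome at L is always the front one) --
                n -= 1
                if collecting:
                    n_term += 1
            else:
                # --- elongation hop i -> i + 1 ----------------------------
                pos[j] = i + 1
                entry[j] = t
                dropped = False
                if dropoff > 0.0 and np.random.random() < dropoff:
                    dropped = True
                    if collecting:
                        n_drop += 1
                    for k in range(j, n - 1):
                        pos[k] = pos[k + 1]
                        tnext[k] = tnext[k + 1]
                        entry[k] = entry[k + 1]
                    n -= 1
                if not dropped:
                    if j < n - 1 and pos[j + 1] - pos[j] <= ell:
                        tnext[j] = INF
                    else:
                        tnext[j] = t + np.random.exponential(1.0 / lam[pos[j]])
            # trailing neighbour may have just been unblocked
            if j > 0 and not np.isfinite(tnext[j - 1]):
                if j == n or pos[j] - pos[j - 1] > ell:
                    tnext[j - 1] = t + np.random.exponential(
                        1.0 / lam[pos[j - 1]]
                    )
            # entry region may have just cleared
            if not np.isfinite(t_init):
                if n == 0 or pos[0] >= 2 + ell:
                    t_init = t + np.random.exponential(1.0 / alpha)

        events += 1

        if events == burn_in:
            collecting = True
            t_stats_start = t
            # restart dwell clocks so only fully observed dwells count
            for j in range(n):
                entry[j] = t
            n_term = 0
            n_drop = 0
            n_init = 0
            dt_snap = (t / burn_in) * interval
            if dt_snap <= 0.0:
                dt_snap = 1e-9
            next_snap = t + dt_snap

    t_elapsed = t - t_stats_start
    return (
        snapshots[:n_collected],
        snap_n[:n_collected],
        dwell_sum,
        dwell_cnt,
        n_term,
        n_init,
        n_drop,
        t_elapsed,
    )
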