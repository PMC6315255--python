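"""Numba kernels for the divisive energy-statistic split scan.

The scaled sample energy divergence between the two sides of a split at
tau is

    Q(tau) = (nl*nr/(nl+nr)) * (2*E|X-Y|^a - E|X-X'|^a - E|Y-Y'|^a)

with the expectations estimated by U-statistics over all pairs.  For the
default exponent a = 1 the scan over all admissible split points is done
in O(n log n): the left block's pairwise-distance sums are maintained in
a Fenwick (binary indexed) tree over value ranks, and the right block's
sums are recovered from static prefix sums of the sorted values.  For
other exponents a plain O(n^2) incremental scan is used.

Within a scan, element t moving from the right block to the left block
updates the three running sums

    WL += s_l,  WR -= s_r,  C += s_r - s_l

where s_l (s_r) is the summed distance from element t to the current
left (right) block.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _scan_l1(vals, ranks, gsum, total_within, total_sum, min_size):
    """Best split under exponent 1.  Returns (best_q, best_tau).

    ``ranks`` are distinct 0..n-1 value ranks; ``gsum`` is the inclusive
    cumulative sum of the sorted values; ``total_within`` the pairwise
    distance sum of the whole block.  best_tau = -1 when no admissible
    split exists.
    """
    n = vals.shape[0]
    cnt_l = np.zeros(n + 1, np.float64)
    sum_l = np.zeros(n + 1, np.float64)
    wl = 0.0
    wr = total_within
    cross = 0.0
    sl_tot = 0.0
    best_q = -1.0
    best_tau = -1
    for t in range(n - 1):
        v = vals[t]
        rk = ranks[t]
        # left-block count/sum of values with rank <= rk
        c = 0.0
        s = 0.0
        r = rk + 1
        while r > 0:
            c += cnt_l[r]
            s += sum_l[r]
            r -= r & (-r)
        nl_before = float(t)
        s_l = v * c - s + (sl_tot - s) - v * (nl_before - c)
        # right block = all minus left minus current; ranks are distinct
        c_r_le = float(rk) - c
        s_r_le = gsum[rk] - v - s
        n_r = float(n - t - 1)
        s_r_tot = total_sum - sl_tot - v
        s_r = v * c_r_le - s_r_le + (s_r_tot - s_r_le) - v * (n_r - c_r_le)
        wr -= s_r
        cross += s_r - s_l
        wl += s_l
        r = rk + 1
        while r <= n:
            cnt_l[r] += 1.0
            sum_l[r] += v
            r += r & (-r)
        sl_tot += v
        tau = t + 1
        if tau >= min_size and n - tau >= min_size:
            nl = float(tau)
            nr = float(n - tau)
            q = (nl * nr / (nl + nr)) * (
                2.0 * cross / (nl * nr)
                - 2.0 * wl / (nl * (nl - 1.0))
                - 2.0 * wr / (nr * (nr - 1.0))
            )
            if q > best_q:
                best_q = q
                best_tau = tau
    return best_q, best_tau


@njit(cache=True)
def _scan_generic(vals, alpha, min_size):
    """O(n^2) incremental scan for an arbitrary exponent alpha."""
    n = vals.shape[0]
    wl = 0.0
    wr = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            wr += abs(vals[i] - vals[j]) ** alpha
    cross = 0.0
    best_q = -1.0
    best_tau = -1
    for t in range(n - 1):
        v = vals[t]
        s_l = 0.0
        for i in range(t):
            s_l += abs(vals[i] - v) ** alpha
        s_r = 0.0
        for j in range(t + 1, n):
            s_r += abs(vals[j] - v) ** alpha
        # before the move, wr still contains the (t, right) pairs
        wr -= s_r
        cross += s_r - s_l
        wl += s_l
        tau = t + 1
        if tau >= min_size and n - tau >= min_size:
            nl = float(tau)
            nr = float(n - tau)
            q = (nl * nr / (nl + nr)) * (
                2.0 * cross / (nl * nr)
                - 2.0 * wl / (nl * (nl - 1.0))
                - 2.0 * wr / (nr * (nr - 1.0))
            )
            if q > best_q:
                best_q = q
                best_tau = tau
    return best_q, best_tau


@njit(cache=True)
def _node_decide_l1(vals, ranks, gsum, total_within, total_sum, min_size,
                    n_perm, max_exceed, seed):
    """Observed scan plus permutation test at one recursion node.

    Returns (tau, reject): ``reject`` is True when the permutation
    p-value (r+1)/(R+1) falls below the significance level, encoded by
    ``max_exceed`` = the largest exceedance count r still compatible
    with rejection.  The loop stops as soon as rejection is impossible;
    the decision equals the full-enumeration decision.
    """
    q_obs, tau = _scan_l1(vals, ranks, gsum, total_within, total_sum, min_size)
    if tau < 0 or max_exceed < 0:
        return tau, False
    np.random.seed(seed)
    n = vals.shape[0]
    r = 0
    for _ in range(n_perm):
        perm = np.random.permutation(n)
        q_p, _tau_p = _scan_l1(vals[perm], ranks[perm], gsum,
                               total_within, total_sum, min_size)
        if q_p >= q_obs:
            r += 1
            if r > max_exceed:
                return tau, False
    return tau, True


@njit(cache=True)
def _node_decide_generic(vals, alpha, min_size, n_perm, max_exceed, seed):
    q_obs, tau = _scan_generic(vals, alpha, min_size)
    if tau < 0 or max_exceed < 0:
        return tau, False
    np.random.seed(seed)
    n = vals.shape[0]
    r = 0
    for _ in range(n_perm):
        perm = np.random.permutation(n)
        q_p, _tau_p = _scan_generic(vals[perm], alpha, min_size)
        if q_p >= q_obs:
            r += 1
            if r > max_exceed:
                return tau, False
    return tau, True


def rank_precompute(vals):
    """Distinct value ranks, inclusive sorted cumsum, and total pairwise
    distance sum for the exponent-1 scan (all permutation-invariant)."""
    order = np.argsort(vals, kind="stable")
    ranks = np.empty(vals.shape[0], dtype=np.int64)
    ranks[order] = np.arange(vals.shape[0])
    sorted_vals = vals[order]
    gsum = np.cumsum(sorted_vals)
    n = vals.shape[0]
    total_within = float(
        np.sum((2.0 * np.arange(n) - n + 1.0) * sorted_vals)
    )
    return ranks, gsum, total_within, float(sorted_vals.sum())
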