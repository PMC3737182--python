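"""Numba kernels for the trajectory sampler and the genealogy importance
sampler at Monte-Carlo scale.

These mirror, operation for operation, the reference implementations in
:mod:`sweepis.wf_trajectory` and :mod:`sweepis.genealogy_is` (same hazards,
same proposal terms, same step weight hbar/(2 gamma)); the agreement of both
routes with the exact dynamic-programming oracle is asserted in the
test-suite.  Constant population size only — the likelihood layer falls back
to the pure-Python path for time-varying demographies.

Configuration layout: parallel arrays over distinct coded types (capacity
``CAP``), each with left/right extents, a mutation-coordinate list (most
recent first, capacity ``KM``) and a multiplicity.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

CAP = 64      # max distinct types
KM = 16       # max mutation coordinates per type
NEG_INF = -np.inf


@njit(cache=True)
def _inverse_map(y, s1, s2):
    """Root in [0,1] of the deterministic selection map equal to y."""
    if y <= 0.0:
        return 0.0
    if y >= 1.0:
        return 1.0
    lo = 0.0
    hi = 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        num = mid * (1.0 + s1 * mid + s2 * (1.0 - mid))
        den = 1.0 + s1 * mid * mid + 2.0 * s2 * mid * (1.0 - mid)
        if num / den < y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def _forward_map(x, s1, s2):
    num = x * (1.0 + s1 * x + s2 * (1.0 - x))
    den = 1.0 + s1 * x * x + 2.0 * s2 * x * (1.0 - x)
    return num / den


@njit(cache=True)
def _binom_logpmf(k, n, p):
    if p <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    if p >= 1.0:
        return 0.0 if k == n else NEG_INF
    return (
        math.lgamma(n + 1.0) - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0)
        + k * math.log(p) + (n - k) * math.log1p(-p)
    )


@njit(cache=True)
def sample_trajectory_kernel(i0, two_n, s1, s2, t_max, seed):
    """Backward path at constant size; returns (counts, logp_b, logp_f, ok).

    counts has length T+1 with counts[T] = 0; ok is False when t_max was
    exceeded (the path is then discarded by the caller).
    """
    np.random.seed(seed)
    buf = np.empty(t_max + 2, dtype=np.int64)
    buf[0] = i0
    logp_b = 0.0
    t = 0
    while buf[t] > 0:
        t += 1
        if t > t_max:
            return buf[:1], 0.0, NEG_INF, False
        y = buf[t - 1] / two_n
        yp = _inverse_map(y, s1, s2)
        it = np.random.binomial(two_n, yp)
        buf[t] = it
        logp_b += _binom_logpmf(it, two_n, yp)
    T = t
    counts = buf[:T + 1].copy()
    # forward probability, founded by a single copy
    if counts[T - 1] != 1:
        return counts, logp_b, NEG_INF, True
    logp_f = 0.0
    for u in range(T - 1, 0, -1):
        x = counts[u] / two_n
        xp = _forward_map(x, s1, s2)
        logp_f += _binom_logpmf(counts[u - 1], two_n, xp)
    return counts, logp_b, logp_f, True


@njit(cache=True)
def forward_path_kernel(two_n, s1, s2, t_cap, seed):
    """Forward Wright-Fisher path from one copy until loss, fixation or
    t_cap; returns the copy-number array (index 0 = founding generation)."""
    np.random.seed(seed)
    buf = np.empty(t_cap + 1, dtype=np.int64)
    buf[0] = 1
    t = 0
    while t < t_cap:
        i = buf[t]
        if i == 0 or i == two_n:
            break
        xp = _forward_map(i / two_n, s1, s2)
        t += 1
        buf[t] = np.random.binomial(two_n, xp)
    return buf[:t + 1]


@njit(cache=True)
def _beta_of(r1, r2, d_left, d_right):
    return (d_left[r1] + d_right[r2]) / (d_left[-1] + d_right[-1])


@njit(cache=True)
def _flank_hazard(r1, r2, d_left, d_right, selected_donor):
    """Per-lineage recombination hazard coefficient (see
    HaplotypeFrequencyModel.flank_hazard_scale)."""
    m_left = len(d_left) - 1
    m_right = len(d_right) - 1
    if selected_donor:
        left = d_left[r1 + 1] - d_left[r1] if r1 < m_left else 0.0
        right = d_right[r2 + 1] - d_right[r2] if r2 < m_right else 0.0
    else:
        left = d_left[r1 + 1] if r1 < m_left else d_left[m_left]
        right = d_right[r2 + 1] if r2 < m_right else d_right[m_right]
    return left + right


@njit(cache=True)
def _find_type(d, r1, r2, nm, mp, tr1, tr2, tmuts, tnm):
    """Index of the type equal to (tr1, tr2, tmuts[:tnm]), or -1."""
    for j in range(d):
        if r1[j] != tr1 or r2[j] != tr2 or nm[j] != tnm:
            continue
        same = True
        for q in range(tnm):
            if mp[j, q] != tmuts[q]:
                same = False
                break
        if same:
            return j
    return -1


@njit(cache=True)
def _one_genealogy(r1_0, r2_0, nm0, mp0, mult0, mb0, d0,
                   counts, xfreq, clock, d_left, d_right, mu, cc,
                   selected_donor, paper_hazard):
    """One importance-sampling path; returns the log weight (-inf = rejected)."""
    m_left = len(d_left) - 1
    m_right = len(d_right) - 1
    T = len(counts) - 1

    r1 = r1_0.copy()
    r2 = r2_0.copy()
    nm = nm0.copy()
    mp = mp0.copy()
    mult = mult0.copy()
    mb = mb0.copy()       # observable-segment fraction per type (mutation clock)
    d = d0

    max_ev = CAP * (2 + m_left + m_right)
    ev_w = np.empty(max_ev)
    ev_kind = np.empty(max_ev, dtype=np.int64)
    ev_src = np.empty(max_ev, dtype=np.int64)
    ev_aux1 = np.empty(max_ev, dtype=np.int64)   # merge dest / recomb side
    ev_aux2 = np.empty(max_ev, dtype=np.int64)   # recomb new extent
    tmut = np.empty(KM, dtype=np.int64)

    logw = 0.0
    t = 0
    while True:
        n = 0
        for j in range(d):
            n += mult[j]
        if (n == 1 and d == 1 and r1[0] == m_left and r2[0] == m_right
                and nm[0] == 0):
            return logw                                   # absorbed at founder

        # per-generation hazard components between events
        a_coal = n * (n - 1) / 2.0
        b_const = 0.0
        b_x = 0.0
        for j in range(d):
            beta_j = _beta_of(r1[j], r2[j], d_left, d_right)
            b_const += mult[j] * mu * mb[j]
            if paper_hazard:
                b_const += mult[j] * cc * beta_j
            else:
                b_x += mult[j] * _flank_hazard(r1[j], r2[j], d_left, d_right,
                                               selected_donor)

        v = -1
        u = t
        while u < T - 1:
            u += 1
            dw = xfreq[u] if selected_donor else 1.0 - xfreq[u]
            h = a_coal / counts[u] + b_const + b_x * dw
            if h > 1.0:
                h = 1.0
            if np.random.random() < h:
                v = u
                break
        if v < 0:
            return NEG_INF                                # beyond trajectory

        iv = counts[v]
        xv = xfreq[v]
        cv = clock[v]

        n_ev = 0
        # coalescences
        for k in range(d):
            if mult[k] >= 2:
                ev_kind[n_ev] = 0
                ev_src[n_ev] = k
                ev_w[n_ev] = n * (mult[k] - 1) / iv
                n_ev += 1
        # mutations (shift or forced merge)
        if mu > 0.0:
            for k in range(d):
                if mult[k] != 1 or nm[k] == 0:
                    continue
                for q in range(nm[k] - 1):
                    tmut[q] = mp[k, q + 1]
                j = _find_type(d, r1, r2, nm, mp, r1[k], r2[k], tmut, nm[k] - 1)
                if j >= 0:
                    ev_kind[n_ev] = 2
                    ev_src[n_ev] = k
                    ev_aux1[n_ev] = j
                    ev_w[n_ev] = 2.0 * mu * mb[j] * (mult[j] + 1)
                    n_ev += 1
                else:
                    ev_kind[n_ev] = 1
                    ev_src[n_ev] = k
                    ev_w[n_ev] = 2.0 * mu * mb[k]
                    n_ev += 1
        # escape reversals (flank extensions)
        donor_w = xv if selected_donor else 1.0 - xv
        if donor_w > 0.0:
            for i in range(d):
                for side in range(2):
                    dd = d_left if side == 0 else d_right
                    m_side = m_left if side == 0 else m_right
                    cur = r1[i] if side == 0 else r2[i]
                    if cur >= m_side:
                        continue
                    r_int = dd[cur + 1] - dd[cur]
                    if r_int <= 0.0:
                        continue
                    base = 2.0 * mult[i] * r_int * donor_w
                    # conditional law rescales by survival past the break
                    ref = dd[cur + 1] * cv if not selected_donor else 0.0
                    for b in range(cur + 1, m_side + 1):
                        head = math.exp(-(dd[b] * cv - ref))
                        if b < m_side:
                            p_b = head * -math.expm1(-(dd[b + 1] - dd[b]) * cv)
                        else:
                            p_b = head
                        if p_b <= 0.0:
                            continue
                        ev_kind[n_ev] = 3
                        ev_src[n_ev] = i
                        ev_aux1[n_ev] = side
                        ev_aux2[n_ev] = b
                        ev_w[n_ev] = base * p_b
                        n_ev += 1

        hbar_g = 0.0
        for e in range(n_ev):
            hbar_g += ev_w[e]
        if hbar_g <= 0.0:
            return NEG_INF                                # dead end
        gamma_g = a_coal / iv + b_const + b_x * donor_w
        logw += math.log(hbar_g / (2.0 * gamma_g))

        # choose the event
        target = np.random.random() * hbar_g
        acc = 0.0
        chosen = n_ev - 1
        for e in range(n_ev):
            acc += ev_w[e]
            if target < acc:
                chosen = e
                break

        kind = ev_kind[chosen]
        k = ev_src[chosen]
        if kind == 0:                                     # coalescence
            mult[k] -= 1
        elif kind == 1:                                   # mutation shift
            for q in range(nm[k] - 1):
                mp[k, q] = mp[k, q + 1]
            nm[k] -= 1
        elif kind == 2:                                   # mutation merge
            j = ev_aux1[chosen]
            mb[j] = (mult[j] * mb[j] + mb[k]) / (mult[j] + 1)
            mult[j] += 1
            d -= 1
            if k != d:
                r1[k] = r1[d]
                r2[k] = r2[d]
                nm[k] = nm[d]
                mult[k] = mult[d]
                mb[k] = mb[d]
                for q in range(KM):
                    mp[k, q] = mp[d, q]
        else:                                             # flank extension
            side = ev_aux1[chosen]
            b = ev_aux2[chosen]
            nr1 = b if side == 0 else r1[k]
            nr2 = r2[k] if side == 0 else b
            tn = nm[k]
            for q in range(tn):
                tmut[q] = mp[k, q]                        # extensions keep M
            carrier_mb = mb[k]      # observable material unchanged by extension
            mult[k] -= 1
            if mult[k] == 0:
                d -= 1
                if k != d:
                    r1[k] = r1[d]
                    r2[k] = r2[d]
                    nm[k] = nm[d]
                    mult[k] = mult[d]
                    mb[k] = mb[d]
                    for q in range(KM):
                        mp[k, q] = mp[d, q]
            j = _find_type(d, r1, r2, nm, mp, nr1, nr2, tmut, tn)
            if j >= 0:
                mb[j] = (mult[j] * mb[j] + carrier_mb) / (mult[j] + 1)
                mult[j] += 1
            else:
                if d >= CAP:
                    return NEG_INF                        # capacity guard
                r1[d] = nr1
                r2[d] = nr2
                nm[d] = tn
                for q in range(tn):
                    mp[d, q] = tmut[q]
                mult[d] = 1
                mb[d] = carrier_mb
                d += 1
        t = v


@njit(cache=True)
def genealogy_batch(r1_0, r2_0, nm0, mp0, mult0, mb0, d0,
                    counts, xfreq, clock, d_left, d_right, mu, cc,
                    n_paths, seed, selected_donor=True, paper_hazard=True):
    """Log weights of ``n_paths`` independent genealogy paths (one seed)."""
    np.random.seed(seed)
    out = np.empty(n_paths)
    for p in range(n_paths):
        out[p] = _one_genealogy(r1_0, r2_0, nm0, mp0, mult0, mb0, d0,
                                counts, xfreq, clock, d_left, d_right, mu, cc,
                                selected_donor, paper_hazard)
    return out


def pack_configuration(cfg, d_left, d_right, cap: int = CAP, km: int = KM):
    """Flatten a SampleConfiguration into the kernel's parallel arrays.

    The observable-segment fraction of each type (its coded beta at
    observation) seeds the mutation clock.
    """
    d = cfg.n_types
    if d > cap:
        raise ValueError("too many distinct types for the kernel capacity")
    r1 = np.zeros(cap, dtype=np.int64)
    r2 = np.zeros(cap, dtype=np.int64)
    nm = np.zeros(cap, dtype=np.int64)
    mp = np.zeros((cap, km), dtype=np.int64)
    mult = np.zeros(cap, dtype=np.int64)
    mb = np.zeros(cap)
    total = d_left[-1] + d_right[-1]
    for i, (h, n) in enumerate(zip(cfg.types, cfg.mult)):
        if h.n_mut > km:
            raise ValueError("too many mutation coordinates for the kernel")
        r1[i] = h.r1
        r2[i] = h.r2
        nm[i] = h.n_mut
        mp[i, :h.n_mut] = h.muts
        mult[i] = n
        mb[i] = (d_left[h.r1] + d_right[h.r2]) / total
    return r1, r2, nm, mp, mult, mb, d
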