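"""Numba kernel for the inside (McCaskill-type) recursion.

All quantities are Boltzmann weights scaled per base by ``inv_sigma``: a
weight w over an interval of length m is stored as w * inv_sigma**m. The
scaling cancels in all traceback ratios and is undone when reporting free
energies; it exists only to keep double precision in range for long
concatenations (multistrand complexes).

Matrices produced (n = total length, intervals in concatenation coordinates):

``qb[i, j]``
    weight of structures on [i..j] with (i, j) paired, including the loop
    closed by (i, j) and the terminal penalty on its interior side.
``w[i, j]``
    qb * terminal weight of (i, j) on its exterior side.
``z[a, b]``
    exterior-style tilings of [a..b-1] (exclusive end): any number of
    helices, each weighted w, unpaired bases weighted inv_sigma. z[a, a]=1.
``ss[a, b]``
    single-helix tilings of [a..b] (inclusive): sum over helices (k, l)
    inside the interval of w[k, l] times inv_sigma per unpaired base.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def inside(
    seq,            # int8[n] base indices
    can_pair,       # uint8[n] 1 where the base may pair (region constraints)
    ncum,           # int64[n+1] ncum[x] = number of nicks at positions < x
    ptype,          # int8[4,4] pair codes, -1 = not pairable
    stack_w,        # float64[6,6] stack Boltzmann weights (0 where illegal)
    tau_w,          # float64[6] terminal-penalty weights per pair code
    hp_w,           # float64[n+1] hairpin weights by loop size (0 below min)
    bulge_w,        # float64[cap+1]
    int_w,          # float64[cap+1]
    cap,            # int64 two-sided loop size cap
    inv_sigma,      # float64 per-base scaling factor
):
    n = seq.shape[0]
    qb = np.zeros((n, n))
    w = np.zeros((n, n))
    ss = np.zeros((n + 1, n + 1))
    z = np.zeros((n + 1, n + 1))
    pow_inv = np.empty(n + 2)
    pow_inv[0] = 1.0
    for m in range(1, n + 2):
        pow_inv[m] = pow_inv[m - 1] * inv_sigma

    for a in range(n + 1):
        z[a, a] = 1.0
    for a in range(n):
        z[a, a + 1] = inv_sigma

    for s in range(1, n):
        for i in range(0, n - s):
            j = i + s
            pt = ptype[seq[i], seq[j]]
            if pt >= 0 and can_pair[i] == 1 and can_pair[j] == 1:
                q = 0.0
                nick_ij = ncum[j] - ncum[i]  # nicks p with i <= p < j
                # hairpin
                if nick_ij == 0 and hp_w[s - 1] > 0.0:
                    q += hp_w[s - 1] * tau_w[pt] * pow_inv[s + 1]
                # stack / bulge / internal (loop must contain no nick)
                kmax = min(i + 1 + cap, j - 2)
                for k in range(i + 1, kmax + 1):
                    if ncum[k] - ncum[i] > 0:
                        break  # nick in left gap; grows with k
                    g1 = k - i - 1
                    lmin = j - 1 - (cap - g1)
                    if lmin < k + 1:
                        lmin = k + 1
                    for l in range(j - 1, lmin - 1, -1):
                        if ncum[j] - ncum[l] > 0:
                            break  # nick in right gap; grows as l decreases
                        if qb[k, l] <= 0.0:
                            continue
                        pt2 = ptype[seq[k], seq[l]]
                        g2 = j - l - 1
                        if g1 == 0 and g2 == 0:
                            q += stack_w[pt, pt2] * qb[k, l] * pow_inv[2]
                        elif g1 == 0 or g2 == 0:
                            q += (
                                bulge_w[g1 + g2]
                                * tau_w[pt]
                                * tau_w[pt2]
                                * qb[k, l]
                                * pow_inv[g1 + g2 + 2]
                            )
                        else:
                            q += (
                                int_w[g1 + g2]
                                * tau_w[pt]
                                * tau_w[pt2]
                                * qb[k, l]
                                * pow_inv[g1 + g2 + 2]
                            )
                # multiloop (>=2 helices) or loop containing a nick
                m_val = z[i + 1, j]  # tilings of [i+1 .. j-1]
                if nick_ij == 0:
                    m_val -= pow_inv[s - 1]  # empty tiling -> hairpin case
                    if s >= 3:
                        m_val -= ss[i + 1, j - 1]  # single-helix -> two-loop case
                else:
                    # subtract single helices covering every nick in the loop
                    pf = n  # first nick position >= i
                    pl = -1  # last nick position < j
                    for p in range(i, j):
                        if ncum[p + 1] - ncum[p] > 0:
                            if p < pf:
                                pf = p
                            pl = p
                    for k in range(i + 1, pf + 1):
                        for l in range(pl + 1, j):
                            if w[k, l] > 0.0:
                                m_val -= w[k, l] * pow_inv[(k - i - 1) + (j - 1 - l)]
                if m_val > 0.0:
                    q += tau_w[pt] * m_val * pow_inv[2]
                qb[i, j] = q
                w[i, j] = tau_w[pt] * q
            # single-helix interval sums (inclusive interval [i..j])
            v = inv_sigma * (ss[i + 1, j] + ss[i, j - 1]) + w[i, j]
            if j - 1 >= i + 1:
                v -= inv_sigma * inv_sigma * ss[i + 1, j - 1]
            ss[i, j] = v
            # exterior tilings of [i..j] stored at z[i, j+1]
            zv = inv_sigma * z[i + 1, j + 1]
            for k in range(i + 1, j + 1):
                if w[i, k] > 0.0:
                    zv += w[i, k] * z[k + 1, j + 1]
            z[i, j + 1] = zv

    return qb, w, ss, z
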