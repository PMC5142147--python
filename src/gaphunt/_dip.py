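"""Hartigans' dip statistic of unimodality.

The dip of an empirical distribution function F_n is the smallest
sup-norm distance between F_n and any unimodal distribution function.
It is computed with the classical alternating greatest-convex-minorant /
least-concave-majorant algorithm: maintain a candidate modal interval
[low, high], fit the GCM of F_n to its left part and the LCM to its
right part, take the largest discrepancy between the two fits, and
shrink the modal interval until the discrepancy no longer exceeds the
dip found so far.

The statistic is location/scale invariant (it depends on the data only
through order) and is bounded below by 1/(2n); a sample in "perfectly
unimodal position" attains that bound, and a constant sample has dip 0.

Correctness is checked in the test-suite against an independent
linear-programming oracle that minimises sup|F_n - G| over unimodal G
directly from the definition.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]


def dip_statistic(values: np.ndarray) -> float:
    """Dip statistic of a 1-D sample (need not be sorted)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("dip_statistic needs at least one value")
    if n < 2 or x[0] == x[n - 1]:
        return 0.0

    # 1-based arrays, index 0 unused, as in the published routine
    xx = np.empty(n + 1)
    xx[1:] = x

    # mn[j]: previous touch point of the greatest convex minorant through j
    mn = np.empty(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (xx[j] - xx[mnj]) * (mnj - mnmnj) < (xx[mnj] - xx[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    # mj[k]: next touch point of the least concave majorant through k
    mj = np.empty(n + 2, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (xx[k] - xx[mjk]) * (mjk - mjmjk) < (xx[mjk] - xx[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in counts; final statistic = dip / (2n)

    while True:
        # GCM change points from high down to low, LCM from low up to high
        gcm = [0, high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm) - 1
        ix = l_gcm - 1

        lcm = [0, low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm) - 1
        iv = 2

        # largest vertical distance between the GCM and the LCM
        d = 0.0
        ig, ih = l_gcm, l_lcm
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next knot comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xx[lcmiv] - xx[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xx[gcmix] - xx[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next knot comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (xx[gcmix] - xx[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xx[lcmiv] - xx[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # largest deviation of F_n from the GCM left of the modal interval
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xx[jj] - xx[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # largest deviation of F_n from the LCM right of the modal interval
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for jj in range(jb, je + 1):
                    t = (xx[jj] - xx[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        low = gcm[ig]
        high = lcm[ih]
        if dip >= d:
            break

    return dip / (2.0 * n)
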