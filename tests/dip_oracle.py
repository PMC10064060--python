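"""Brute-force oracle for the dip statistic.

For each candidate mode location (a sample point, with an atom allowed at
the mode), the closest unimodal CDF in sup-norm is found by linear
programming; the dip is the minimum over modes.  This encodes the
definition directly — a unimodal CDF is convex left of the mode and
concave right of it — and serves as ground truth for small samples.
"""
import numpy as np
from scipy.optimize import linprog


def dip_lp_oracle(x):
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    assert n >= 2
    best = np.inf
    for m in range(n):  # mode at sample point x[m]
        # variables: g_0..g_{n-1} = G(x_i) (right limits), G(x_m^-), t
        nv = n + 2
        it, igm = n + 1, n
        c = np.zeros(nv)
        c[it] = 1.0
        A, b = [], []

        def ub(row, rhs):
            A.append(row)
            b.append(rhs)

        def band(idx, values):
            for val in values:
                r = np.zeros(nv); r[idx] = 1.0; r[it] = -1.0
                ub(r, val)
                r = np.zeros(nv); r[idx] = -1.0; r[it] = -1.0
                ub(r, -val)

        for i in range(n):
            if i == m:
                band(i, [(i + 1) / n])  # right limit vs F(x_m)
            else:
                band(i, [i / n, (i + 1) / n])
        band(igm, [m / n])  # left limit at the mode vs F(x_m^-)

        chain = list(range(m)) + [igm] + list(range(m, n))
        for a_i, b_i in zip(chain[:-1], chain[1:]):  # monotone
            r = np.zeros(nv); r[a_i] = 1.0; r[b_i] = -1.0
            ub(r, 0.0)
        for i in list(range(n)) + [igm]:  # G in [0, 1]
            r = np.zeros(nv); r[i] = -1.0
            ub(r, 0.0)
            r = np.zeros(nv); r[i] = 1.0
            ub(r, 1.0)
        # convex branch: slopes nondecreasing up to the mode
        pts = [(x[i], i) for i in range(m)] + [(x[m], igm)]
        for (xa, ia), (xb, ib), (xc, ic) in zip(pts[:-2], pts[1:-1], pts[2:]):
            r = np.zeros(nv)
            r[ib] += (xc - xb); r[ia] -= (xc - xb)
            r[ic] -= (xb - xa); r[ib] += (xb - xa)
            ub(r, 0.0)
        # concave branch: slopes nonincreasing from the mode
        pts = [(x[i], i) for i in range(m, n)]
        for (xa, ia), (xb, ib), (xc, ic) in zip(pts[:-2], pts[1:-1], pts[2:]):
            r = np.zeros(nv)
            r[ib] -= (xc - xb); r[ia] += (xc - xb)
            r[ic] += (xb - xa); r[ib] -= (xb - xa)
            ub(r, 0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(None, None)] * nv, method="highs")
        assert res.success, res.message
        best = min(best, res.fun)
    return best
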