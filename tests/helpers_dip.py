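"""Brute-force oracle for the dip statistic.

Minimizes the sup-norm radius over unimodal CDFs directly as a linear
program, one LP per candidate mode (every data atom, plus a grid of
positions inside each gap), entirely independent of the production
bisection/hull implementation.
"""
import numpy as np
from scipy.optimize import linprog


def dip_lp(values, gap_grid=5):
    x = np.sort(np.asarray(values, float))
    n = len(x)
    v, counts = np.unique(x, return_counts=True)
    T = len(v)
    if T == 1:
        return 0.0
    cum = np.cumsum(counts) / n
    prev = np.concatenate([[0.0], cum[:-1]])

    def solve_mode_atom(s):
        # variables: G_0..G_{T-1}, L (left limit at the mode atom), eps
        nv = T + 2
        iL, ie = T, T + 1
        A_ub, b_ub = [], []

        def le(coefs, rhs):
            row = np.zeros(nv)
            for i, c in coefs:
                row[i] += c
            A_ub.append(row)
            b_ub.append(rhs)

        for t in range(T):
            if t == s:
                le([(t, 1.0), (ie, -1.0)], cum[t])
                le([(t, -1.0), (ie, -1.0)], -cum[t])
                le([(iL, 1.0), (ie, -1.0)], prev[t])
                le([(iL, -1.0), (ie, -1.0)], -prev[t])
            else:
                le([(t, 1.0), (ie, -1.0)], prev[t])
                le([(t, -1.0), (ie, -1.0)], -cum[t])
        for t in range(T - 1):
            le([(t, 1.0), (t + 1, -1.0)], 0.0)
        le([(iL, 1.0), (s, -1.0)], 0.0)
        if s > 0:
            le([(s - 1, 1.0), (iL, -1.0)], 0.0)

        left_pts = [(v[t], t) for t in range(s)] + [(v[s], iL)]
        for i in range(len(left_pts) - 2):
            (xa, ia), (xb, ib), (xc, ic) = left_pts[i:i + 3]
            le([(ib, (xc - xb) + (xb - xa)), (ia, -(xc - xb)),
                (ic, -(xb - xa))], 0.0)
        right_pts = [(v[s], s)] + [(v[t], t) for t in range(s + 1, T)]
        for i in range(len(right_pts) - 2):
            (xa, ia), (xb, ib), (xc, ic) = right_pts[i:i + 3]
            le([(ib, -((xc - xb) + (xb - xa))), (ia, (xc - xb)),
                (ic, (xb - xa))], 0.0)

        res = linprog(np.eye(nv)[ie], A_ub=np.array(A_ub),
                      b_ub=np.array(b_ub),
                      bounds=[(0.0, 1.0)] * nv, method="highs")
        return res.fun if res.status == 0 else np.inf

    def solve_gap(k, m):
        # free (tube-less) mode point m inserted after atom k
        nv = T + 2
        ie = T + 1
        A_ub, b_ub = [], []

        def le(coefs, rhs):
            row = np.zeros(nv)
            for i, c in coefs:
                row[i] += c
            A_ub.append(row)
            b_ub.append(rhs)

        for t in range(T):
            le([(t, 1.0), (ie, -1.0)], prev[t])
            le([(t, -1.0), (ie, -1.0)], -cum[t])
        order = list(range(k + 1)) + [T] + list(range(k + 1, T))
        pos = list(v[:k + 1]) + [m] + list(v[k + 1:])
        for i in range(len(order) - 1):
            le([(order[i], 1.0), (order[i + 1], -1.0)], 0.0)
        left = list(zip(pos[:k + 2], order[:k + 2]))
        for i in range(len(left) - 2):
            (xa, ia), (xb, ib), (xc, ic) = left[i:i + 3]
            le([(ib, (xc - xb) + (xb - xa)), (ia, -(xc - xb)),
                (ic, -(xb - xa))], 0.0)
        right = list(zip(pos[k + 1:], order[k + 1:]))
        for i in range(len(right) - 2):
            (xa, ia), (xb, ib), (xc, ic) = right[i:i + 3]
            le([(ib, -((xc - xb) + (xb - xa))), (ia, (xc - xb)),
                (ic, (xb - xa))], 0.0)
        res = linprog(np.eye(nv)[ie], A_ub=np.array(A_ub),
                      b_ub=np.array(b_ub),
                      bounds=[(0.0, 1.0)] * nv, method="highs")
        return res.fun if res.status == 0 else np.inf

    best = min(solve_mode_atom(s) for s in range(T))
    if gap_grid:
        for k in range(T - 1):
            for m in np.linspace(v[k], v[k + 1], gap_grid + 2)[1:-1]:
                best = min(best, solve_gap(k, m))
    return float(best)
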