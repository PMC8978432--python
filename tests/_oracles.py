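"""Independent brute-force reference implementations.

Everything here is written with plain Python loops directly from the
estimator definitions, deliberately sharing no code with the package
internals, so the vectorized implementations can be checked against an
independent evaluation path on small inputs.
"""

from __future__ import annotations

import math

import numpy as np


def _subjects(table):
    """List of per-subject dicts with episode lists in order."""
    out = []
    for sid in table.subject_ids:
        grp = table.df[table.df["id"] == sid]
        out.append(
            {
                "x": grp["xij"].tolist(),
                "y": grp["yij"].tolist(),
                "d1": grp["d1"].tolist(),
                "d2": grp["d2"].tolist(),
            }
        )
    for s in out:
        m = len(s["x"])
        s["m"] = m
        s["mstar"] = m - 1 if m >= 2 else 1
        s["C"] = sum(s["x"]) + sum(s["y"])
    return out


def _weights(subjects, ai):
    return [s["C"] if ai == 2 else 1.0 for s in subjects]


def joint_cdf_oracle(table, x, y, ai=1):
    """Triple-loop product-limit evaluation of the joint CDF."""
    subs = _subjects(table)
    n = len(subs)
    a = _weights(subs, ai)

    def H(z, xx, yy):
        tot = 0.0
        for s, ai_ in zip(subs, a):
            if s["m"] < 2:
                continue
            for j in range(s["mstar"]):
                zij = s["x"][j] + s["y"][j]
                if zij == z and s["x"][j] <= xx and s["y"][j] <= yy:
                    tot += ai_ / s["mstar"]
        return tot / n

    def R(z):
        tot = 0.0
        for s, ai_ in zip(subs, a):
            for j in range(s["mstar"]):
                if s["x"][j] + s["y"][j] >= z:
                    tot += ai_ / s["mstar"]
        return tot / n

    t_star = sorted(
        {
            s["x"][j] + s["y"][j]
            for s in subs
            if s["m"] >= 2
            for j in range(s["mstar"])
        }
    )
    total = 0.0
    for k, tk in enumerate(t_star):
        if tk > x + y:
            continue
        pref = 1.0
        for tl in t_star[:k]:
            pref *= 1.0 - H(tl, math.inf, math.inf) / R(tl)
        total += pref * H(tk, x, y) / R(tk)
    return total


def marginal_survival_oracle(table, x, ai=1):
    """Product-limit survival of Type I gaps by direct looping."""
    subs = _subjects(table)
    n = len(subs)
    a = _weights(subs, ai)

    def HX(t):
        tot = 0.0
        for s, ai_ in zip(subs, a):
            if s["m"] < 2:
                continue
            for j in range(s["mstar"]):
                if s["x"][j] == t:
                    tot += ai_ / s["mstar"]
        return tot / n

    def RX(t):
        tot = 0.0
        for s, ai_ in zip(subs, a):
            for j in range(s["mstar"]):
                if s["x"][j] >= t:
                    tot += ai_ / s["mstar"]
        return tot / n

    x_star = sorted(
        {
            s["x"][j]
            for s in subs
            for j in range(s["mstar"])
            if s["d1"][j] == 1
        }
    )
    surv = 1.0
    for xk in x_star:
        if xk <= x:
            surv *= 1.0 - HX(xk) / RX(xk)
    return surv


def chang_transform_oracle(table, A, b):
    """Row-by-row recursive transformed times and their indicators."""
    subs = _subjects(table)
    p = A.shape[1]
    b1, b2 = b[:p], b[p:]
    out = []
    for i, s in enumerate(subs):
        e1 = math.exp(-float(A[i] @ b1))
        e2 = math.exp(-float(A[i] @ b2))
        bound_base = s["C"] * e1
        running = 0.0
        rows = []
        for j in range(s["m"]):
            z0 = s["x"][j] * e1 + s["y"][j] * e2
            x0 = s["x"][j] * e1
            bound = bound_base - running
            zt = min(z0, bound)
            xt = min(x0, bound)
            dxt = int(s["d1"][j] == 1 and x0 <= bound)
            dzt = int(s["d2"][j] == 1 and z0 <= bound)
            rows.append((xt, zt, dxt, dzt))
            running += zt
        out.append(rows)
    return out


def chang_U_oracle(table, A, b):
    """Double-loop rank estimating functions U1, U2."""
    subs = _subjects(table)
    n = len(subs)
    p = A.shape[1]
    trans = chang_transform_oracle(table, A, b)

    def S(kind, k, t):
        col = 0 if kind == "X" else 1
        tot = np.zeros(p) if k == 1 else 0.0
        for i, s in enumerate(subs):
            for j in range(s["mstar"]):
                if trans[i][j][col] >= t:
                    contrib = (A[i] if k == 1 else 1.0) / s["mstar"]
                    tot = tot + contrib
        return tot / n

    U1 = np.zeros(p)
    U2 = np.zeros(p)
    for i, s in enumerate(subs):
        for j in range(s["mstar"]):
            xt, zt, dxt, dzt = trans[i][j]
            if dxt:
                s0 = S("X", 0, xt)
                if s0 > 0:
                    U1 += (A[i] - S("X", 1, xt) / s0) / s["mstar"]
            if dzt:
                s0 = S("Z", 0, zt)
                if s0 > 0:
                    U2 += (A[i] - S("Z", 1, zt) / s0) / s["mstar"]
    return U1 / math.sqrt(n), U2 / math.sqrt(n)


def lee_D_oracle(table, A, b, km1, km2, L):
    """Quadruple-loop U-statistic estimating functions D1*, D2*."""
    subs = _subjects(table)
    n = len(subs)
    p = A.shape[1]
    b1, b2 = b[:p], b[p:]

    def OL(s, t):
        return math.log(min(max(t, s), L)) - math.log(L)

    D1 = np.zeros(p)
    D2 = np.zeros(p)
    for i, si in enumerate(subs):
        for ip in range(n):
            Aii = A[ip] - A[i]
            acc1 = 0.0
            acc2 = 0.0
            for j in range(si["mstar"]):
                xij = si["x"][j]
                yij = si["y"][j]
                zij = xij + yij
                e1 = math.exp(float(Aii @ b1))
                e2 = math.exp(float(Aii @ b2))
                if si["d1"][j] == 1:
                    g = float(km1.G(min(xij, L)))
                    acc1 += OL(xij, e1 * xij) / g
                if si["d2"][j] == 1:
                    g = float(km2.G(min(zij, L)))
                    acc2 += OL(zij, e1 * xij + e2 * yij) / g
            D1 += Aii * acc1 / si["mstar"]
            D2 += Aii * acc2 / si["mstar"]
    return D1 / n**2, D2 / n**2
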