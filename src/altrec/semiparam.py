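"""Accelerated failure time regression for alternating gap times.

The model: conditional on baseline covariates ``A_i`` and a latent
subject-level frailty pair ``(g_i1, g_i2)``, the log gap times are

    log X0_ij = g_i1 + A_i' beta1 + e_ij1
    log Y0_ij = g_i2 + A_i' beta2 + e_ij2

with mean-zero errors of unspecified law.  Two estimators are offered:

* ``lee`` (default): smooth, monotone U-statistic estimating equations
  built from pairwise-transformed gap times, inverse-weighted by a
  Kaplan-Meier estimate of the censoring survival.  Solved inductively:
  the Type I equation for ``beta1`` first, then the Type II equation
  with ``beta1`` fixed.  Variance by a sandwich (numerical Jacobian,
  bootstrap middle).
* ``chang``: nonsmooth rank-based estimating functions on transformed
  gap times, solved by a multi-start simplex search; variance by
  perturbed-estimating-equation resampling.

Coefficients are log gap-time ratios: ``exp(beta)`` multiplies the gap
length per unit of covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize, stats

from .data import (
    ConvergenceError,
    EpisodeTable,
    check_time_invariant_covariates,
    validate,
)
from .nonparam import DataInvariantError

logger = logging.getLogger("altrec")


@dataclass
class RegressionSpec:
    """Inputs for an AFT fit: data, covariates, method and solver knobs.

    ``tol`` is the convergence tolerance on the sup-norm of the
    estimating function; when ``None`` a method-specific default is used
    (1e-8 for the smooth ``lee`` equations; for the discrete ``chang``
    rank statistic, a resolution-scaled default ``4 / sqrt(n)``, since a
    step function of that jump size admits no smaller residual).
    """

    table: EpisodeTable
    covariates: Sequence[str]
    method: str = "lee"
    level: float = 0.95
    max_iter: int | None = None
    tol: float | None = None
    n_resample: int = 200
    seed: int | None = None

    def prepared(self):
        if len(self.covariates) == 0:
            raise ValueError("at least one covariate is required")
        if self.method not in ("lee", "chang"):
            raise ValueError(f"method must be 'lee' or 'chang' (got {self.method!r})")
        validate(self.table)
        check_time_invariant_covariates(self.table)
        A = self.table.covariate_matrix()[
            :, [list(self.table.covariate_names).index(c) for c in self.covariates]
        ]
        return A


@dataclass
class AFTFit:
    """Fitted AFT coefficients for both gap types."""

    beta1: np.ndarray
    beta2: np.ndarray
    covariates: tuple[str, ...]
    method: str
    converged: bool
    n_used: int
    residual_norm: float
    level: float = 0.95
    vcov: np.ndarray | None = None

    @property
    def beta(self) -> np.ndarray:
        return np.concatenate([self.beta1, self.beta2])

    @property
    def names(self) -> list[str]:
        return [f"{c} (Type I)" for c in self.covariates] + [
            f"{c} (Type II)" for c in self.covariates
        ]

    @property
    def se(self) -> np.ndarray:
        self._require_vcov()
        return np.sqrt(np.diag(self.vcov))

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_value(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.z))

    def ci(self, level: float | None = None):
        q = stats.norm.ppf(0.5 + (level or self.level) / 2)
        return self.beta - q * self.se, self.beta + q * self.se

    def _require_vcov(self):
        if self.vcov is None:
            raise ValueError(
                "no variance estimate attached; run lee_vcov or "
                "parzen_resample_vcov first"
            )


# ---------------------------------------------------------------------- #
# shared episode arrays
# ---------------------------------------------------------------------- #
def _rows(table: EpisodeTable):
    """Rows j <= m*_i with subject index, gaps, indicators and 1/m* weight."""
    m = table.m
    mstar = table.m_star
    sid_order = {s: k for k, s in enumerate(table.subject_ids)}
    df = table.df
    subj = df["id"].map(sid_order).to_numpy()
    epi = df.groupby("id", sort=False).cumcount().to_numpy() + 1
    keep = epi <= mstar[subj]
    return (
        subj[keep],
        epi[keep],
        df["xij"].to_numpy(float)[keep],
        df["yij"].to_numpy(float)[keep],
        df["d1"].to_numpy(int)[keep],
        df["d2"].to_numpy(int)[keep],
        (1.0 / mstar)[subj[keep]],
    )


def _check_variation(A: np.ndarray):
    if np.any(A.std(axis=0) == 0):
        raise DataInvariantError("no covariate variation")


# ====================================================================== #
# Chang: rank-based estimating functions
# ====================================================================== #
def chang_transform(table: EpisodeTable, A: np.ndarray, b: np.ndarray):
    """Transformed observed gap times for every episode.

    Scales each subject's times to the baseline covariate level:
    ``X~0 = X exp(-A'b1)``, ``Z~0 = X exp(-A'b1) + Y exp(-A'b2)``, then
    truncates at the transformed residual follow-up
    ``C exp(-A'b1) - sum_{l<j} Z~_il``.  The running sum of truncated
    totals telescopes, so the truncation is applied through the capped
    cumulative sum ``min(cumsum Z~0, C exp(-A'b1))``.

    Because the residual follow-up shrinks differently from the gaps
    when ``b1 != b2``, a fully observed episode can be cut by the
    transformed cap (artificial censoring); the returned indicators
    ``dXt``/``dZt`` mark transformed times that remain complete.

    Returns per-row arrays (all episodes, in table order):
    Xt, Zt, dXt, dZt.
    """
    p = A.shape[1]
    b1, b2 = b[:p], b[p:]
    sid_order = {s: k for k, s in enumerate(table.subject_ids)}
    subj = table.df["id"].map(sid_order).to_numpy()
    x = table.df["xij"].to_numpy(float)
    y = table.df["yij"].to_numpy(float)
    C = table.follow_up
    e1 = np.exp(-A @ b1)[subj]
    e2 = np.exp(-A @ b2)[subj]
    cap = (C * np.exp(-A @ b1))[subj]
    z0 = x * e1 + y * e2
    cum = pd.Series(z0).groupby(subj).cumsum().to_numpy()
    cum_cap = np.minimum(cum, cap)
    prev_cap = np.minimum(cum - z0, cap)  # capped sum of earlier episodes
    Zt = cum_cap - prev_cap
    Xt = np.minimum(x * e1, cap - prev_cap)
    d1 = table.df["d1"].to_numpy(int)
    d2 = table.df["d2"].to_numpy(int)
    dXt = ((d1 == 1) & (x * e1 <= cap - prev_cap)).astype(int)
    dZt = ((d2 == 1) & (z0 <= cap - prev_cap)).astype(int)
    return Xt, Zt, dXt, dZt


def chang_U(
    table: EpisodeTable,
    A: np.ndarray,
    b: np.ndarray,
    return_subject_terms: bool = False,
):
    """Rank-based estimating functions (U1, U2) at parameter b.

    U_k = n^{-1/2} sum_i (1/m*_i) sum_{j<=m*_i} [A_i - S1/S0], with S0 and
    S1 the weighted at-risk count and covariate sum over transformed
    times.  Terms with an empty risk set contribute zero.  With
    ``return_subject_terms`` the per-subject summands phi_i (before the
    ``n^{-1/2}`` scaling) are returned as two (n, p) arrays, for the
    resampling variance estimator.
    """
    n = table.n
    Xt_all, Zt_all, dXt_all, dZt_all = chang_transform(table, A, b)
    subj, epi, x, y, d1, d2, w = _rows(table)
    mstar = table.m_star
    sid_order = {s: k for k, s in enumerate(table.subject_ids)}
    allsubj = table.df["id"].map(sid_order).to_numpy()
    allepi = table.df.groupby("id", sort=False).cumcount().to_numpy() + 1
    keep = allepi <= mstar[allsubj]
    Xt, Zt = Xt_all[keep], Zt_all[keep]
    dXt, dZt = dXt_all[keep], dZt_all[keep]

    Arow = A[subj]  # (R, p)
    U, phis = [], []
    # Outer terms carry the event indicator of the transformed time:
    # censored episodes (single-episode subjects) stay in the risk sets
    # but contribute no comparison of their own.
    for T, d in ((Xt, dXt), (Zt, dZt)):
        ind = T[:, None] >= T[None, :]  # I(T_r >= T_q)
        S0 = (w @ ind) / n
        S1 = (Arow * w[:, None]).T @ ind / n  # (p, R)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(S0 > 0, S1 / np.where(S0 > 0, S0, 1.0), 0.0)
        centered = np.where(S0 > 0, Arow.T - ratio, 0.0)  # empty risk set -> 0
        terms = (centered * w * d).T  # (R, p)
        phi = np.zeros((n, A.shape[1]))
        np.add.at(phi, subj, terms)
        phis.append(phi)
        U.append(phi.sum(axis=0) / np.sqrt(n))
    if return_subject_terms:
        return U[0], U[1], phis[0], phis[1]
    return U[0], U[1]


def _chang_events(table: EpisodeTable, A: np.ndarray, b: np.ndarray):
    """Events surviving artificial censoring at b, for X and Z ranks."""
    _, _, dXt, dZt = chang_transform(table, A, b)
    mstar = table.m_star
    sid_order = {s: k for k, s in enumerate(table.subject_ids)}
    subj = table.df["id"].map(sid_order).to_numpy()
    epi = table.df.groupby("id", sort=False).cumcount().to_numpy() + 1
    keep = epi <= mstar[subj]
    return int(dXt[keep].sum()), int(dZt[keep].sum())


def _chang_targets(table, A, seed, n_starts=5):
    rng = np.random.default_rng(seed)
    p = A.shape[1]
    starts = [np.zeros(p), np.full(p, 0.5), np.full(p, -0.5)]
    while len(starts) < n_starts:
        starts.append(rng.uniform(-0.5, 0.5, p))
    return starts


#: search box for the rank-based solver, on the log gap-time ratio scale.
#: Beyond |b| ~ 3 the transformed follow-up truncation caps every total
#: gap, and the rank statistic degenerates toward a spurious root there.
CHANG_BOX = 3.0


def _nm_solve(fun, starts, max_iter, tol, box=CHANG_BOX, valid=None):
    """Simplex search for a root of the nonsmooth statistic ``fun``.

    Minimizes ||fun||^2 from each start inside a box |b_k| <= box.  The
    statistic has spurious far-out roots: extreme parameters artificially
    censor every comparison, making it vanish identically; ``valid``
    (e.g. an event-retention check) screens those out.  Among admissible
    candidates the smallest residual wins.
    """

    def objective(v):
        pen = np.sum(np.maximum(np.abs(v) - box, 0.0) ** 2)
        return float(np.sum(fun(np.clip(v, -box, box)) ** 2)) + 1e3 * pen

    candidates = []
    for s0 in starts:
        res = optimize.minimize(
            objective,
            np.clip(s0, -box, box),
            method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-12},
        )
        v = np.clip(res.x, -box, box)
        ok = valid(v) if valid is not None else True
        candidates.append((v, float(np.max(np.abs(fun(v)))), ok))
    admissible = [c for c in candidates if c[2]] or candidates
    v, r, _ = min(admissible, key=lambda c: c[1])
    return v, r


def solve_chang(spec: RegressionSpec) -> AFTFit:
    """Point estimation by the rank-based method.

    Minimizes ||U1||^2 over b1 (risk sets evaluated with b2 = b1, under
    which the transformed truncation never binds for complete episodes),
    then ||U2||^2 over b2 with b1 fixed.  Raises the convergence error
    when the residual cannot be brought under ``tol``.
    """
    A = spec.prepared()
    p = A.shape[1]
    n = spec.table.n
    max_iter = spec.max_iter if spec.max_iter is not None else 1000
    tol = spec.tol if spec.tol is not None else 4.0 / np.sqrt(n)
    try:
        _check_variation(A)
    except DataInvariantError as exc:
        raise ConvergenceError(str(exc)) from exc
    if max_iter <= 0:
        raise ConvergenceError("iteration cap is 0")

    starts = _chang_targets(spec.table, A, spec.seed)
    nev1, nev2 = _chang_events(spec.table, A, np.zeros(2 * p))

    def u1(b1):
        return chang_U(spec.table, A, np.concatenate([b1, b1]))[0]

    def valid1(b1):
        return _chang_events(spec.table, A, np.concatenate([b1, b1]))[0] >= 0.5 * nev1

    b1, r1 = _nm_solve(u1, starts, max_iter, tol, valid=valid1)
    if r1 > tol:
        raise ConvergenceError(f"||U1||_inf = {r1:.4g} > tol = {tol:.4g}")

    def u2(b2):
        return chang_U(spec.table, A, np.concatenate([b1, b2]))[1]

    def valid2(b2):
        return _chang_events(spec.table, A, np.concatenate([b1, b2]))[1] >= 0.5 * nev2

    b2, r2 = _nm_solve(u2, starts, max_iter, tol, valid=valid2)
    if r2 > tol:
        raise ConvergenceError(f"||U2||_inf = {r2:.4g} > tol = {tol:.4g}")
    return AFTFit(
        beta1=np.asarray(b1),
        beta2=np.asarray(b2),
        covariates=tuple(spec.covariates),
        method="chang",
        converged=True,
        n_used=n,
        residual_norm=max(r1, r2),
        level=spec.level,
    )


def parzen_resample_vcov(spec: RegressionSpec, fit: AFTFit) -> np.ndarray:
    """Perturbed-estimating-equation variance for the rank-based fit.

    For each replicate, solves ``U(b) = u*_r`` where the perturbation
    target is generated on the scale of U's own sampling noise:
    ``u*_r = n^{-1/2} sum_i G_i phi_i(beta-hat)`` with i.i.d. standard
    normal subject multipliers ``G_i`` and ``phi_i`` the per-subject
    summands of the estimating function at the fit.  The empirical
    covariance of the replicate solutions estimates the covariance of
    the estimator (the ``n^{-1/2}`` scaling of U makes the two directly
    comparable).  Deterministic given ``spec.seed``.  Raises if more
    than 20% of replicates fail to solve.
    """
    if spec.n_resample < 2:
        raise ValueError("n_resample must be at least 2 to form a covariance")
    A = spec.prepared()
    p = A.shape[1]
    n = spec.table.n
    max_iter = spec.max_iter if spec.max_iter is not None else 1000
    tol = spec.tol if spec.tol is not None else 4.0 / np.sqrt(n)
    rng = np.random.default_rng(spec.seed)
    _, _, phi1, phi2 = chang_U(
        spec.table, A, np.concatenate([fit.beta1, fit.beta2]),
        return_subject_terms=True,
    )
    sols, failures = [], 0
    for _ in range(spec.n_resample):
        g = rng.standard_normal(n)
        zr = np.concatenate([g @ phi1, g @ phi2]) / np.sqrt(n)
        starts1 = [fit.beta1, np.zeros(p)]

        def u1(b1, _z=zr[:p]):
            return chang_U(spec.table, A, np.concatenate([b1, b1]))[0] - _z

        b1, r1 = _nm_solve(u1, starts1, max_iter, tol)
        if r1 > tol:
            failures += 1
            continue

        def u2(b2, _z=zr[p:], _b1=b1):
            return chang_U(spec.table, A, np.concatenate([_b1, b2]))[1] - _z

        b2, r2 = _nm_solve(u2, [fit.beta2, np.zeros(p)], max_iter, tol)
        if r2 > tol:
            failures += 1
            continue
        sols.append(np.concatenate([b1, b2]))
    if failures > 0.2 * spec.n_resample:
        raise ConvergenceError(
            f"{failures}/{spec.n_resample} resampling replicates failed to "
            "converge; consider method='lee'"
        )
    V = np.cov(np.asarray(sols).T)
    fit.vcov = 0.5 * (V + V.T)
    return fit.vcov


# ====================================================================== #
# Lee et al.: smooth U-statistic estimating equations
# ====================================================================== #
@dataclass
class CensoringKM:
    """Kaplan-Meier estimate of the censoring survival G.

    Built by treating censoring as the event: ``which=1`` uses the
    first-episode Type I times with indicator ``1 - d1``; ``which=2``
    the first-episode total gaps with ``1 - d2``.
    """

    support_times: np.ndarray
    survival: np.ndarray
    which: int
    L: float

    def G(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        idx = np.searchsorted(self.support_times, t, side="right") - 1
        s = np.concatenate([[1.0], self.survival])
        return s[idx + 1]

    @property
    def zero_time(self) -> float:
        """Smallest time at which G hits zero (inf when it never does)."""
        hit = np.nonzero(self.survival <= 0)[0]
        return float(self.support_times[hit[0]]) if len(hit) else np.inf


def censoring_km(table: EpisodeTable, which: int) -> CensoringKM:
    """Censoring-survival Kaplan-Meier from first-episode data."""
    first = table.df.groupby("id", sort=False).first()
    first = first.loc[table.subject_ids]
    if which == 1:
        t = first["xij"].to_numpy(float)
        ev = 1 - first["d1"].to_numpy(int)
    elif which == 2:
        t = (first["xij"] + first["yij"]).to_numpy(float)
        ev = 1 - first["d2"].to_numpy(int)
    else:
        raise ValueError("which must be 1 or 2")
    # default trimming bound: largest uncensored first-episode time
    if (ev == 0).any():
        L = float(t[ev == 0].max())
    else:
        L = float(t.max())
    if ev.sum() == 0:
        logger.info("censoring KM (which=%d): no censoring events, G == 1", which)
        return CensoringKM(np.array([]), np.array([]), which, L)
    km = KaplanMeierFitter()
    km.fit(t, event_observed=ev)
    sf = km.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    keep = times > 0
    return CensoringKM(times[keep], surv[keep], which, L)


def o_kernel(s, t, L):
    """Gehan-type log kernel O_L(s, t) = log(min(max(t, s), L)) - log(L).

    Symmetric, nonpositive, and monotone in each argument; caps both
    arguments at the trimming bound L.
    """
    s = np.asarray(s, float)
    t = np.asarray(t, float)
    if np.any(s <= 0) or np.any(t <= 0) or L <= 0:
        raise ValueError("o_kernel requires positive s, t and L")
    return np.log(np.minimum(np.maximum(t, s), L)) - np.log(L)


def default_L(table: EpisodeTable) -> float:
    """Trimming bound: largest uncensored first-episode total gap."""
    first = table.df.groupby("id", sort=False).first()
    z1 = (first["xij"] + first["yij"]).to_numpy(float)
    d2 = first["d2"].to_numpy(int)
    if (d2 == 1).any():
        return float(z1[d2 == 1].max())
    return float(z1.max())


@dataclass
class _LeeWork:
    """Precomputed arrays for repeated evaluation of D1*/D2*."""

    A: np.ndarray            # (n, p)
    subj: np.ndarray         # (R,) row -> subject
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    c1: np.ndarray           # (R,) dX * (1/m*) / G1(x ^ L)
    c2: np.ndarray           # (R,) dY * (1/m*) / G2(z ^ L)
    L: float
    n: int


def _lee_work(
    table: EpisodeTable,
    A: np.ndarray,
    km1: CensoringKM | None = None,
    km2: CensoringKM | None = None,
    L: float | None = None,
) -> _LeeWork:
    km1 = km1 or censoring_km(table, 1)
    km2 = km2 or censoring_km(table, 2)
    if L is None:
        L = default_L(table)
    # keep the inverse weights finite: stay strictly below the first time
    # either censoring KM hits zero
    zcap = min(km1.zero_time, km2.zero_time)
    if L >= zcap:
        L_new = zcap * (1 - 1e-12)
        logger.info("trimming bound reduced from %g to %g to keep G > 0", L, L_new)
        L = L_new
    subj, epi, x, y, d1, d2, w = _rows(table)
    z = x + y
    g1 = km1.G(np.minimum(x, L)) if len(km1.support_times) else np.ones_like(x)
    g2 = km2.G(np.minimum(z, L)) if len(km2.support_times) else np.ones_like(z)
    # uncensored rows within j <= m* carry d = 1; the D sums only use those
    dX = d1
    dY = d2
    c1 = np.where(dX == 1, w / np.where(g1 > 0, g1, 1.0), 0.0)
    c2 = np.where(dY == 1, w / np.where(g2 > 0, g2, 1.0), 0.0)
    if np.any((dX == 1) & (g1 <= 0)) or np.any((dY == 1) & (g2 <= 0)):
        raise DataInvariantError("censoring survival is zero on needed support")
    return _LeeWork(A, subj, x, y, z, c1, c2, L, table.n)


def _lee_D1(work: _LeeWork, b1: np.ndarray) -> np.ndarray:
    """D1*(b1): n^-2 double sum of A_ii' weighted log-kernel comparisons."""
    u = np.exp(work.A @ b1)  # (n,)
    rows = work.c1 > 0
    x = work.x[rows]
    c = work.c1[rows]
    s = work.subj[rows]
    # pairwise-transformed X_ii'j = exp(A_ii''b1) X_ij = (u_i'/u_i) X_ij
    Xp = (x / u[s])[:, None] * u[None, :]  # (R, n)
    M = np.log(np.minimum(np.maximum(Xp, x[:, None]), work.L)) - np.log(work.L)
    V = M * c[:, None]
    term_pos = V.sum(axis=0) @ work.A          # sum_r sum_i' V A_i'
    term_neg = V.sum(axis=1) @ work.A[s]       # sum_r (sum_i' V) A_i
    return (term_pos - term_neg) / work.n**2


def _lee_D2(work: _LeeWork, b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    u1 = np.exp(work.A @ b1)
    u2 = np.exp(work.A @ b2)
    rows = work.c2 > 0
    x = work.x[rows]
    y = work.y[rows]
    z = work.z[rows]
    c = work.c2[rows]
    s = work.subj[rows]
    Zp = (x / u1[s])[:, None] * u1[None, :] + (y / u2[s])[:, None] * u2[None, :]
    M = np.log(np.minimum(np.maximum(Zp, z[:, None]), work.L)) - np.log(work.L)
    V = M * c[:, None]
    term_pos = V.sum(axis=0) @ work.A
    term_neg = V.sum(axis=1) @ work.A[s]
    return (term_pos - term_neg) / work.n**2


def lee_D(
    table: EpisodeTable,
    A: np.ndarray,
    b: np.ndarray,
    km1: CensoringKM | None = None,
    km2: CensoringKM | None = None,
    L: float | None = None,
):
    """Evaluate the pair of U-statistic estimating functions at b."""
    _check_variation(A)
    p = A.shape[1]
    work = _lee_work(table, A, km1, km2, L)
    return _lee_D1(work, b[:p]), _lee_D2(work, b[:p], b[p:])


def _newton(fun, b0, max_iter, tol, h_scale=1e-5):
    """Damped Newton with central-difference Jacobian and backtracking."""
    b = np.asarray(b0, float).copy()
    f = fun(b)
    for _ in range(max_iter):
        if np.max(np.abs(f)) < tol:
            return b, float(np.max(np.abs(f)))
        p = len(b)
        J = np.empty((p, p))
        for k in range(p):
            h = h_scale * max(1.0, abs(b[k]))
            bp, bm = b.copy(), b.copy()
            bp[k] += h
            bm[k] -= h
            J[:, k] = (fun(bp) - fun(bm)) / (2 * h)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step = -np.linalg.pinv(J) @ f
        lam = 1.0
        for _bt in range(40):
            cand = b + lam * step
            fc = fun(cand)
            if np.linalg.norm(fc) < np.linalg.norm(f):
                b, f = cand, fc
                break
            lam *= 0.5
        else:
            break  # stalled
    return b, float(np.max(np.abs(f)))


def solve_lee(spec: RegressionSpec) -> AFTFit:
    """Point estimation by the smooth U-statistic method.

    Solves D1*(b1) = 0 first, then D2*((beta1, b2)) = 0 with beta1 fixed;
    monotonicity of the smooth equations makes the roots unique, so a
    damped Newton iteration (with a hybrid-Powell fallback) suffices.
    """
    A = spec.prepared()
    p = A.shape[1]
    max_iter = spec.max_iter if spec.max_iter is not None else 100
    tol = spec.tol if spec.tol is not None else 1e-8
    _check_variation(A)
    if max_iter <= 0:
        raise ConvergenceError("iteration cap is 0")
    work = _lee_work(spec.table, A)

    def stage(fun, b0):
        b, r = _newton(fun, b0, max_iter, tol)
        if r > tol:
            res = optimize.root(fun, b, method="hybr")
            r2 = float(np.max(np.abs(fun(res.x))))
            if r2 < r:
                b, r = res.x, r2
        if r > tol:
            raise ConvergenceError(f"||D||_inf = {r:.4g} > tol = {tol:.4g}")
        return b, r

    b1, r1 = stage(lambda v: _lee_D1(work, v), np.zeros(p))
    b2, r2 = stage(lambda v: _lee_D2(work, b1, v), np.zeros(p))
    return AFTFit(
        beta1=np.asarray(b1),
        beta2=np.asarray(b2),
        covariates=tuple(spec.covariates),
        method="lee",
        converged=True,
        n_used=spec.table.n,
        residual_norm=max(r1, r2),
        level=spec.level,
    )


def _pair_kernels(work: _LeeWork, b1: np.ndarray, b2: np.ndarray):
    """Scalar pairwise kernels k1[i, i'], k2[i, i'] at the fitted b.

    The estimating functions decompose as
    D = n^-2 sum_{i, i'} (A_i' - A_i) k[i, i'], which lets the
    subject-level bootstrap re-weight subjects without re-evaluating the
    log-kernel comparisons.
    """
    n = work.n
    out = []
    for which in (1, 2):
        if which == 1:
            u = np.exp(work.A @ b1)
            rows = work.c1 > 0
            t = work.x[rows]
            Tp = (t / u[work.subj[rows]])[:, None] * u[None, :]
            c = work.c1[rows]
        else:
            u1 = np.exp(work.A @ b1)
            u2 = np.exp(work.A @ b2)
            rows = work.c2 > 0
            t = work.z[rows]
            Tp = (work.x[rows] / u1[work.subj[rows]])[:, None] * u1[None, :] + (
                work.y[rows] / u2[work.subj[rows]]
            )[:, None] * u2[None, :]
            c = work.c2[rows]
        M = (np.log(np.minimum(np.maximum(Tp, t[:, None]), work.L)) - np.log(work.L)) * c[
            :, None
        ]
        K = np.zeros((n, n))
        np.add.at(K, work.subj[rows], M)
        out.append(K)
    return out  # [k1, k2], each (n, n): rows index i, cols i'


def _D_from_kernel(K: np.ndarray, A: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """D block for a bootstrap index multiset, from the pairwise kernel."""
    n = len(idx)
    Ks = K[np.ix_(idx, idx)]
    Ai = A[idx]
    return (Ks.sum(axis=0) @ Ai - Ks.sum(axis=1) @ Ai) / n**2


def lee_vcov(
    spec: RegressionSpec,
    fit: AFTFit,
    n_boot: int | None = None,
    full_bootstrap: bool = False,
) -> np.ndarray:
    """Sandwich variance for the smooth-equation fit.

    Middle term: subject-level bootstrap covariance of the stacked
    estimating functions at the fitted coefficients (pairwise kernels
    precomputed, censoring weights held fixed).  Bread: numerical
    Jacobian by central differences.  ``full_bootstrap=True`` instead
    refits the whole estimator on each resampled dataset.  Deterministic
    given ``spec.seed``.
    """
    A = spec.prepared()
    p = A.shape[1]
    n = spec.table.n
    B = n_boot if n_boot is not None else (spec.n_resample or 200)
    rng = np.random.default_rng(spec.seed)

    if full_bootstrap:
        sols = []
        for _ in range(B):
            idx = rng.integers(0, n, n)
            parts = []
            ids = spec.table.subject_ids
            for new_id, k in enumerate(idx):
                grp = spec.table.df[spec.table.df["id"] == ids[k]].copy()
                grp["id"] = new_id
                parts.append(grp)
            rep_table = EpisodeTable(
                pd.concat(parts, ignore_index=True), spec.table.covariate_names
            )
            try:
                rep_fit = solve_lee(
                    RegressionSpec(
                        rep_table, spec.covariates, "lee", spec.level,
                        spec.max_iter, spec.tol,
                    )
                )
            except (ConvergenceError, DataInvariantError):
                continue
            sols.append(rep_fit.beta)
        V = np.cov(np.asarray(sols).T)
        fit.vcov = 0.5 * (V + V.T)
        return fit.vcov

    work = _lee_work(spec.table, A)
    K1, K2 = _pair_kernels(work, fit.beta1, fit.beta2)

    # bread: Jacobian of stacked (D1(b1), D2(b1, b2)) at the fit
    def stacked(b):
        return np.concatenate([_lee_D1(work, b[:p]), _lee_D2(work, b[:p], b[p:])])

    beta = fit.beta
    Sig = np.empty((2 * p, 2 * p))
    for k in range(2 * p):
        h = 1e-5 * max(1.0, abs(beta[k]))
        bp, bm = beta.copy(), beta.copy()
        bp[k] += h
        bm[k] -= h
        Sig[:, k] = (stacked(bp) - stacked(bm)) / (2 * h)
    cond = np.linalg.cond(Sig)
    if not np.isfinite(cond) or cond > 1e12:
        raise DataInvariantError(
            f"singular estimating-function Jacobian (condition number {cond:.3g})"
        )

    # middle: bootstrap the estimating function through the kernels
    Ds = np.empty((B, 2 * p))
    for r in range(B):
        idx = rng.integers(0, n, n)
        Ds[r, :p] = _D_from_kernel(K1, A, idx)
        Ds[r, p:] = _D_from_kernel(K2, A, idx)
    Omega = np.cov(Ds.T)
    Sinv = np.linalg.inv(Sig)
    V = Sinv @ Omega @ Sinv.T
    fit.vcov = 0.5 * (V + V.T)
    return fit.vcov


# ---------------------------------------------------------------------- #
# fitting front door and summaries
# ---------------------------------------------------------------------- #
def fit_aft(spec: RegressionSpec) -> AFTFit:
    """Fit the AFT model and attach the method's variance estimate."""
    if spec.method == "lee":
        fit = solve_lee(spec)
        lee_vcov(spec, fit)
    else:
        fit = solve_chang(spec)
        parzen_resample_vcov(spec, fit)
    return fit


def summarize(fit: AFTFit, level: float | None = None) -> pd.DataFrame:
    """Coefficient table: estimate, SE, z, two-sided p, Wald CI."""
    if not fit.converged:
        raise ValueError("fit did not converge; no summary available")
    lo, hi = fit.ci(level)
    return pd.DataFrame(
        {
            "estimate": fit.beta,
            "se": fit.se,
            "z": fit.z,
            "p_value": fit.p_value,
            "ci_low": lo,
            "ci_high": hi,
        },
        index=fit.names,
    )


def coef(fit: AFTFit) -> pd.Series:
    if not fit.converged:
        raise ValueError("fit did not converge; coefficients unavailable")
    return pd.Series(fit.beta, index=fit.names)


def confint(
    fit: AFTFit, parm: Sequence[str] | None = None, level: float | None = None
) -> pd.DataFrame:
    lo, hi = fit.ci(level)
    out = pd.DataFrame({"ci_low": lo, "ci_high": hi}, index=fit.names)
    if parm is not None:
        unknown = [q for q in parm if q not in fit.names]
        if unknown:
            raise KeyError(
                f"unknown parameter(s) {unknown}; valid names: {fit.names}"
            )
        out = out.loc[list(parm)]
    return out


def vcov(fit: AFTFit) -> pd.DataFrame:
    fit._require_vcov()
    return pd.DataFrame(fit.vcov, index=fit.names, columns=fit.names)
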