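"""Nonparametric estimation for bivariate alternating gap times.

Estimates three population quantities for the latent (uncensored) gap
pairs ``(X0, Y0)``:

* the joint CDF ``F(x, y) = Pr(X0 <= x, Y0 <= y)``, via a weighted
  product-limit representation over distinct uncensored total-gap times,
* the marginal survival ``S_X(x) = Pr(X0 >= x)`` of Type I gaps, via the
  analogous product-limit estimator on Type I gaps alone,
* the conditional CDF ``Pr(Y0 <= y | v1 <= X0 <= v2)`` as a ratio of the
  two.

The marginal distribution of Type II gaps is *not* estimable: its
censoring time depends on the preceding Type I gap (induced dependent
censoring), so only the conditional distribution is offered.

All sums weight subject ``i`` by ``a_i / m*_i`` over its first ``m*_i``
episodes, which corrects for the informative number of episodes per
subject; ``a_i`` is either 1 or the follow-up time ``C_i``.  Standard
errors come from a subject-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import EpisodeTable, validate

logger = logging.getLogger("altrec")

LEVEL_RANGE_MSG = "confidence level must be between 0.50 and 0.99"


class ConfigError(ValueError):
    pass


@dataclass
class NPConfig:
    """Settings for :func:`run_nonparametric`.

    level is the pointwise confidence level (in [0.50, 0.99]); ai selects
    the subject weight (1 -> a_i = 1, 2 -> a_i = C_i); u1/u2 are the
    joint-CDF evaluation grids (deciles of the observed uncensored gaps
    when omitted); given_interval = (v1, v2) conditions the Type II CDF
    on v1 <= X0 <= v2 and is required when conditional is on.
    """

    level: float = 0.95
    ai: int = 1
    u1: Sequence[float] | None = None
    u2: Sequence[float] | None = None
    conditional: bool = False
    given_interval: tuple[float, float] | None = None
    n_boot: int = 200
    seed: int | None = None

    def check(self) -> "NPConfig":
        if not (0.50 <= self.level <= 0.99):
            raise ConfigError(
                f"{LEVEL_RANGE_MSG} (got {self.level})"
            )
        if self.ai not in (1, 2):
            raise ConfigError(f"ai must be 1 or 2 (got {self.ai})")
        if self.conditional:
            if self.given_interval is None:
                raise ConfigError(
                    "given_interval must be specified if conditional is on"
                )
            v1, v2 = self.given_interval
            if not v1 < v2:
                raise ConfigError(
                    f"given_interval must satisfy v1 < v2 (got {v1}, {v2})"
                )
        return self


# ---------------------------------------------------------------------- #
# risk and jump functions
# ---------------------------------------------------------------------- #
def _episode_arrays(table: EpisodeTable, ai: int):
    """Flatten the first m*_i episodes of every subject into arrays.

    Returns (subj_idx, x, y, z, d1, w, hw) where w = a_i / m*_i is the
    at-risk weight and hw = a_i I(m_i >= 2) / m*_i the jump weight.
    """
    m = table.m
    mstar = table.m_star
    a = table.follow_up if ai == 2 else np.ones(table.n)
    sid_order = {s: k for k, s in enumerate(table.subject_ids)}
    df = table.df
    subj = df["id"].map(sid_order).to_numpy()
    # keep rows with episode index <= m* of their subject
    epi = df.groupby("id", sort=False).cumcount().to_numpy() + 1
    keep = epi <= mstar[subj]
    subj = subj[keep]
    x = df["xij"].to_numpy(float)[keep]
    y = df["yij"].to_numpy(float)[keep]
    d1 = df["d1"].to_numpy(int)[keep]
    w = (a / mstar)[subj]
    hw = (a * (m >= 2) / mstar)[subj]
    return subj, x, y, x + y, d1, w, hw


@dataclass
class RiskJumpFunctions:
    """Weighted at-risk and jump processes of total gap times.

    t_star are the distinct uncensored total-gap times; R(z) is the
    weighted at-risk mass n^-1 sum_i (a_i/m*_i) sum_j I(Z_ij >= z) and
    H(z, x, y) the weighted jump mass at z restricted to episodes with
    X <= x, Y <= y.  tau_c_hat is the estimated censoring support (the
    largest observed follow-up time); the joint CDF is never evaluated
    beyond it.
    """

    n: int
    t_star: np.ndarray              # sorted distinct uncensored Z
    R_at_t: np.ndarray              # R(t*_k)
    Hinf_at_t: np.ndarray           # H(t*_k, inf, inf)
    tau_c_hat: float
    # per-jump-episode data (uncensored rows only), for H(z, x, y)
    _jz: np.ndarray = field(repr=False, default=None)
    _jx: np.ndarray = field(repr=False, default=None)
    _jy: np.ndarray = field(repr=False, default=None)
    _jw: np.ndarray = field(repr=False, default=None)  # hw / n
    # full at-risk rows
    _rz: np.ndarray = field(repr=False, default=None)
    _rw: np.ndarray = field(repr=False, default=None)  # w / n

    @property
    def tau_trim(self) -> float:
        # evaluation bound L; estimates are refused, never extrapolated,
        # beyond the censoring support
        return self.tau_c_hat

    def R(self, z: float) -> float:
        return float(self._rw[self._rz >= z].sum())

    def H(self, z: float, x: float = np.inf, y: float = np.inf) -> float:
        sel = (self._jz == z) & (self._jx <= x) & (self._jy <= y)
        return float(self._jw[sel].sum())

    def surv_prefactors(self) -> np.ndarray:
        """prod_{l<k} {1 - H(t*_l, inf)/R(t*_l)} for each k.

        This is the product-limit survival of the total gap evaluated
        just before t*_k (the left limit S_Z(t-)).
        """
        haz = self.Hinf_at_t / self.R_at_t
        return np.concatenate([[1.0], np.cumprod(1.0 - haz)])[:-1]

    def joint_at(self, x, y) -> np.ndarray:
        """Joint CDF estimate on broadcastable arrays of (x, y).

        Entries with x + y beyond the censoring support are NaN.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        x, y = np.broadcast_arrays(x, y)
        pref = self.surv_prefactors()
        # coefficient of each uncensored episode row: w/n * S_Z(t-)/R(t)
        k_of_row = np.searchsorted(self.t_star, self._jz)
        coef = self._jw * pref[k_of_row] / self.R_at_t[k_of_row]
        xs = x.ravel()[:, None]
        ys = y.ravel()[:, None]
        ind = (
            (self._jz[None, :] <= xs + ys)
            & (self._jx[None, :] <= xs)
            & (self._jy[None, :] <= ys)
        )
        out = ind @ coef
        out[xs.ravel() + ys.ravel() > self.tau_c_hat] = np.nan
        return out.reshape(x.shape)


def risk_jump_functions(table: EpisodeTable, ai: int = 1) -> RiskJumpFunctions:
    """Build the weighted risk/jump processes of the total gap times."""
    subj, x, y, z, d1, w, hw = _episode_arrays(table, ai)
    n = table.n
    m = table.m
    unc = m[subj] >= 2  # rows j <= m* of subjects with >= 2 episodes are uncensored
    if not unc.any():
        raise DataInvariantError(
            "no uncensored episodes: every subject has a single, censored pair"
        )
    t_star = np.unique(z[unc])
    rw = w / n
    jw = (hw / n)[unc]
    jz, jx, jy = z[unc], x[unc], y[unc]
    # suffix sums over the sorted at-risk times give R at every jump
    order = np.argsort(z, kind="stable")
    suffix = np.concatenate([np.cumsum(rw[order][::-1])[::-1], [0.0]])
    R_at_t = suffix[np.searchsorted(z[order], t_star, side="left")]
    Hinf_at_t = np.zeros_like(t_star)
    np.add.at(Hinf_at_t, np.searchsorted(t_star, jz), jw)
    tau_c_hat = float(table.follow_up.max())
    return RiskJumpFunctions(
        n=n,
        t_star=t_star,
        R_at_t=R_at_t,
        Hinf_at_t=Hinf_at_t,
        tau_c_hat=tau_c_hat,
        _jz=jz,
        _jx=jx,
        _jy=jy,
        _jw=jw,
        _rz=z,
        _rw=rw,
    )


class DataInvariantError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# estimates
# ---------------------------------------------------------------------- #
@dataclass
class JointCDFEstimate:
    """Joint CDF on the grid u1 x u2; NaN where x + y exceeds the
    estimated censoring support (never extrapolated)."""

    x: np.ndarray                   # flattened grid, len = |u1|*|u2|
    y: np.ndarray
    estimate: np.ndarray
    tau_c_hat: float
    se: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        d = {"x": self.x, "y": self.y, "joint_cdf": self.estimate}
        if self.se is not None:
            d |= {"se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high}
        return pd.DataFrame(d)


@dataclass
class MarginalSurvivalEstimate:
    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.times, "survival": self.survival}
        if self.se is not None:
            d |= {"se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high}
        return pd.DataFrame(d)

    def at(self, x) -> np.ndarray:
        """Step-function evaluation S_X(x) (right-continuous... the
        product runs over jump times <= x)."""
        x = np.asarray(x, float)
        idx = np.searchsorted(self.times, x, side="right") - 1
        s = np.concatenate([[1.0], self.survival])
        return s[idx + 1]


@dataclass
class ConditionalCDFEstimate:
    y_grid: np.ndarray
    cdf: np.ndarray                 # clipped into [0, 1]
    raw: np.ndarray                 # unclipped diagnostic values
    interval: tuple[float, float]
    se: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        d = {"y": self.y_grid, "conditional_cdf": self.cdf}
        if self.se is not None:
            d |= {"se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high}
        return pd.DataFrame(d)


def joint_cdf(
    rj: RiskJumpFunctions, u1: Sequence[float], u2: Sequence[float]
) -> JointCDFEstimate:
    """Evaluate the joint CDF on the product grid u1 x u2."""
    u1 = np.asarray(u1, float)
    u2 = np.asarray(u2, float)
    gx, gy = np.meshgrid(u1, u2, indexing="ij")
    est = rj.joint_at(gx.ravel(), gy.ravel())
    return JointCDFEstimate(
        x=gx.ravel(), y=gy.ravel(), estimate=est, tau_c_hat=rj.tau_c_hat
    )


def marginal_survival(table: EpisodeTable, ai: int = 1) -> MarginalSurvivalEstimate:
    """Product-limit estimate of S_X over distinct uncensored Type I times."""
    subj, x, y, z, d1, w, hw = _episode_arrays(table, ai)
    n = table.n
    m = table.m
    unc = d1 == 1                 # X is uncensored wherever d1 = 1
    jumps = (m[subj] >= 2) & unc  # jump mass carries the I(m >= 2) factor
    x_star = np.unique(x[unc])
    rw = w / n
    order = np.argsort(x, kind="stable")
    suffix = np.concatenate([np.cumsum(rw[order][::-1])[::-1], [0.0]])
    R = suffix[np.searchsorted(x[order], x_star, side="left")]
    H = np.zeros_like(x_star)
    np.add.at(H, np.searchsorted(x_star, x[jumps]), (hw / n)[jumps])
    surv = np.cumprod(1.0 - H / R)
    return MarginalSurvivalEstimate(times=x_star, survival=surv)


def conditional_cdf(
    rj: RiskJumpFunctions,
    marg: MarginalSurvivalEstimate,
    interval: tuple[float, float],
    y_grid: Sequence[float],
) -> ConditionalCDFEstimate:
    """Estimate Pr(Y0 <= y | v1 <= X0 <= v2) on y_grid.

    Uses the difference form [F(v2, y) - F(v1, y)] / [S_X(v1) - S_X(v2)],
    which targets Pr(Y <= y, v1 < X <= v2) / Pr(v1 < X <= v2); the
    single-bound conditional Pr(Y <= y | X <= v2) is the special case
    v1 = 0.  Raw ratios can exceed [0, 1] in finite samples because
    numerator and denominator are estimated separately; the cdf field is
    clipped, the raw field is not.
    """
    v1, v2 = interval
    if not v1 < v2:
        raise ConfigError(f"interval must satisfy v1 < v2 (got {v1}, {v2})")
    y_grid = np.asarray(y_grid, float)
    denom = float(marg.at(v1) - marg.at(v2))
    if denom == 0.0:
        raise DataInvariantError(
            f"no Type I mass in the interval [{v1}, {v2}]: "
            "S_X(v1) - S_X(v2) = 0"
        )
    top2 = rj.joint_at(np.full_like(y_grid, v2), y_grid)
    top1 = (
        rj.joint_at(np.full_like(y_grid, v1), y_grid)
        if v1 > 0
        else np.zeros_like(y_grid)
    )
    raw = (top2 - top1) / denom
    return ConditionalCDFEstimate(
        y_grid=y_grid,
        cdf=np.clip(raw, 0.0, 1.0),
        raw=raw,
        interval=(v1, v2),
    )


# ---------------------------------------------------------------------- #
# bootstrap standard errors
# ---------------------------------------------------------------------- #
def _resample_table(table: EpisodeTable, rng: np.random.Generator) -> EpisodeTable:
    """Draw subjects with replacement; duplicates become distinct ids."""
    ids = table.subject_ids
    pick = rng.integers(0, len(ids), size=len(ids))
    parts = []
    for new_id, k in enumerate(pick):
        grp = table.df[table.df["id"] == ids[k]].copy()
        grp["id"] = new_id
        parts.append(grp)
    out = pd.concat(parts, ignore_index=True)
    return EpisodeTable(out, table.covariate_names)


def bootstrap_se(
    table: EpisodeTable,
    config: NPConfig,
    target: str,
    point: JointCDFEstimate | MarginalSurvivalEstimate | ConditionalCDFEstimate,
):
    """Subject-level bootstrap SEs and pointwise normal-quantile CIs.

    target is one of {"joint", "marginal", "conditional"}; the replicate
    estimates are evaluated on the point estimate's own grid.  A
    replicate with no uncensored episode is redrawn (up to 10 attempts,
    then skipped with a warning).  Deterministic given config.seed.
    """
    if config.n_boot < 2:
        raise ConfigError("n_boot must be at least 2 to form a standard error")
    if table.n < 2:
        raise ConfigError("bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(config.seed)
    reps = []
    for _ in range(config.n_boot):
        rep = None
        for _attempt in range(10):
            cand = _resample_table(table, rng)
            if (cand.m >= 2).any():
                rep = cand
                break
        if rep is None:
            logger.warning("bootstrap replicate skipped: no uncensored episode")
            continue
        if target == "joint":
            rj = risk_jump_functions(rep, config.ai)
            vals = rj.joint_at(point.x, point.y)
        elif target == "marginal":
            vals = marginal_survival(rep, config.ai).at(point.times)
        elif target == "conditional":
            rj = risk_jump_functions(rep, config.ai)
            marg = marginal_survival(rep, config.ai)
            try:
                vals = conditional_cdf(
                    rj, marg, point.interval, point.y_grid
                ).cdf
            except DataInvariantError:
                continue
        else:  # pragma: no cover
            raise ValueError(f"unknown target {target!r}")
        reps.append(vals)
    reps = np.asarray(reps, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid cells
        se = np.nanstd(reps, axis=0, ddof=1)
    q = stats.norm.ppf(0.5 + config.level / 2)
    center = {
        "joint": getattr(point, "estimate", None),
        "marginal": getattr(point, "survival", None),
        "conditional": getattr(point, "cdf", None),
    }[target]
    lo = np.clip(center - q * se, 0.0, 1.0)
    hi = np.clip(center + q * se, 0.0, 1.0)
    return se, lo, hi


# ---------------------------------------------------------------------- #
# orchestration
# ---------------------------------------------------------------------- #
@dataclass
class NPResult:
    joint: JointCDFEstimate
    marginal: MarginalSurvivalEstimate
    conditional: ConditionalCDFEstimate | None
    config: NPConfig

    def to_frames(self) -> dict[str, pd.DataFrame]:
        out = {
            "joint_cdf": self.joint.to_frame(),
            "marginal_survival": self.marginal.to_frame(),
        }
        if self.conditional is not None:
            out["conditional_cdf"] = self.conditional.to_frame()
        return out

    def head(self, k: int = 6) -> dict[str, pd.DataFrame]:
        return {name: df.head(k) for name, df in self.to_frames().items()}


def _default_grid(values: np.ndarray) -> np.ndarray:
    return np.unique(np.quantile(values, np.linspace(0.1, 1.0, 10)))


def run_nonparametric(table: EpisodeTable, config: NPConfig | None = None) -> NPResult:
    """Joint, marginal and (optionally) conditional estimates with SEs."""
    config = (config or NPConfig()).check()
    validate(table)
    rj = risk_jump_functions(table, config.ai)
    subj, x, y, z, d1, w, hw = _episode_arrays(table, config.ai)
    unc = table.m[subj] >= 2
    u1 = np.asarray(config.u1, float) if config.u1 is not None else _default_grid(x[unc])
    u2 = np.asarray(config.u2, float) if config.u2 is not None else _default_grid(y[unc])

    joint = joint_cdf(rj, u1, u2)
    joint.level = config.level
    joint.se, joint.ci_low, joint.ci_high = bootstrap_se(
        table, config, "joint", joint
    )

    marg = marginal_survival(table, config.ai)
    marg.level = config.level
    marg.se, marg.ci_low, marg.ci_high = bootstrap_se(
        table, config, "marginal", marg
    )

    cond = None
    if config.conditional:
        v1, v2 = config.given_interval
        ymax = rj.tau_c_hat - v2
        y_unc = y[unc & (y > 0)]
        grid = np.unique(np.quantile(y_unc[y_unc <= max(ymax, y_unc.min())],
                                     np.linspace(0.05, 1.0, 20)))
        cond = conditional_cdf(rj, marg, (v1, v2), grid)
        cond.level = config.level
        cond.se, cond.ci_low, cond.ci_high = bootstrap_se(
            table, config, "conditional", cond
        )
    return NPResult(joint=joint, marginal=marg, conditional=cond, config=config)
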