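"""Long-format data model for bivariate alternating recurrent event data.

Subjects alternate between two states (e.g., periods in care and breaks
from care).  Episode ``j`` of subject ``i`` is the pair of gap times
``(x_ij, y_ij)`` — the Type I gap followed by the Type II gap — with
censoring indicators ``(d1, d2)``.  Follow-up ends at a subject-level
censoring time, so the Type II gap of the last episode is always censored
(``d2 = 0``) and the Type I gap of the last episode may be.

The canonical container, :class:`EpisodeTable`, is a validated wrapper
around a :class:`pandas.DataFrame` in long format: one row per episode,
baseline covariates repeated across a subject's rows.  It derives the
per-subject quantities every estimator in this package consumes: the
episode count ``m_i``, the effective episode count ``m*_i`` (``m_i - 1``
for subjects with at least two episodes, else 1), the total gap
``z_ij = x_ij + y_ij``, and the observed follow-up time ``c_i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("altrec")

#: canonical internal column names, in order
REQUIRED_COLUMNS = ("id", "episode", "xij", "yij", "d1", "d2")

DATA_NOT_CLEANED = "Error: Data not cleaned"
TIME_VARYING = "Error: Time-varying covariates not allowed"


class InputError(ValueError):
    """Unreadable source, missing column, or empty input."""


class DataCleaningError(ValueError):
    """A structural rule of the alternating gap-time format is violated.

    The message always begins with ``"Error: Data not cleaned"``; detail
    lines identify the offending subject and rule.
    """

    def __init__(self, detail: str):
        super().__init__(f"{DATA_NOT_CLEANED}\n{detail}")
        self.detail = detail


class TimeVaryingCovariateError(ValueError):
    def __init__(self):
        super().__init__(TIME_VARYING)


class ConvergenceError(RuntimeError):
    """Estimating-equation solver hit its iteration cap."""

    def __init__(self, detail: str = ""):
        msg = "Error: Max Iterations reached. Did not converge."
        if detail:
            msg += f"\n{detail}"
        super().__init__(msg)


@dataclass
class EpisodeTable:
    """Validated long-format bivariate alternating recurrent event data.

    Rows are grouped by subject (in order of first appearance) and sorted
    by episode number within subject.  Construct via
    :func:`parse_long_table` or :meth:`from_frame`.
    """

    df: pd.DataFrame
    covariate_names: tuple[str, ...] = ()
    n_dropped_missing: int = 0
    _validated: bool = field(default=False, repr=False)

    # ------------------------------------------------------------------ #
    # derived per-subject quantities
    # ------------------------------------------------------------------ #
    @property
    def subject_ids(self) -> np.ndarray:
        """Subject identifiers in first-appearance order."""
        return self.df["id"].unique()

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def m(self) -> np.ndarray:
        """Episodes per subject, aligned with :attr:`subject_ids`."""
        counts = self.df.groupby("id", sort=False).size()
        return counts.loc[self.subject_ids].to_numpy()

    @property
    def m_star(self) -> np.ndarray:
        """Effective episode count: ``m - 1`` when ``m >= 2``, else 1.

        Weighting sums by ``1/m*`` over the first ``m*`` episodes offsets
        the informative number of episodes per subject.
        """
        m = self.m
        return np.where(m >= 2, m - 1, 1)

    @property
    def z(self) -> np.ndarray:
        """Total gap ``x + y`` per row."""
        return (self.df["xij"] + self.df["yij"]).to_numpy(float)

    @property
    def follow_up(self) -> np.ndarray:
        """Observed follow-up per subject, ``c_i = sum_j (x_ij + y_ij)``.

        Because the last Type II gap is censored at the end of follow-up,
        this reconstructs the censoring time ``C_i`` exactly.
        """
        tot = self.df.assign(_z=self.z).groupby("id", sort=False)["_z"].sum()
        return tot.loc[self.subject_ids].to_numpy(float)

    def covariate_matrix(self) -> np.ndarray:
        """Baseline covariates as an ``(n, p)`` array of floats."""
        first = self.df.groupby("id", sort=False).first()
        first = first.loc[self.subject_ids]
        return first[list(self.covariate_names)].to_numpy(float)

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        covariate_names: Sequence[str] = (),
        n_dropped_missing: int = 0,
    ) -> "EpisodeTable":
        cols = list(REQUIRED_COLUMNS) + list(covariate_names)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise InputError(f"missing column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise InputError("empty table: no episodes to analyze")
        out = df[cols].copy()
        # group by subject in first-appearance order; sort episodes within
        order = {sid: k for k, sid in enumerate(out["id"].unique())}
        out = out.sort_values(
            ["id", "episode"],
            key=lambda s: s.map(order) if s.name == "id" else s,
            kind="stable",
        ).reset_index(drop=True)
        return cls(out, tuple(covariate_names), n_dropped_missing)

    def to_csv(self, path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False)

    def __len__(self) -> int:
        return len(self.df)


def parse_long_table(
    source,
    column_map: Mapping[str, str] | None = None,
    covariate_names: Sequence[str] = (),
    sep: str | None = None,
) -> EpisodeTable:
    """Read long-format data from a CSV/TSV file or a DataFrame.

    Parameters
    ----------
    source
        Path to a delimited text file with a header row, or an in-memory
        :class:`pandas.DataFrame`.
    column_map
        Mapping from the canonical names ``id, episode, xij, yij, d1, d2``
        to the column names used in ``source``.  Omitted keys default to
        the canonical name itself (``epi`` is also accepted for
        ``episode``).
    covariate_names
        Baseline covariate columns to carry along.
    sep
        Field delimiter; inferred from the file extension when ``None``.

    Subjects with a missing value in any required column or requested
    covariate are dropped in full, and a message reports how many
    subjects were used out of the total.
    """
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        if sep is None:
            sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
        try:
            raw = pd.read_csv(source, sep=sep, na_values=["NA", ""])
        except OSError as exc:
            raise InputError(f"cannot read source: {exc}") from exc
    if len(raw) == 0:
        raise InputError("empty table: no episodes to analyze")

    cmap = dict(column_map or {})
    if "episode" not in cmap and "episode" not in raw.columns and "epi" in raw.columns:
        cmap["episode"] = "epi"
    rename = {}
    for canon in REQUIRED_COLUMNS:
        src = cmap.get(canon, canon)
        if src not in raw.columns:
            raise InputError(f"missing column: {src!r} (mapped to {canon!r})")
        rename[src] = canon
    df = raw.rename(columns=rename)
    for cov in covariate_names:
        if cov not in df.columns:
            raise InputError(f"missing column: {cov!r} (covariate)")

    needed = list(REQUIRED_COLUMNS) + list(covariate_names)
    n_total = df["id"].nunique()
    bad = df.loc[df[needed].isna().any(axis=1), "id"].unique()
    if len(bad):
        df = df[~df["id"].isin(bad)]
    n_used = df["id"].nunique()
    if n_used < n_total:
        logger.info(
            "Subjects with missing values removed: using %d of the %d subjects.",
            n_used,
            n_total,
        )
    if len(df) == 0:
        raise InputError("empty table after dropping subjects with missing values")
    return EpisodeTable.from_frame(
        df, covariate_names, n_dropped_missing=n_total - n_used
    )


# ---------------------------------------------------------------------- #
# validation
# ---------------------------------------------------------------------- #
def validate(table: EpisodeTable) -> EpisodeTable:
    """Check the structural rules of the observed-data format.

    Raises :class:`DataCleaningError` (message prefix
    ``"Error: Data not cleaned"``) on: negative gap times, an uncensored
    zero gap, non-consecutive or non-integer episode numbers within a
    subject, indicator values outside {0, 1}, ``(d1, d2) = (0, 1)`` in
    any episode, ``(d1, d2) = (1, 1)`` in a subject's last episode, or no
    subject with any uncensored episode (all ``d2 = 0``).  Returns the
    table unchanged when every rule holds; idempotent and side-effect
    free.
    """
    df = table.df
    x = df["xij"].to_numpy(float)
    y = df["yij"].to_numpy(float)
    d1 = df["d1"].to_numpy()
    d2 = df["d2"].to_numpy()

    if np.any(x < 0) or np.any(y < 0):
        sid = df.loc[(x < 0) | (y < 0), "id"].iloc[0]
        raise DataCleaningError(f"negative gap time for subject {sid!r}")
    if not np.isin(d1, (0, 1)).all() or not np.isin(d2, (0, 1)).all():
        bad = ~(np.isin(d1, (0, 1)) & np.isin(d2, (0, 1)))
        sid = df.loc[bad, "id"].iloc[0]
        raise DataCleaningError(
            f"censoring indicators must be 0 or 1 (subject {sid!r})"
        )
    # an uncensored zero gap has no log-scale representation
    zero_unc = ((x == 0) & (d1 == 1)) | ((y == 0) & (d2 == 1))
    if np.any(zero_unc):
        sid = df.loc[zero_unc, "id"].iloc[0]
        raise DataCleaningError(f"uncensored zero gap time for subject {sid!r}")
    if np.any((d1 == 0) & (d2 == 1)):
        sid = df.loc[(d1 == 0) & (d2 == 1), "id"].iloc[0]
        raise DataCleaningError(f"(d1, d2) = (0, 1) for subject {sid!r}")

    for sid, grp in df.groupby("id", sort=False):
        epi = grp["episode"].to_numpy()
        if not np.all(epi == np.round(epi)):
            raise DataCleaningError(
                f"non-integer episode number for subject {sid!r}"
            )
        if not np.array_equal(epi.astype(int), np.arange(1, len(epi) + 1)):
            raise DataCleaningError(
                f"episode numbers for subject {sid!r} are not consecutive "
                f"integers 1..{len(epi)}"
            )
        last = grp.iloc[-1]
        if last["d1"] == 1 and last["d2"] == 1:
            raise DataCleaningError(
                f"(d1, d2) = (1, 1) in the last episode of subject {sid!r}; "
                "if the censoring event fell on the same day as the last "
                "observed event, add a small quantity to the censoring time"
            )
    if np.all(d2 == 0):
        raise DataCleaningError(
            "no subject has any uncensored episode (all d2 = 0)"
        )
    table._validated = True
    return table


def check_time_invariant_covariates(table: EpisodeTable) -> EpisodeTable:
    """Require every covariate to be constant within every subject.

    Raises :class:`TimeVaryingCovariateError` (exact message
    ``"Error: Time-varying covariates not allowed"``) on any
    within-subject variation; vacuously passes with no covariates.
    """
    for cov in table.covariate_names:
        nun = table.df.groupby("id", sort=False)[cov].nunique(dropna=False)
        if (nun > 1).any():
            raise TimeVaryingCovariateError()
    return table
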