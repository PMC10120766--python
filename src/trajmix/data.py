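"""Long-format longitudinal data: loading, validation, derived covariates.

The whole package operates on one in-memory container, :class:`LongData`: a
validated long-format table with one row per subject-visit, a continuous
outcome, an observation time (any affine timescale; negative retrospective
times such as years before death are the motivating case) and optional
subject-constant covariate columns.

Missing-data policy is listwise deletion of rows with a missing identifier,
time or outcome, with the dropped count logged and recorded on the object.
Duplicate (subject, time) pairs are retained — the residual model absorbs
them — but flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger("trajmix")

#: Subject-count threshold below which a small-sample warning is emitted.
SMALL_SAMPLE_N = 50
#: Covariate warning fires when total fixed-effect count exceeds N / this.
COVARIATE_RATIO = 10


@dataclass
class LongData:
    """Validated long-format repeated-measures table.

    Attributes
    ----------
    df : pandas.DataFrame
        The cleaned table (retained rows only), original column names.
    id_col, outcome_col, time_col : str
        Names of the mandatory columns.
    n_dropped : int
        Rows removed by listwise deletion during loading.
    n_duplicates : int
        Retained rows that share a (subject, time) pair with another row.
    """

    df: pd.DataFrame
    id_col: str
    outcome_col: str
    time_col: str
    n_dropped: int = 0
    n_duplicates: int = 0
    warnings: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.df[self.id_col].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df[self.id_col].unique()

    def obs_per_subject(self) -> pd.Series:
        return self.df.groupby(self.id_col, sort=False).size()

    @property
    def time(self) -> np.ndarray:
        return self.df[self.time_col].to_numpy(float)

    @property
    def outcome(self) -> np.ndarray:
        return self.df[self.outcome_col].to_numpy(float)

    def covariate_table(self, names) -> pd.DataFrame:
        """One row per subject with the requested covariate columns.

        Raises
        ------
        ConfigurationError
            If a covariate column is absent.
        DataError
            If a covariate varies within a subject (time-varying covariates
            are rejected) or is missing for some subject.
        """
        names = list(names)
        for name in names:
            if name not in self.df.columns:
                raise ConfigurationError(f"covariate column {name!r} not found")
        if not names:
            return pd.DataFrame(index=pd.Index(self.subject_ids, name=self.id_col))
        grp = self.df.groupby(self.id_col, sort=False)[names]
        nun = grp.nunique(dropna=False)
        if (nun > 1).any().any():
            bad = [c for c in names if (nun[c] > 1).any()]
            raise DataError(
                f"covariates must be constant within subject; time-varying: {bad}"
            )
        tab = grp.first()
        for name in names:
            if tab[name].isna().any():
                subj = tab.index[tab[name].isna()][0]
                raise DataError(
                    f"missing covariate {name!r} for subject {subj!r}"
                )
            if not pd.api.types.is_numeric_dtype(tab[name]):
                raise DataError(f"covariate {name!r} is not numeric")
        return tab.loc[self.subject_ids]

    def to_csv(self, path) -> None:
        """Write the cleaned table back to CSV (round-trips exactly)."""
        self.df.to_csv(path, index=False)


def _validate_frame(df, id_col, outcome_col, time_col) -> LongData:
    for col in (id_col, outcome_col, time_col):
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} not found in data")
    n_in = len(df)
    for col in (outcome_col, time_col):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    keep = df[[id_col, outcome_col, time_col]].notna().all(axis=1)
    df = df.loc[keep].reset_index(drop=True)
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.info("dropped %d row(s) with missing id/outcome/time", n_dropped)
    if len(df) == 0:
        raise DataError("no usable rows after removing missing id/outcome/time")
    dup_mask = df.duplicated(subset=[id_col, time_col], keep=False)
    n_dup = int(dup_mask.sum())
    data = LongData(
        df=df,
        id_col=id_col,
        outcome_col=outcome_col,
        time_col=time_col,
        n_dropped=n_dropped,
        n_duplicates=n_dup,
    )
    if n_dup:
        msg = f"{n_dup} row(s) share a (subject, time) pair; retained as repeats"
        data.warnings.append(msg)
        logger.warning(msg)
    logger.info(
        "loaded %d observations on %d subjects (median %d per subject)",
        data.n_obs,
        data.n_subjects,
        int(data.obs_per_subject().median()),
    )
    return data


def load_long_data(path, id_col, outcome_col, time_col) -> LongData:
    """Read a long-format CSV and return a validated :class:`LongData`.

    The CSV must have a header row, '.' decimal separator and the three named
    columns. Rows with missing subject id, time or outcome are dropped
    (listwise deletion) and counted.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise ConfigurationError(f"data file not found: {path}") from None
    except pd.errors.EmptyDataError:
        raise DataError(f"data file is empty: {path}") from None
    return _validate_frame(df, id_col, outcome_col, time_col)


def from_frame(df: pd.DataFrame, id_col, outcome_col, time_col) -> LongData:
    """Validate an in-memory data frame (same contract as :func:`load_long_data`)."""
    return _validate_frame(df.copy(), id_col, outcome_col, time_col)


def derive_centered_covariate(data: LongData, source, center, new_name) -> LongData:
    """Append ``new_name = source - center`` (e.g. ageDeath90 = ageDeath - 90)."""
    if source not in data.df.columns:
        raise ConfigurationError(f"source column {source!r} not found")
    if not pd.api.types.is_numeric_dtype(data.df[source]):
        raise DataError(f"source column {source!r} is not numeric")
    df = data.df.copy()
    df[new_name] = df[source] - center
    return LongData(
        df=df,
        id_col=data.id_col,
        outcome_col=data.outcome_col,
        time_col=data.time_col,
        n_dropped=data.n_dropped,
        n_duplicates=data.n_duplicates,
        warnings=list(data.warnings),
    )


def emit_data_warnings(data: LongData, spec=None,
                       small_sample_n=SMALL_SAMPLE_N,
                       covariate_ratio=COVARIATE_RATIO) -> list:
    """Return the data-adequacy warnings for a planned fit; never raises.

    Two documented checks, both with user-overridable thresholds:

    * small sample — fewer than ``small_sample_n`` subjects;
    * covariate count — total number of fixed effects (4 structural means
      plus every covariate coefficient) exceeds N / ``covariate_ratio``.
    """
    out = []
    n = data.n_subjects
    if n < small_sample_n:
        out.append(
            f"small sample: {n} subjects (< {small_sample_n}); "
            "estimates and standard errors may be unstable"
        )
    if spec is not None:
        p_total = spec.n_fixed_effects()
        if p_total > n / covariate_ratio:
            out.append(
                f"many fixed effects: {p_total} coefficients for {n} subjects "
                f"(> N/{covariate_ratio}); consider fewer covariates"
            )
    if data.n_duplicates:
        out.append(
            f"{data.n_duplicates} duplicated (subject, time) rows retained"
        )
    for w in out:
        logger.warning(w)
    return out
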