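"""Cohort tables and case-cohort samples.

A *cohort table* is a pandas DataFrame with one row per individual and
columns::

    id          unique identifier
    sex         "female" | "male"
    entry_age   age at study inclusion (years)
    exit_age    age at event or censoring (years); exit_age > entry_age
    event       1 if incident VTE, else 0
    bmi         body mass index (kg/m^2)
    <snp_id>    one column per panel SNP: risk-allele count 0/1/2 or NA

A :class:`CaseCohortSample` is the analysis dataset of a case-cohort design:
all incident cases plus a simple random subcohort drawn from the full source
cohort. Because subcohort sampling ignores case status, cases can also be
subcohort members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import Panel

__all__ = ["CaseCohortSample", "validate_cohort", "write_cohort", "read_cohort",
           "BASE_COLUMNS"]

BASE_COLUMNS = ["id", "sex", "entry_age", "exit_age", "event", "bmi"]


def validate_cohort(df: pd.DataFrame, panel: Panel | None = None) -> pd.DataFrame:
    """Validate a cohort table against the schema; returns ``df`` unchanged."""
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate individual id {dup!r}")
    bad_sex = set(df["sex"].unique()) - {"female", "male"}
    if bad_sex:
        raise ValueError(f"unknown sex values {sorted(bad_sex)}")
    if (df["entry_age"] < 0).any():
        raise ValueError("negative entry_age")
    nonpos = df["exit_age"] <= df["entry_age"]
    if nonpos.any():
        ident = df.loc[nonpos, "id"].iloc[0]
        raise ValueError(f"exit_age <= entry_age for individual {ident!r}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    if panel is not None:
        absent = [s for s in panel.snp_ids if s not in df.columns]
        if absent:
            raise ValueError(f"cohort table missing genotype columns: {absent}")
        known = set(BASE_COLUMNS) | {"in_subcohort", "is_case"} | set(panel.snp_ids)
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ValueError(f"unknown SNP columns not in panel: {unknown}")
        for s in panel.snp_ids:
            vals = df[s]
            ok = vals.isna() | vals.isin([0, 1, 2])
            if not ok.all():
                ident = df.loc[~ok, "id"].iloc[0]
                raise ValueError(
                    f"invalid genotype {vals[~ok].iloc[0]!r} for individual "
                    f"{ident!r} at SNP {s}"
                )
    return df


@dataclass
class CaseCohortSample:
    """All cases plus a random subcohort, with membership flags.

    Attributes
    ----------
    data
        The retained rows; includes boolean columns ``in_subcohort`` and
        ``is_case`` (``is_case`` mirrors ``event``).
    subcohort_size, source_size
        Sizes of the subcohort and of the source cohort it was drawn from.
    sampling_fraction
        ``subcohort_size / source_size``.
    """

    data: pd.DataFrame
    subcohort_size: int
    source_size: int
    sampling_fraction: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        for col in ("in_subcohort", "is_case"):
            if col not in self.data.columns:
                raise ValueError(f"case-cohort sample missing column {col!r}")
        if np.isnan(self.sampling_fraction):
            self.sampling_fraction = self.subcohort_size / self.source_size
        keep = self.data["in_subcohort"] | self.data["is_case"]
        if not keep.all():
            raise ValueError("sample contains rows neither in subcohort nor cases")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_cases(self) -> int:
        return int(self.data["is_case"].sum())

    @property
    def n_overlap(self) -> int:
        """Cases that were by chance also sampled into the subcohort."""
        return int((self.data["is_case"] & self.data["in_subcohort"]).sum())

    def restrict_sex(self, sex: str) -> "CaseCohortSample":
        if sex not in ("female", "male"):
            raise ValueError(f"unknown sex {sex!r}")
        sub = self.data[self.data["sex"] == sex]
        return CaseCohortSample(
            sub.reset_index(drop=True),
            subcohort_size=int(sub["in_subcohort"].sum()),
            source_size=self.source_size,
            sampling_fraction=self.sampling_fraction,
        )


_MISSING_TOKEN = "NA"


def write_cohort(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a cohort table (or case-cohort data) as delimited text."""
    out = df.copy()
    for col in ("event", "in_subcohort", "is_case"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep=sep, index=False, na_rep=_MISSING_TOKEN)


def read_cohort(path, panel: Panel | None = None, sep: str = "\t") -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort` and validate it.

    Missing genotypes are encoded as ``NA`` in the file and come back as NaN.
    """
    try:
        df = pd.read_csv(path, sep=sep, na_values=[_MISSING_TOKEN], keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort file {path}: {exc}") from exc
    for col in ("event", "in_subcohort", "is_case"):
        if col in df.columns:
            df[col] = df[col].astype(bool) if col != "event" else df[col].astype(int)
    validate_cohort(df, panel)
    return df
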