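"""Cohort domain model: beneficiaries, strata ingredients, ZIP attributes.

The cohort is an *open* cohort of elderly beneficiaries: individuals enter
during the study window (at the window start, or later when they become
eligible), and exit at death or administrative censoring. In memory a cohort
is a pair of pandas DataFrames:

``cohort``
    one row per beneficiary with columns ``id, birth_month, sex, race,
    follow_up_start, follow_up_end, death_month, icd10_cause``
    (months as integer indices, see :mod:`pmcox.months`);
``residence``
    long format, one row per residence segment: ``id, start_month, zip``.
    A segment runs until the next segment's start (or the end of follow-up).

Baseline hazards are stratified on attained age (one-year bins 65..89 plus a
single open 90+ bin), sex, race, ZIP code and optionally a ZIP-level income
tertile, so this module also provides the age-bin and tertile classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .months import month_index_array, month_str

SEXES = ("F", "M")
RACES = ("White", "Black", "Asian", "Hispanic", "Other")
MIN_AGE_YEARS = 65
OPEN_AGE_BIN = 90  # ages >= 90 share one stratum

COHORT_COLUMNS = [
    "id",
    "birth_month",
    "sex",
    "race",
    "follow_up_start",
    "follow_up_end",
    "death_month",
    "icd10_cause",
]


class CohortValidationError(ValueError):
    pass


def age_years(birth_month, at_month):
    """Attained age in whole years at a given month (floor)."""
    return (np.asarray(at_month) - np.asarray(birth_month)) // 12


def age_category(birth_month, at_month):
    """One-year attained-age bin, with everything >= 90 pooled into ``"90+"``.

    Works on scalars or arrays; raises for out-of-cohort ages (< 65).
    """
    yrs = age_years(birth_month, at_month)
    if np.any(yrs < MIN_AGE_YEARS):
        raise CohortValidationError("age below 65 is outside the cohort")
    yrs = np.minimum(yrs, OPEN_AGE_BIN)
    labels = np.where(yrs >= OPEN_AGE_BIN, "90+", yrs.astype(str))
    return labels if labels.ndim else labels.item()


def age_bin_code(birth_month, at_month):
    """Integer age-bin code (65..90, where 90 encodes the 90+ bin)."""
    yrs = age_years(birth_month, at_month)
    return np.minimum(yrs, OPEN_AGE_BIN)


def classify_ses_tertiles(zip_incomes: pd.Series) -> pd.Series:
    """Cut one year's per-ZIP incomes at the empirical 1/3 and 2/3 quantiles.

    Boundary values fall in the lower tertile, so labels are deterministic
    and invariant to ZIP ordering. Raises on a degenerate (constant) income
    distribution, where tertiles are undefined.
    """
    s = pd.Series(zip_incomes).astype(float)
    if s.notna().sum() < 3:
        raise CohortValidationError("need >= 3 ZIP incomes to form tertiles")
    if s.nunique() == 1:
        raise CohortValidationError("degenerate income distribution: all equal")
    lo, hi = s.quantile([1 / 3, 2 / 3])
    labels = pd.Series(
        np.where(s <= lo, "low", np.where(s <= hi, "medium", "high")),
        index=s.index,
    )
    labels[s.isna()] = np.nan
    return labels


def impute_missing_income_years(
    incomes: dict[int, float],
    fill_map: dict[int, int] = {2000: 2001, 2003: 2004},
) -> dict[int, float]:
    """Carry donor-year income into known missing years (2000<-2001, 2003<-2004)."""
    out = dict(incomes)
    for missing, donor in fill_map.items():
        if missing not in out or pd.isna(out.get(missing)):
            if donor not in out or pd.isna(out.get(donor)):
                raise CohortValidationError(
                    f"cannot impute income for {missing}: donor year {donor} absent"
                )
            out[missing] = out[donor]
    return out


@dataclass
class ZipAttributes:
    """Per-ZIP static attributes plus annual income."""

    table: pd.DataFrame  # columns: zip, urban (bool), lat, lon
    income: pd.DataFrame  # columns: zip, year, income

    def income_year(self, year: int) -> pd.Series:
        sub = self.income[self.income["year"] == year]
        return sub.set_index("zip")["income"]

    def ses_levels(self, year: int) -> pd.Series:
        """Per-ZIP low/medium/high label for one calendar year."""
        return classify_ses_tertiles(self.income_year(year))


def validate_cohort(cohort: pd.DataFrame, residence: pd.DataFrame) -> list[str]:
    """Structural checks; returns a list of human-readable error strings."""
    errors: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        return [f"cohort table missing columns: {missing}"]
    if cohort["id"].duplicated().any():
        dup = cohort.loc[cohort["id"].duplicated(), "id"].iloc[0]
        errors.append(f"duplicate beneficiary id {dup!r}")

    bad = cohort["follow_up_start"] > cohort["follow_up_end"]
    for bid in cohort.loc[bad, "id"]:
        errors.append(f"beneficiary {bid!r}: follow-up start after end")

    died = cohort["death_month"].notna()
    mism = died & (cohort["death_month"] != cohort["follow_up_end"])
    for bid in cohort.loc[mism, "id"]:
        errors.append(f"beneficiary {bid!r}: death month != follow-up end")
    pre = died & (cohort["death_month"] < cohort["follow_up_start"])
    for bid in cohort.loc[pre, "id"]:
        errors.append(f"beneficiary {bid!r}: death before entry")

    under = age_years(cohort["birth_month"], cohort["follow_up_start"]) < MIN_AGE_YEARS
    for bid in cohort.loc[under, "id"]:
        errors.append(f"beneficiary {bid!r}: younger than 65 at entry")

    res = residence.sort_values(["id", "start_month"])
    if res.duplicated(["id", "start_month"]).any():
        bid = res.loc[res.duplicated(["id", "start_month"]), "id"].iloc[0]
        errors.append(f"beneficiary {bid!r}: overlapping residence segments")
    first = res.groupby("id")["start_month"].min()
    joined = cohort.set_index("id")["follow_up_start"]
    uncovered = first.reindex(joined.index)
    gap = uncovered.isna() | (uncovered > joined)
    for bid in joined.index[gap]:
        errors.append(f"beneficiary {bid!r}: residence history does not cover entry")
    return errors


def zip_at_month(residence: pd.DataFrame, ids: pd.Index) -> pd.DataFrame:
    """Wide helper used by the engine: residence sorted per id for interval lookup."""
    return residence.sort_values(["id", "start_month"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# delimited-text I/O (months serialised as YYYY-MM)

_MONTH_COLS = ["birth_month", "follow_up_start", "follow_up_end", "death_month"]


def read_cohort_csv(cohort_path, residence_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    cohort = pd.read_csv(cohort_path, dtype={"icd10_cause": "string"})
    for col in _MONTH_COLS:
        vals = cohort[col]
        present = vals.notna()
        out = np.full(len(vals), np.nan)
        if present.any():
            out[present.to_numpy()] = month_index_array(vals[present])
        cohort[col] = out if col == "death_month" else out.astype(int)
    residence = pd.read_csv(residence_path)
    residence["start_month"] = month_index_array(residence["start_month"].astype(str))
    return cohort, residence


def write_cohort_csv(cohort: pd.DataFrame, residence: pd.DataFrame, cohort_path, residence_path):
    out = cohort.copy()
    for col in _MONTH_COLS:
        out[col] = [month_str(v) if pd.notna(v) else "" for v in out[col]]
    out.to_csv(cohort_path, index=False)
    res = residence.copy()
    res["start_month"] = [month_str(v) for v in res["start_month"]]
    res.to_csv(residence_path, index=False)
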