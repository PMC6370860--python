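"""ICD-9 -> phecode case/control phenotyping.

Implements the standard phecode semantics: a person is a *case* for a
phecode with component ICD-9 codes on at least two distinct dates, is
*excluded* with exactly one instance, is *excluded* as a control if any
of their codes map to a different phecode inside the phecode's exclusion
range, and is a *control* otherwise.  Status codes in the assignment
matrix: 1 = case, 0 = control, -1 = excluded (single instance),
-2 = excluded (related code in exclusion range).
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import DAYS_PER_YEAR, EPOCH_YEAR

logger = logging.getLogger(__name__)

CASE = 1
CONTROL = 0
EXCLUDED_SINGLE_INSTANCE = -1
EXCLUDED_RELATED_CODE = -2


def _normalise_dates(dates: pd.Series) -> pd.Series:
    """Coerce event dates to comparable keys (integer day offsets pass
    through; strings are parsed as calendar dates and raise if malformed)."""
    if pd.api.types.is_numeric_dtype(dates):
        return dates
    return pd.to_datetime(dates, errors="raise")


def validate_phecode_map(pmap: pd.DataFrame) -> pd.DataFrame:
    if pmap.empty:
        raise ValueError("phecode map is empty")
    if pmap["icd9"].duplicated().any():
        dups = pmap.loc[pmap["icd9"].duplicated(), "icd9"].tolist()
        raise ValueError(f"duplicate ICD-9 rows in phecode map: {dups}")
    bad = pmap[(pmap["exclusion_low"] > pmap["phecode"]) | (pmap["phecode"] > pmap["exclusion_high"])]
    if len(bad):
        raise ValueError(f"phecodes outside their exclusion range: {bad['phecode'].tolist()}")
    return pmap


def map_icd_to_phecodes(events: pd.DataFrame, pmap: pd.DataFrame) -> pd.DataFrame:
    """Count distinct event dates per person per phecode.

    ICD-9 codes absent from the map are dropped (with a logged count).
    Returns a person x phecode matrix of distinct-date counts covering
    every phecode in the map; persons with no mapped events do not appear
    (callers reindex against the cohort).
    """
    validate_phecode_map(pmap)
    ev = events.copy()
    ev["date"] = _normalise_dates(ev["date"])
    merged = ev.merge(pmap[["icd9", "phecode"]], left_on="code", right_on="icd9", how="left")
    n_unmapped = int(merged["phecode"].isna().sum())
    if n_unmapped:
        logger.info("dropped %d events with ICD-9 codes absent from the phecode map", n_unmapped)
    merged = merged.dropna(subset=["phecode"])
    distinct = merged.drop_duplicates(subset=["person", "phecode", "date"])
    counts = (
        distinct.groupby(["person", "phecode"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=sorted(pmap["phecode"].unique()), fill_value=0)
    )
    counts.columns.name = "phecode"
    return counts


def assign_case_control(
    counts: pd.DataFrame,
    pmap: pd.DataFrame,
    cohort: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Assign case/control/excluded status for every phecode in the map.

    ``counts`` is the distinct-date count matrix from
    :func:`map_icd_to_phecodes`.  Precedence per phecode: count >= 2 is a
    case (even if other codes fall in the exclusion range); count == 1 is
    excluded as a single instance; count == 0 with any code mapping to a
    phecode inside the exclusion range is excluded as a related code;
    everyone else is a control.
    """
    validate_phecode_map(pmap)
    phecodes = sorted(pmap["phecode"].unique())
    missing = [p for p in counts.columns if p not in set(phecodes)]
    if missing:
        raise KeyError(f"count matrix has phecodes absent from the map: {missing}")
    if cohort is None:
        cohort = counts.index
    C = counts.reindex(index=cohort, columns=phecodes, fill_value=0).to_numpy()
    ranges = (
        pmap[["phecode", "exclusion_low", "exclusion_high"]]
        .drop_duplicates("phecode")
        .set_index("phecode")
        .loc[phecodes]
    )
    codes = np.asarray(phecodes, dtype=float)
    out = np.zeros_like(C, dtype=np.int8)
    for j, ph in enumerate(phecodes):
        lo, hi = ranges.loc[ph, "exclusion_low"], ranges.loc[ph, "exclusion_high"]
        in_range = (codes >= lo) & (codes <= hi) & (codes != ph)
        related_any = C[:, in_range].sum(axis=1) > 0 if in_range.any() else np.zeros(len(C), bool)
        col = C[:, j]
        out[:, j] = np.where(
            col >= 2,
            CASE,
            np.where(col == 1, EXCLUDED_SINGLE_INSTANCE,
                     np.where(related_any, EXCLUDED_RELATED_CODE, CONTROL)),
        )
    assignments = pd.DataFrame(out, index=cohort, columns=phecodes)
    assignments.columns.name = "phecode"
    assignments.index.name = "person"
    return assignments


def person_ages(events: pd.DataFrame, demographics: pd.DataFrame) -> pd.Series:
    """Age in years at each person's last recorded event.

    Event dates are integer day offsets from the epoch year; persons with
    no events are aged at the cohort's overall last event day.
    """
    if len(events):
        dates = _normalise_dates(events["date"])
        if not pd.api.types.is_numeric_dtype(dates):
            dates = (dates - pd.Timestamp(f"{EPOCH_YEAR}-01-01")).dt.days
        last = pd.Series(dates.to_numpy(), index=events["person"].to_numpy()).groupby(level=0).max()
        ref_day = float(dates.max())
    else:
        last = pd.Series(dtype=float)
        ref_day = 0.0
    last = last.reindex(demographics.index).fillna(ref_day)
    event_year = EPOCH_YEAR + last // DAYS_PER_YEAR
    return (event_year - demographics["birth_year"]).rename("age")


def median_event_ages(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    per_phecode: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Median age at which a person's ICD-9 codes were recorded.

    This is the age covariate for the scan: by default the median is over
    ALL of a person's events (one covariate per person).  Persons with no
    events fall back to their age at the cohort's last event day.
    """
    if len(events):
        dates = _normalise_dates(events["date"])
        if not pd.api.types.is_numeric_dtype(dates):
            dates = (dates - pd.Timestamp(f"{EPOCH_YEAR}-01-01")).dt.days
        med = pd.Series(dates.to_numpy(), index=events["person"].to_numpy()).groupby(level=0).median()
        ref_day = float(dates.max())
    else:
        med = pd.Series(dtype=float)
        ref_day = 0.0
    med = med.reindex(demographics.index).fillna(ref_day)
    event_year = EPOCH_YEAR + med / DAYS_PER_YEAR
    return (event_year - demographics["birth_year"]).rename("median_event_age")


def filter_adults(
    assignments: pd.DataFrame,
    demographics: pd.DataFrame,
    events: pd.DataFrame,
    min_age: int = 18,
) -> pd.DataFrame:
    """Restrict assignments to adults (age strictly greater than ``min_age``).

    Persons with a missing birth year are dropped with a warning.
    """
    demo = demographics.reindex(assignments.index)
    missing = demo["birth_year"].isna()
    if missing.any():
        logger.warning("dropping %d persons with missing birth year", int(missing.sum()))
    ages = person_ages(events, demo)
    keep = (~missing) & (ages > min_age)
    return assignments.loc[keep[keep].index]


def filter_phecodes(
    assignments: pd.DataFrame, min_cases: int = 200
) -> Tuple[list, pd.DataFrame]:
    """Keep phecodes with at least ``min_cases`` cases.

    Returns ``(kept_phecodes, counts)`` where ``counts`` has one row per
    phecode with its case and control totals.
    """
    n_case = (assignments == CASE).sum(axis=0)
    n_control = (assignments == CONTROL).sum(axis=0)
    counts = pd.DataFrame({"n_case": n_case, "n_control": n_control})
    counts.index.name = "phecode"
    kept = counts.index[counts["n_case"] >= min_cases].tolist()
    return kept, counts
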