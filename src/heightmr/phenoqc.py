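"""Cleaning of longitudinal height/weight records and phecode case/control assignment.

Height and weight arrive as raw EHR vitals (inches and pounds, many visits per
person); diagnoses arrive as long-format ICD-9/ICD-10 events.  This module
reduces them to one cleaned height (cm) and BMI per person and to a
person x phecode case/control/missing matrix.

Cleaning rules
--------------
Height: average all of a person's measurements (inches), drop any measurement
deviating strictly more than 3 inches from that provisional mean, recompute the
mean once, exclude the person entirely if the final mean is <= 50 or >= 100
inches, and convert to cm.  The outlier pass runs exactly once (no iteration to
a fixed point).

Weight/BMI: restrict to weights within 1.5 years of enrollment, drop weights
deviating strictly more than 60 lb from the person's in-window mean (single
pass), then BMI = mean weight (kg) / height (m)^2.

Phecodes: an ICD event maps to a phecode by exact (vocabulary, code) lookup.
A person is a case for a phecode with >= `min_code_count` mapped events
(default 2), a control with zero, and missing in between (the "one-code"
convention: a single code is treated as diagnostically ambiguous).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

IN_TO_CM = 2.54
LB_TO_KG = 0.45359237

HEIGHT_MAX_DEV_IN = 3.0
HEIGHT_MIN_MEAN_IN = 50.0
HEIGHT_MAX_MEAN_IN = 100.0

WEIGHT_MAX_DEV_LB = 60.0
BMI_WINDOW_DAYS = 1.5 * 365.25


def clean_height(values_in) -> tuple[float | None, str]:
    """Clean one person's height series (inches) -> (height_cm, reason).

    Returns ``(cm, "ok")`` or ``(None, reason)`` when the person is excluded.
    """
    vals = np.asarray(list(values_in), dtype=float)
    if vals.size == 0:
        return None, "no_measurements"
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ValueError("height measurements must be finite and positive")
    provisional = vals.mean()
    kept = vals[np.abs(vals - provisional) <= HEIGHT_MAX_DEV_IN]
    if kept.size == 0:
        return None, "all_measurements_outlying"
    final = kept.mean()
    if final <= HEIGHT_MIN_MEAN_IN or final >= HEIGHT_MAX_MEAN_IN:
        return None, "extreme_mean_height"
    return final * IN_TO_CM, "ok"


def clean_heights(measurements: pd.DataFrame, *, person_col: str = "person_id",
                  value_col: str = "value") -> tuple[pd.Series, pd.DataFrame]:
    """Vectorised :func:`clean_height` over a long measurement table.

    Returns (heights_cm indexed by person, exclusions table with reasons).
    """
    heights: dict = {}
    excluded: list[tuple] = []
    for pid, grp in measurements.groupby(person_col, sort=True):
        cm, reason = clean_height(grp[value_col].to_numpy())
        if cm is None:
            excluded.append((pid, reason))
        else:
            heights[pid] = cm
    return (
        pd.Series(heights, name="height_cm", dtype=float),
        pd.DataFrame(excluded, columns=[person_col, "reason"]),
    )


def clean_bmi(weights_lb, dates, height_cm: float, enrollment_date) -> float:
    """One person's BMI from in-window weights (lb) and cleaned height (cm).

    Weights outside +/-1.5 years of enrollment are ignored; in-window weights
    deviating strictly > 60 lb from the in-window mean are dropped (single
    pass).  Returns NaN when no usable weight remains.
    """
    vals = np.asarray(list(weights_lb), dtype=float)
    dts = pd.to_datetime(pd.Series(list(dates)))
    if vals.size != dts.size:
        raise ValueError("weights and dates must align")
    if vals.size and (np.any(vals <= 0) or not np.all(np.isfinite(vals))):
        raise ValueError("weight measurements must be finite and positive")
    enroll = pd.Timestamp(enrollment_date)
    delta = (dts - enroll).dt.total_seconds().to_numpy() / 86400.0
    in_window = vals[np.abs(delta) <= BMI_WINDOW_DAYS]
    if in_window.size == 0:
        return float("nan")
    kept = in_window[np.abs(in_window - in_window.mean()) <= WEIGHT_MAX_DEV_LB]
    if kept.size == 0:
        return float("nan")
    mean_kg = kept.mean() * LB_TO_KG
    h_m = height_cm / 100.0
    return float(mean_kg / h_m**2)


def clean_bmis(weight_measurements: pd.DataFrame, heights_cm: pd.Series,
               enrollment: pd.Series, *, person_col: str = "person_id",
               date_col: str = "date", value_col: str = "value") -> pd.Series:
    """BMI per person; persons without a cleaned height or usable weights get NaN."""
    out = pd.Series(np.nan, index=heights_cm.index, name="bmi", dtype=float)
    for pid, grp in weight_measurements.groupby(person_col, sort=True):
        if pid not in heights_cm.index or pid not in enrollment.index:
            continue
        out.loc[pid] = clean_bmi(
            grp[value_col].to_numpy(), grp[date_col], heights_cm.loc[pid],
            enrollment.loc[pid],
        )
    return out


@dataclass
class PhecodeMatrix:
    """Person x phecode status matrix: 1.0 = case, 0.0 = control, NaN = missing."""

    status: pd.DataFrame
    unmapped_codes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["vocabulary", "code"])
    )

    @property
    def phecodes(self) -> list[str]:
        return list(self.status.columns)

    @property
    def n_case(self) -> pd.Series:
        return (self.status == 1.0).sum(axis=0)

    @property
    def n_control(self) -> pd.Series:
        return (self.status == 0.0).sum(axis=0)

    @property
    def n_missing(self) -> pd.Series:
        return self.status.isna().sum(axis=0)

    def counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_case": self.n_case, "n_control": self.n_control,
             "n_missing": self.n_missing}
        )


def assign_phecodes(icd_events: pd.DataFrame, phecode_map: pd.DataFrame,
                    persons, *, min_code_count: int = 2,
                    exclusion_map: dict | None = None) -> PhecodeMatrix:
    """Build the phecode case/control matrix from long-format ICD events.

    Parameters
    ----------
    icd_events
        Columns person_id, date, vocabulary (ICD9/ICD10), code.
    phecode_map
        Columns vocabulary, code, phecode (exact-string mapping; no hierarchy
        expansion).
    persons
        Full person universe; persons with zero mapped events are controls for
        every phecode.
    exclusion_map
        Optional hook: {phecode: [related phecodes]} — controls carrying any
        code of a related phecode are set to missing for that phecode.  The
        default applies no exclusion ranges.
    """
    persons = pd.Index(persons, name="person_id")
    required = {"person_id", "vocabulary", "code"}
    if not required.issubset(icd_events.columns):
        raise ValueError(f"ICD events need columns {sorted(required)}")

    events = icd_events.copy()
    dedup_keys = [c for c in ("person_id", "date", "vocabulary", "code")
                  if c in events.columns]
    n_before = len(events)
    events = events.drop_duplicates(subset=dedup_keys)
    if len(events) < n_before:
        warnings.warn(
            f"dropped {n_before - len(events)} duplicate (person, date, code) events",
            stacklevel=2,
        )

    pmap = phecode_map.astype({"phecode": str})
    merged = events.merge(pmap, on=["vocabulary", "code"], how="left")
    unmapped = (
        merged.loc[merged["phecode"].isna(), ["vocabulary", "code"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    mapped = merged.dropna(subset=["phecode"])

    all_phecodes = sorted(pmap["phecode"].unique())
    counts = (
        mapped.groupby(["person_id", "phecode"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=persons, columns=all_phecodes, fill_value=0)
    )
    status = pd.DataFrame(
        np.where(counts.to_numpy() >= min_code_count, 1.0,
                 np.where(counts.to_numpy() == 0, 0.0, np.nan)),
        index=counts.index, columns=counts.columns,
    )
    status.columns = [str(c) for c in status.columns]

    if exclusion_map:
        counts.columns = [str(c) for c in counts.columns]
        for phe, related in exclusion_map.items():
            phe = str(phe)
            if phe not in status.columns:
                continue
            related_present = [str(r) for r in related if str(r) in counts.columns]
            if not related_present:
                continue
            hit = (counts[related_present] > 0).any(axis=1)
            mask = hit & (status[phe] == 0.0)
            status.loc[mask, phe] = np.nan

    return PhecodeMatrix(status=status, unmapped_codes=unmapped)


def filter_phecodes(matrix: PhecodeMatrix, min_cases: int = 200,
                    min_controls: int = 200) -> PhecodeMatrix:
    """Retain phecodes with >= min_cases cases AND >= min_controls controls.

    The thresholds are inclusive; an empty result is permitted (downstream
    sweeps then no-op with a warning).
    """
    keep = (matrix.n_case >= min_cases) & (matrix.n_control >= min_controls)
    kept = matrix.status.loc[:, keep[keep].index]
    if kept.shape[1] == 0:
        warnings.warn("no phecode passes the case/control filter", stacklevel=2)
    return PhecodeMatrix(status=kept, unmapped_codes=matrix.unmapped_codes)
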