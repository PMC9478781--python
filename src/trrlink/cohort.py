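"""Waitlist cohort construction.

Canonicalizes facility identifiers through the many-to-one alias
crosswalk, drops entries at centers absent from the active-center table,
then applies the inclusion rules in a fixed, logged order:

1. drop entries whose start date is missing or later than the recorded
   end date;
2. administratively censor open entries (missing end date) at the last
   day of the study period;
3. trim each interval to the adult portion inside the study period —
   start to max(start, 18th birthday, study start), end to
   min(end, study end);
4. drop entries whose trimmed interval is empty.

"At least one day on the waitlist during the study period" is read with
inclusive endpoints: a one-day interval (trimmed start == trimmed end)
is retained. The under-18 rule trims rather than excludes, because only
the portion of the listing at age >= 18 counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd


class DataError(ValueError):
    """Raised for contradictory or unparseable input rows."""


@dataclass(frozen=True)
class StudyPeriod:
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("study period start must precede end")


def _parse_date(value, column: str, row_label) -> date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    try:
        return date.fromisoformat(s)
    except ValueError as exc:
        raise DataError(f"row {row_label}: unparseable {column} {value!r}") from exc


def eighteenth_birthday(birth: date) -> date:
    """Date a person born on ``birth`` turns 18 (Feb 29 -> Mar 1)."""
    try:
        return birth.replace(year=birth.year + 18)
    except ValueError:
        return date(birth.year + 18, 3, 1)


def canonicalize_facilities(
    entries: pd.DataFrame,
    facility_xwalk: pd.DataFrame,
    active_centers: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Replace alias facility ids with canonical center ids.

    Ids absent from the crosswalk are taken to be already canonical.
    Entries whose canonical id is not in the active-center table are
    dropped and tallied (these mirror listings at centers that never
    performed a transplant or are no longer active).
    """
    xw = facility_xwalk.astype(str)
    dup = xw.groupby("alias_id")["canonical_id"].nunique()
    bad = dup[dup > 1]
    if len(bad):
        raise DataError(
            f"alias ids map to multiple canonical ids: {sorted(bad.index)}"
        )
    mapping = dict(zip(xw["alias_id"], xw["canonical_id"]))
    out = entries.copy()
    out["center_id"] = out["facility_id"].astype(str).map(
        lambda f: mapping.get(f, f)
    )
    active = set(active_centers["id"].astype(str))
    keep = out["center_id"].isin(active)
    dropped = out[~keep]
    log = {
        "facility_dropped_entries": int((~keep).sum()),
        "facility_dropped_centers": int(dropped["center_id"].nunique()),
    }
    return out[keep].reset_index(drop=True), log


def filter_waitlist(
    entries: pd.DataFrame, period: StudyPeriod
) -> tuple[pd.DataFrame, dict]:
    """Apply the inclusion rules; return the cohort and an exclusion tally.

    The cohort gains ``eff_start``/``eff_end`` columns: the adult portion
    of each listing inside the study period. The tally reports, per rule,
    how many entries were excluded, plus how many open entries were
    administratively censored.
    """
    tally = {
        "input": int(len(entries)),
        "bad_start_date": 0,
        "censored_to_study_end": 0,
        "no_days_in_period": 0,
        "included": 0,
    }
    kept_idx: list = []
    eff_start: list[date] = []
    eff_end: list[date] = []
    for label, row in entries.iterrows():
        start = _parse_date(row["start_date"], "start_date", label)
        end = _parse_date(row["end_date"], "end_date", label)
        birth = _parse_date(row["birth_date"], "birth_date", label)
        if birth is None:
            raise DataError(f"row {label}: missing birth_date")
        if start is None or (end is not None and start > end):
            tally["bad_start_date"] += 1
            continue
        if end is None:
            end = period.end
            tally["censored_to_study_end"] += 1
        s = max(start, eighteenth_birthday(birth), period.start)
        e = min(end, period.end)
        if s > e:
            tally["no_days_in_period"] += 1
            continue
        kept_idx.append(label)
        eff_start.append(s)
        eff_end.append(e)
    cohort = entries.loc[kept_idx].copy()
    cohort["eff_start"] = [d.isoformat() for d in eff_start]
    cohort["eff_end"] = [d.isoformat() for d in eff_end]
    tally["included"] = int(len(cohort))
    return cohort.reset_index(drop=True), tally


def build_cohort(
    entries: pd.DataFrame,
    facility_xwalk: pd.DataFrame,
    active_centers: pd.DataFrame,
    period: StudyPeriod,
) -> tuple[pd.DataFrame, dict]:
    """Canonicalize then filter; the combined tally conserves counts:
    included + per-rule exclusions + facility drops == input."""
    canon, flog = canonicalize_facilities(entries, facility_xwalk, active_centers)
    cohort, tally = filter_waitlist(canon, period)
    tally["input"] = int(len(entries))
    tally.update(flog)
    return cohort, tally
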