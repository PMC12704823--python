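"""Minute-epoch classification, day validity and person-level compositions.

Wake wear minutes are labelled by vector-magnitude counts/min using the
half-open bands [0, 2000) = SB, [2000, 7500) = LPA, [7500, inf) = MVPA; a
sleep flag takes precedence over the bands (the sleep period is defined
upstream by the device-processing guider and its minutes are not
re-classified by counts). Days with >= 16 h of wear are valid; participants
need >= 4 valid days. Valid days are averaged arithmetically per behavior,
person-level zero minutes are replaced by a configurable pseudo-minute
(default 0.5 min) so log-ratios exist, and the mean is closed to 1440 min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coda import BEHAVIORS, MINUTES_PER_DAY, closure

SB_UPPER = 2000.0    # counts/min; below is sedentary
MVPA_LOWER = 7500.0  # counts/min; at or above is MVPA
MIN_WEAR_HOURS = 16.0
MIN_VALID_DAYS = 4


@dataclass(frozen=True)
class DayRecord:
    """Behavior minutes and wear time for one calendar day."""
    date: object
    sleep_min: float
    sb_min: float
    lpa_min: float
    mvpa_min: float
    wear_hours: float

    @property
    def minutes(self) -> np.ndarray:
        return np.array([self.sleep_min, self.sb_min, self.lpa_min,
                         self.mvpa_min])


@dataclass(frozen=True)
class ParticipantTimeUse:
    """Person-level mean daily composition over valid days."""
    participant_id: str
    n_valid_days: int
    mean_minutes: np.ndarray  # closed to 1440 when valid
    valid: bool


def classify_epoch(counts: float, wear: bool = True,
                   sleep: bool = False) -> str:
    """Label one worn minute as sleep / sb / lpa / mvpa."""
    if not wear:
        raise ValueError("non-wear minutes are not classified")
    if counts < 0:
        raise ValueError("counts must be non-negative")
    if sleep:
        return "sleep"
    if counts < SB_UPPER:
        return "sb"
    if counts < MVPA_LOWER:
        return "lpa"
    return "mvpa"


def classify_counts(counts) -> np.ndarray:
    """Vectorised wake-minute labelling by count bands."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    return np.select([c < SB_UPPER, c < MVPA_LOWER], ["sb", "lpa"], "mvpa")


def summarize_day(epochs: pd.DataFrame) -> DayRecord:
    """Tally worn minutes per behavior for one calendar day.

    ``epochs`` needs columns ``timestamp, counts, wear, sleep``; all rows
    must fall on one date with unique timestamps (at most 1440). Non-wear
    minutes are excluded from the behavior totals, so the totals plus
    non-wear minutes conserve the epoch count.
    """
    ts = pd.to_datetime(epochs["timestamp"])
    dates = ts.dt.date.unique()
    if len(dates) != 1:
        raise ValueError(f"epochs span {len(dates)} calendar days; expected 1")
    if ts.duplicated().any():
        raise ValueError("duplicate timestamps in day")
    if len(epochs) > 1440:
        raise ValueError("more than 1440 epochs in one day")

    worn = epochs[epochs["wear"].astype(bool)]
    labels = np.where(worn["sleep"].astype(bool), "sleep",
                      classify_counts(worn["counts"]))
    tally = pd.Series(labels).value_counts()
    return DayRecord(
        date=dates[0],
        sleep_min=float(tally.get("sleep", 0)),
        sb_min=float(tally.get("sb", 0)),
        lpa_min=float(tally.get("lpa", 0)),
        mvpa_min=float(tally.get("mvpa", 0)),
        wear_hours=len(worn) / 60.0,
    )


def filter_valid_days(days, min_wear_hours: float = MIN_WEAR_HOURS,
                      min_valid_days: int = MIN_VALID_DAYS):
    """Keep days with enough wear; flag whether the participant qualifies.

    Returns ``(valid_days, participant_valid)`` where a day is valid iff
    ``wear_hours >= min_wear_hours`` and the participant is valid iff at
    least ``min_valid_days`` days survive.
    """
    valid = [d for d in days if d.wear_hours >= min_wear_hours]
    return valid, len(valid) >= min_valid_days


def average_composition(valid_days, participant_id: str = "",
                        kappa: float = MINUTES_PER_DAY,
                        zero_replacement: float = 0.5) -> ParticipantTimeUse:
    """Average valid days into one composition closed to ``kappa``.

    Arithmetic mean of daily minutes per behavior; any behavior whose mean
    is exactly zero is replaced by ``zero_replacement`` minutes before
    closure (log-ratios need strictly positive parts). Non-wear time makes
    day totals fall short of 1440, so closure proportionally rescales.
    """
    if len(valid_days) == 0:
        raise ValueError("no valid days to average")
    mean = np.mean([d.minutes for d in valid_days], axis=0)
    mean = np.where(mean == 0.0, zero_replacement, mean)
    if np.any(mean <= 0):
        raise ValueError(
            "a behavior mean is non-positive after zero replacement; "
            "set a positive zero_replacement")
    return ParticipantTimeUse(
        participant_id=participant_id,
        n_valid_days=len(valid_days),
        mean_minutes=closure(mean, kappa),
        valid=len(valid_days) >= MIN_VALID_DAYS,
    )


def process_epochs(epochs: pd.DataFrame,
                   min_wear_hours: float = MIN_WEAR_HOURS,
                   min_valid_days: int = MIN_VALID_DAYS,
                   zero_replacement: float = 0.5):
    """Epoch table -> per-participant compositions plus an exclusion log.

    ``epochs`` holds one row per minute for any number of participants
    (columns ``participant_id, timestamp, counts, wear, sleep``). Returns
    ``(participants, exclusions)``: a DataFrame with one row per valid
    participant (``participant_id, n_valid_days, sleep_min .. mvpa_min``)
    and a list of human-readable exclusion reasons.
    """
    rows, exclusions = [], []
    ts = pd.to_datetime(epochs["timestamp"])
    for pid, part in epochs.groupby("participant_id", sort=True):
        days = [summarize_day(day_df)
                for _, day_df in part.groupby(ts.loc[part.index].dt.date)]
        valid, ok = filter_valid_days(days, min_wear_hours, min_valid_days)
        if not ok:
            exclusions.append(
                f"{pid}: excluded ({len(valid)} valid days of {len(days)}; "
                f"need >= {min_valid_days} with >= {min_wear_hours:g} h wear)")
            continue
        p = average_composition(valid, participant_id=str(pid),
                                zero_replacement=zero_replacement)
        rows.append({"participant_id": str(pid),
                     "n_valid_days": p.n_valid_days,
                     **{f"{b}_min": m for b, m in
                        zip(BEHAVIORS, p.mean_minutes)}})
    return pd.DataFrame(rows), exclusions
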