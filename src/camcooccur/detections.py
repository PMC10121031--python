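"""Detection histories from raw camera-trap records.

A camera-trap study produces a table of photo events (station, species,
timestamp).  Before any occupancy modelling these events are reduced to
*independent records* (consecutive photos of the same species at the same
station are collapsed unless separated by more than an independence window,
conventionally 60 minutes) and then binned into a site x occasion detection
history.  Multi-year studies are *stacked*: each station x survey-block
combination becomes an independent site row, with a survey block (default
120 days) divided into equal occasions (default 10 occasions of 12 days).

The occasion-level *effort* (number of days the camera was active) is kept
alongside the binary history; occasions with zero effort are recorded as
missing rather than as non-detections.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("station_id", "species", "timestamp")
DEPLOYMENT_COLUMNS = ("station_id", "start", "end")


class RecordValidationError(ValueError):
    """Raised when a record table fails validation; carries row indices."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check and normalise a raw record table.

    Returns a copy with ``timestamp`` parsed to datetime64 and rows sorted by
    (station, species, time).  Unparseable timestamps or missing species
    labels raise :class:`RecordValidationError` naming the offending rows.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise RecordValidationError(f"record table lacks columns: {missing}")
    out = records.loc[:, list(RECORD_COLUMNS)].copy()
    ts = pd.to_datetime(out["timestamp"], errors="coerce")
    bad = out.index[ts.isna()].tolist()
    if bad:
        raise RecordValidationError(f"unparseable timestamps at rows {bad}", bad)
    out["timestamp"] = ts
    bad = out.index[out["species"].isna()].tolist()
    if bad:
        raise RecordValidationError(f"missing species labels at rows {bad}", bad)
    return out.sort_values(["station_id", "species", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )


def filter_independent_records(
    records: pd.DataFrame,
    window_minutes: float = 60.0,
    deployments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Collapse photo bursts into independent records.

    Within each (station, species) stream a record is kept iff it is the
    first, or falls strictly more than ``window_minutes`` after the last
    *kept* record (rolling-window collapse, the camtrapR convention for
    unmarked individuals).  The operation is idempotent.

    If ``deployments`` is given, stations absent from it are rejected.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be > 0")
    rec = validate_records(records)
    if deployments is not None:
        known = set(deployments["station_id"])
        unknown = sorted(set(rec["station_id"]) - known)
        if unknown:
            raise RecordValidationError(f"stations not in deployment table: {unknown}")
    window = pd.Timedelta(minutes=window_minutes)
    keep = np.zeros(len(rec), dtype=bool)
    for _, idx in rec.groupby(["station_id", "species"], sort=False).groups.items():
        last_kept = None
        for i in idx:
            t = rec.at[i, "timestamp"]
            if last_kept is None or (t - last_kept) > window:
                keep[rec.index.get_loc(i)] = True
                last_kept = t
    return rec.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class SurveyDesign:
    """Stacked survey layout: 120-day blocks of 10 x 12-day occasions."""

    study_start: _dt.date
    survey_days: int = 120
    n_occasions: int = 10
    occasion_days: int = 12

    def __post_init__(self):
        if self.n_occasions * self.occasion_days != self.survey_days:
            raise ValueError(
                "occasions_per_survey x occasion_length must equal survey_block_length "
                f"({self.n_occasions} x {self.occasion_days} != {self.survey_days})"
            )
        if isinstance(self.study_start, str):
            object.__setattr__(self, "study_start", _dt.date.fromisoformat(self.study_start))

    def day_offset(self, when) -> int:
        """Whole days elapsed since the study start (0 for the first day)."""
        d = when.date() if hasattr(when, "date") and not isinstance(when, _dt.date) else when
        if isinstance(d, _dt.datetime):
            d = d.date()
        return (d - self.study_start).days

    def locate(self, when) -> tuple[int, int]:
        """Map a date to 1-based (survey, occasion) indices."""
        off = self.day_offset(when)
        if off < 0:
            raise ValueError(f"{when} precedes the study start")
        survey = off // self.survey_days + 1
        day_in_survey = off % self.survey_days + 1  # 1-based
        occasion = (day_in_survey - 1) // self.occasion_days + 1
        return survey, occasion

    def n_surveys(self, study_end: _dt.date) -> int:
        """Number of (possibly partial) survey blocks up to ``study_end``."""
        span = (study_end - self.study_start).days + 1
        return max(1, math.ceil(span / self.survey_days))

    def occasion_window(self, survey: int, occasion: int) -> tuple[_dt.date, _dt.date]:
        """Inclusive first/last dates of a 1-based (survey, occasion) cell."""
        start_off = (survey - 1) * self.survey_days + (occasion - 1) * self.occasion_days
        start = self.study_start + _dt.timedelta(days=start_off)
        end = start + _dt.timedelta(days=self.occasion_days - 1)
        return start, end


def assign_occasions(records: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Annotate each record with 1-based (survey, occasion) indices.

    Records preceding the study start are dropped with a warning stating the
    count; there is no upper bound because trailing partial blocks are kept.
    """
    rec = validate_records(records)
    offs = np.array([design.day_offset(t) for t in rec["timestamp"]])
    bad = offs < 0
    if bad.any():
        warnings.warn(f"dropped {int(bad.sum())} records before the study start")
        rec = rec.loc[~bad].reset_index(drop=True)
        offs = offs[~bad]
    rec["survey"] = offs // design.survey_days + 1
    day_in_survey = offs % design.survey_days + 1
    rec["occasion"] = (day_in_survey - 1) // design.occasion_days + 1
    return rec


def merge_intervals(deployments: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent active intervals per station.

    Intervals are inclusive date ranges; ``start`` must not exceed ``end``.
    """
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in deployments.columns]
    if missing:
        raise ValueError(f"deployment table lacks columns: {missing}")
    dep = deployments.copy()
    dep["start"] = pd.to_datetime(dep["start"]).dt.date
    dep["end"] = pd.to_datetime(dep["end"]).dt.date
    if (pd.Series(dep["start"]) > pd.Series(dep["end"])).any():
        raise ValueError("deployment interval with start > end")
    rows = []
    for station, grp in dep.groupby("station_id", sort=True):
        ivals = sorted(zip(grp["start"], grp["end"]))
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e + _dt.timedelta(days=1):
                cur_e = max(cur_e, e)
            else:
                rows.append((station, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((station, cur_s, cur_e))
    return pd.DataFrame(rows, columns=list(DEPLOYMENT_COLUMNS))


def _interval_days_in(ivals, lo: _dt.date, hi: _dt.date) -> int:
    """Count active days of merged intervals inside the inclusive [lo, hi]."""
    total = 0
    for s, e in ivals:
        a, b = max(s, lo), min(e, hi)
        if a <= b:
            total += (b - a).days + 1
    return total


@dataclass
class DetectionData:
    """Stacked detection histories for a species pair.

    ``y[species]`` is an (n_sites, n_occasions) float array with values in
    {0, 1, NaN}; NaN marks occasions with zero effort.  ``effort`` holds the
    active-day count per site x occasion.  ``sites`` are (station_id, survey)
    pairs; ``site_covariates`` is an aligned DataFrame (may include a
    ``survey`` column for year-type effects).
    """

    sites: list[tuple[str, int]]
    y: dict[str, np.ndarray]
    effort: np.ndarray
    design: SurveyDesign
    site_covariates: pd.DataFrame | None = None
    species_pair: tuple[str, str] = ("species1", "species2")

    @property
    def n_sites(self) -> int:
        return self.effort.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.effort.shape[1]

    def validate(self) -> None:
        for sp, mat in self.y.items():
            if mat.shape != self.effort.shape:
                raise ValueError(f"shape mismatch for species {sp!r}")
            zero = self.effort == 0
            if np.isfinite(mat[zero]).any():
                raise ValueError("y must be missing wherever effort is 0")
            obs = mat[~zero]
            if not np.isin(obs[np.isfinite(obs)], (0.0, 1.0)).all():
                raise ValueError("observed y values must be 0/1")
        if self.site_covariates is not None and len(self.site_covariates) != self.n_sites:
            raise ValueError("site_covariates misaligned with sites")


def build_detection_data(
    records: pd.DataFrame,
    deployments: pd.DataFrame,
    design: SurveyDesign,
    species_pair: tuple[str, str],
    covariates: pd.DataFrame | None = None,
) -> DetectionData:
    """Bin independence-filtered records into stacked detection histories.

    Detection collapses within-occasion counts to 0/1.  Occasions with zero
    effort are missing for both species; site rows (station x survey) with no
    effort at all are dropped.  Stations with records but no deployment raise.
    Trailing partial survey blocks are kept, their uncovered occasions missing.
    """
    rec = assign_occasions(records, design)
    dep = merge_intervals(deployments)
    unknown = sorted(set(rec["station_id"]) - set(dep["station_id"]))
    if unknown:
        raise RecordValidationError(f"stations with records but no deployment: {unknown}")

    study_end = max(dep["end"])
    n_surveys = design.n_surveys(study_end)
    stations = sorted(dep["station_id"].unique())
    ivals = {st: list(zip(g["start"], g["end"])) for st, g in dep.groupby("station_id")}

    sites: list[tuple[str, int]] = []
    effort_rows = []
    for st in stations:
        for sv in range(1, n_surveys + 1):
            eff = np.array(
                [
                    _interval_days_in(ivals[st], *design.occasion_window(sv, occ))
                    for occ in range(1, design.n_occasions + 1)
                ],
                dtype=float,
            )
            if eff.sum() > 0:
                sites.append((st, sv))
                effort_rows.append(eff)
            else:
                logger.info("dropping all-missing site (%s, survey %d)", st, sv)
    effort = np.vstack(effort_rows) if effort_rows else np.zeros((0, design.n_occasions))
    site_index = {s: i for i, s in enumerate(sites)}

    y = {
        sp: np.where(effort > 0, 0.0, np.nan).copy() for sp in species_pair
    }
    for sp in species_pair:
        sub = rec[rec["species"] == sp]
        for _, row in sub.iterrows():
            key = (row["station_id"], int(row["survey"]))
            if key not in site_index:
                raise RecordValidationError(
                    f"record of {sp!r} at {key} falls in a zero-effort site row"
                )
            i, j = site_index[key], int(row["occasion"]) - 1
            if effort[i, j] == 0:
                raise RecordValidationError(
                    f"record of {sp!r} at {key} occasion {j + 1} has zero effort"
                )
            y[sp][i, j] = 1.0

    site_cov = None
    if covariates is not None:
        cov = covariates.set_index("station_id") if "station_id" in covariates.columns else covariates
        missing = [st for st, _ in sites if st not in cov.index]
        if missing:
            raise ValueError(f"stations lacking covariate rows: {sorted(set(missing))}")
        site_cov = cov.loc[[st for st, _ in sites]].reset_index(drop=True)
        site_cov["survey"] = [sv for _, sv in sites]

    data = DetectionData(
        sites=sites,
        y=y,
        effort=effort,
        design=design,
        site_covariates=site_cov,
        species_pair=tuple(species_pair),
    )
    data.validate()
    return data


def trapping_rate(n_records: int, trap_nights: float) -> float:
    """Independent records per 100 trap-nights, rounded to 2 decimals."""
    if trap_nights <= 0:
        raise ValueError("trap_nights must be positive")
    return round(100.0 * n_records / trap_nights, 2)


def summarize_effort(
    records: pd.DataFrame, deployments: pd.DataFrame
) -> tuple[int, pd.DataFrame]:
    """Total trap-nights and per-species independent-record counts and rates.

    ``records`` should already be independence-filtered.  Trap-nights are the
    merged deployment days, so they equal the sum of the effort matrix built
    from the same deployments.
    """
    dep = merge_intervals(deployments)
    trap_nights = int(sum((e - s).days + 1 for s, e in zip(dep["start"], dep["end"])))
    if trap_nights == 0:
        raise ValueError("zero trap-nights")
    rec = validate_records(records)
    counts = rec.groupby("species").size().sort_values(ascending=False)
    table = pd.DataFrame(
        {
            "species": counts.index,
            "n_records": counts.values,
            "rate_per_100_trap_nights": [trapping_rate(n, trap_nights) for n in counts.values],
        }
    ).reset_index(drop=True)
    return trap_nights, table
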