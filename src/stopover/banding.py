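"""Banding-record ingestion, preparation rules, and capture histories.

The raw input is a delimited table of capture events — one row per time a
bird was handled — with columns ``band_id, species, date, hour``.  This
module applies the standard preparation rules for mist-net data:

* capture times rounded to the nearest hour (23:30+ clamps to 23 so a
  record never rolls into the next day);
* within (band, date, hour) duplicates, only the earliest record kept;
* records outside both season windows dropped;
* individuals that overwinter at the station removed entirely;

and then builds the two analysis inputs: a first-capture table (one row
per individual per season-year, feeding the arrival-quantile trends) and
binary capture-history matrices (individuals x occasions, feeding the
Cormack-Jolly-Seber model).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import FALL, SPRING, SeasonWindow

__all__ = [
    "RECORD_COLUMNS",
    "CaptureHistoryMatrix",
    "ingest_records",
    "preprocess",
    "first_captures",
    "build_capture_histories",
    "sample_size_filter",
    "recapture_summary",
    "recapture_percentage",
]

logger = logging.getLogger(__name__)

#: Required columns of the raw capture-record schema.
RECORD_COLUMNS = ("band_id", "species", "date", "hour")


@dataclass
class CaptureHistoryMatrix:
    """Binary detection matrix for one species-season-year cohort.

    ``matrix[i, t] == 1`` iff individual ``band_ids[i]`` was captured on
    occasion ``t + 1``.  Every row has at least one detection (the data
    condition on first capture); rows are ordered by band id.
    """

    species: str
    season: str
    year: int
    band_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("capture-history matrix must be 2-D")
        if len(self.band_ids) != self.matrix.shape[0]:
            raise ValueError("band_ids length does not match matrix rows")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("capture-history matrix must be binary")
        if self.matrix.shape[0] and not (self.matrix.sum(axis=1) >= 1).all():
            raise ValueError("every capture history must contain >=1 detection")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"occ{t}" for t in range(1, self.k + 1)]
        return pd.DataFrame(self.matrix, index=pd.Index(self.band_ids, name="band_id"),
                            columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species: str, season: str, year: int
                   ) -> "CaptureHistoryMatrix":
        return cls(species, season, year, list(df.index), df.to_numpy())


def _round_hour(raw) -> int | None:
    """Parse an hour cell: integer hour or 'HH:MM'; minutes >= 30 round up,
    23:30+ clamps to 23.  Returns None when out of range/unparseable."""
    if isinstance(raw, str) and ":" in raw:
        try:
            hh, mm = raw.split(":")[:2]
            h, m = int(hh), int(mm)
        except ValueError:
            return None
        if not (0 <= h <= 23 and 0 <= m <= 59):
            return None
        return min(h + (1 if m >= 30 else 0), 23)
    try:
        h = int(raw)
    except (TypeError, ValueError):
        return None
    return h if 0 <= h <= 23 else None


def ingest_records(path) -> pd.DataFrame:
    """Read raw capture records from a delimited file.

    Rows with an unparseable date or an out-of-range hour are skipped and
    counted; a summary of skipped rows (with 1-based data line numbers) is
    logged and stored in ``df.attrs["ingest_report"]``.  A missing required
    column is a hard error.
    """
    raw = pd.read_csv(path, dtype={"band_id": str, "species": str, "hour": str})
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"records file {path} missing columns: {missing}")

    dates = pd.to_datetime(raw["date"], errors="coerce", format="mixed")
    hours = raw["hour"].map(_round_hour)
    bad = dates.isna() | hours.isna() | raw["band_id"].isna() | raw["species"].isna()
    bad_lines = (raw.index[bad] + 1).tolist()
    if bad_lines:
        logger.warning("skipped %d unparseable record(s) at data line(s) %s",
                       len(bad_lines), bad_lines[:20])

    out = pd.DataFrame({
        "band_id": raw.loc[~bad, "band_id"],
        "species": raw.loc[~bad, "species"],
        "date": dates[~bad].dt.date,
        "hour": hours[~bad].astype(int),
    }).reset_index(drop=True)
    out.attrs["ingest_report"] = {"n_read": len(raw), "n_kept": len(out),
                                  "n_skipped": len(bad_lines),
                                  "skipped_lines": bad_lines}
    return out


def _overwinter_bands(records: pd.DataFrame) -> set[tuple[str, str]]:
    """(species, band_id) pairs captured in fall of year y and spring of
    year y+1 — the default operationalization of overwintering at the site."""
    key = records[["species", "band_id", "season", "year"]].drop_duplicates()
    fall = key[key["season"] == "fall"]
    spring = key[key["season"] == "spring"].copy()
    spring["year"] -= 1
    merged = fall.merge(spring, on=["species", "band_id", "year"])
    return set(zip(merged["species"], merged["band_id"]))


def preprocess(records: pd.DataFrame,
               windows: tuple[SeasonWindow, ...] = (SPRING, FALL),
               overwinter_rule: str = "fall-to-next-spring") -> pd.DataFrame:
    """Apply the data-preparation rules and annotate season/occasion.

    Returns a new frame with added columns ``year``, ``doy``, ``season`` and
    ``occasion`` (1-based; occasion 1 = window start).  Rules applied, with
    counts logged and kept in ``df.attrs["preprocess_report"]``:

    1. records outside every season window dropped;
    2. within (band_id, date, hour) only the earliest record retained;
    3. individuals matching the overwinter rule removed entirely.

    ``overwinter_rule`` is ``"fall-to-next-spring"`` (remove individuals of
    a species captured in both fall of year y and spring of year y+1) or
    ``"none"``.  The operation is idempotent.
    """
    if overwinter_rule not in ("fall-to-next-spring", "none"):
        raise ValueError(f"unknown overwinter rule {overwinter_rule!r}")
    df = records.copy()
    n_in = len(df)
    dates = pd.to_datetime(df["date"], format="mixed").dt.date

    win_by_date = dates.map(lambda d: next((w for w in windows if w.contains(d)), None))
    in_window = win_by_date.notna()
    df = df[in_window].copy()
    dates = dates[in_window]
    wins = win_by_date[in_window]
    df["year"] = [d.year for d in dates]
    df["doy"] = [d.timetuple().tm_yday for d in dates]
    df["season"] = [w.label for w in wins]
    df["occasion"] = [w.occasion(d) for w, d in zip(wins, dates)]
    df["date"] = dates
    n_dropped_window = n_in - len(df)

    before = len(df)
    df = df.drop_duplicates(subset=["band_id", "species", "date", "hour"],
                            keep="first")
    n_dupes = before - len(df)

    ow = _overwinter_bands(df) if overwinter_rule == "fall-to-next-spring" else set()
    if ow:
        mask = [(sp, b) in ow for sp, b in zip(df["species"], df["band_id"])]
        df = df[~np.asarray(mask)]
    n_overwinter = before - n_dupes - len(df)

    df = df.sort_values(["species", "season", "year", "band_id", "occasion", "hour"],
                        kind="stable").reset_index(drop=True)
    report = {"n_in": n_in, "n_out": len(df),
              "n_dropped_outside_window": n_dropped_window,
              "n_dropped_duplicate": n_dupes,
              "n_dropped_overwinter": n_overwinter,
              "overwinter_individuals": sorted(ow)}
    assert report["n_in"] == (report["n_out"] + n_dropped_window
                              + n_dupes + n_overwinter)
    logger.info("preprocess: %s", {k: v for k, v in report.items()
                                   if k != "overwinter_individuals"})
    df.attrs["preprocess_report"] = report
    return df


def first_captures(records: pd.DataFrame) -> pd.DataFrame:
    """First-capture table: one row per individual per season-year.

    A bird recaptured in a later year starts a fresh row for that
    season-year.  Returns columns species, season, year, band_id, doy,
    occasion (the minimum over that individual's records in the season-year).
    """
    cols = ["species", "season", "year", "band_id"]
    if records.empty:
        return pd.DataFrame(columns=cols + ["doy", "occasion"])
    out = (records.groupby(cols, as_index=False)[["doy", "occasion"]].min()
           .sort_values(cols, kind="stable").reset_index(drop=True))
    return out


def build_capture_histories(records: pd.DataFrame,
                            windows: tuple[SeasonWindow, ...] = (SPRING, FALL),
                            ) -> dict[tuple[str, str, int], CaptureHistoryMatrix]:
    """Build one binary capture-history matrix per (species, season, year).

    Cell (i, t) is 1 iff individual i was detected on occasion t+1; multiple
    same-day captures collapse to a single 1.  Rows are ordered by band id.
    """
    k_by_season = {w.label: w.k for w in windows}
    out: dict[tuple[str, str, int], CaptureHistoryMatrix] = {}
    for (sp, season, year), grp in records.groupby(["species", "season", "year"]):
        k = k_by_season[season]
        bands = sorted(grp["band_id"].unique())
        idx = {b: i for i, b in enumerate(bands)}
        mat = np.zeros((len(bands), k), dtype=np.uint8)
        rows = grp["band_id"].map(idx).to_numpy()
        cols = grp["occasion"].to_numpy() - 1
        mat[rows, cols] = 1
        out[(sp, season, year)] = CaptureHistoryMatrix(sp, season, int(year),
                                                       bands, mat)
    return out


def sample_size_filter(first_caps: pd.DataFrame, min_n: int = 300
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop species-season datasets without more than ``min_n`` individuals.

    The retention rule is strict: a species-season is kept only when its
    total individual count exceeds ``min_n``.  Returns the filtered
    first-capture table and a report frame (species, season, n, retained).
    """
    if first_caps.empty:
        report = pd.DataFrame(columns=["species", "season", "n", "retained"])
        return first_caps.copy(), report
    counts = (first_caps.groupby(["species", "season"], as_index=False)
              .size().rename(columns={"size": "n"}))
    counts["retained"] = counts["n"] > min_n
    keep = counts[counts["retained"]][["species", "season"]]
    filtered = first_caps.merge(keep, on=["species", "season"])
    for _, row in counts[~counts["retained"]].iterrows():
        logger.warning("excluding %s %s: n=%d <= %d",
                       row["species"], row["season"], row["n"], min_n)
    return filtered.reset_index(drop=True), counts


def recapture_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-season record accounting: total records and recapture events.

    A record is a recapture when the same (species, band_id) was already
    captured on an earlier occasion of the dataset; the first-ever record
    of a band is the banding event itself.
    """
    df = records.sort_values(["species", "band_id", "date", "hour"], kind="stable")
    firsts = df.groupby(["species", "band_id"]).head(1).index
    df = df.assign(recapture=~df.index.isin(firsts))
    out = df.groupby("season").agg(n_records=("band_id", "size"),
                                   n_recaptures=("recapture", "sum")).reset_index()
    out["recapture_pct"] = [recapture_percentage(r, c) for r, c
                            in zip(out["n_records"], out["n_recaptures"])]
    return out


def recapture_percentage(n_records: int, n_recaptures: int) -> float:
    """Recapture share of all records, in percent rounded to one decimal."""
    if n_records <= 0:
        raise ValueError("n_records must be positive")
    if not 0 <= n_recaptures <= n_records:
        raise ValueError("n_recaptures must lie in [0, n_records]")
    return round(100.0 * n_recaptures / n_records, 1)
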