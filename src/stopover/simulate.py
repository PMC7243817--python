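"""Synthetic banding data with known ground truth.

The generator emulates a multi-decade mist-netting study so that every
downstream stage — arrival-quantile trends, the Cormack-Jolly-Seber
stopover model, and their comparison — has a parameter-recovery test:

* per-year cohorts of individuals whose arrival-day distribution has
  exactly controllable 0.15/0.50/0.85 quantiles drifting linearly over
  the years (the quantity the phenology analysis estimates);
* a geometric length of stay governed by a daily persistence probability
  phi, with logit-scale year random effects and an optional linear
  logit-scale trend (the quantity the CJS model estimates);
* daily Bernoulli detection with probability p, and the mist-net
  conditioning rule: individuals never detected are discarded.

Arrival days are drawn by inverse-CDF sampling from a piecewise-linear
quantile function through the three target quantiles, with linear tails
through (0.02, q15 - (q50 - q15)) and (0.98, q85 + (q85 - q50)), then
rounded to integer occasions and clipped to the season window.  The
construction puts the simulation truth on the same scale as the
estimator: the continuous quantile function passes exactly through the
three targets in every year.

Mean length of stay differs between the discrete-day truth, 1/(1 - phi),
and the continuous-time life-expectancy transform -1/ln(phi) reported by
the stopover model; :class:`SimulationTruth` records phi itself so
recovery tests can compare on whichever scale they need.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .banding import CaptureHistoryMatrix
from .windows import SPRING, SeasonWindow

__all__ = [
    "ArrivalTrendParams",
    "StopoverDetectParams",
    "SimulationTruth",
    "simulate_arrivals",
    "simulate_capture_histories",
    "export_records",
    "simulate_banding_dataset",
]


@dataclass(frozen=True)
class ArrivalTrendParams:
    """Targets of the simulated arrival-day distribution.

    baseline_quantiles are the 0.15/0.50/0.85 quantiles (days from season
    start, occasion scale) in year 0; slopes_per_decade are their linear
    drifts in days per decade.  cohort_size may be a single int or one per
    year.  The three quantile curves must never cross over the simulated
    span and the baselines must lie inside [1, season_length_k].
    """

    baseline_quantiles: tuple[float, float, float]
    slopes_per_decade: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_years: int = 46
    cohort_size: int | tuple[int, ...] = 1000
    season_length_k: int = SPRING.k

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.season_length_k < 1:
            raise ValueError("season_length_k must be >= 1")
        q = self.baseline_quantiles
        if not (1 <= q[0] and q[2] <= self.season_length_k):
            raise ValueError("baseline quantiles must lie in [1, k]")
        for y in range(self.n_years):
            qy = self.quantiles_at(y)
            if not (qy[0] < qy[1] < qy[2]):
                raise ValueError(
                    f"quantile targets cross in simulated year {y}: {qy}")

    def cohort_sizes(self) -> np.ndarray:
        if np.isscalar(self.cohort_size):
            return np.full(self.n_years, int(self.cohort_size))
        sizes = np.asarray(self.cohort_size, dtype=int)
        if sizes.shape != (self.n_years,):
            raise ValueError("cohort_size list must have n_years entries")
        return sizes

    def quantiles_at(self, year_index: int) -> np.ndarray:
        """Target (q15, q50, q85) in simulated year ``year_index``."""
        base = np.asarray(self.baseline_quantiles, float)
        slopes = np.asarray(self.slopes_per_decade, float)
        return base + slopes * (year_index / 10.0)


@dataclass(frozen=True)
class StopoverDetectParams:
    """Daily persistence (phi) and detection (p) process parameters.

    Year effects act on the logit scale: logit(phi_y) = logit(phi_mean)
    + phi_trend_per_decade * year/10 + Normal(0, phi_logit_sd), and
    analogously for p without a trend.  The logit-scale construction keeps
    every realized probability strictly inside (0, 1).
    """

    phi_mean: float = 0.6
    phi_logit_sd: float = 0.0
    phi_trend_per_decade: float = 0.0
    p_mean: float = 0.3
    p_logit_sd: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("phi_mean", self.phi_mean), ("p_mean", self.p_mean)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.phi_logit_sd < 0 or self.p_logit_sd < 0:
            raise ValueError("logit-scale SDs must be non-negative")

    def realize(self, n_years: int, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
        """Draw per-year (phi_y, p_y)."""
        years = np.arange(n_years)
        lphi = (logit(self.phi_mean) + self.phi_trend_per_decade * years / 10.0
                + rng.normal(0.0, self.phi_logit_sd, n_years))
        lp = logit(self.p_mean) + rng.normal(0.0, self.p_logit_sd, n_years)
        phi_y, p_y = expit(lphi), expit(lp)
        if not (np.all((phi_y > 0) & (phi_y < 1)) and np.all((p_y > 0) & (p_y < 1))):
            raise ValueError("realized probabilities left (0, 1)")  # pragma: no cover
        return phi_y, p_y


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    individuals holds one row per simulated bird (including discarded
    never-detected ones): year_index, individual, arrival, departure
    (true last day present, possibly beyond the season end), detected.
    """

    arrival_params: ArrivalTrendParams
    stopover_params: StopoverDetectParams
    phi_y: np.ndarray
    p_y: np.ndarray
    individuals: pd.DataFrame = field(default_factory=pd.DataFrame)

    def retained(self) -> pd.DataFrame:
        return self.individuals[self.individuals["detected"]]


def _quantile_knots(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q15, q50, q85 = q
    u = np.array([0.02, 0.15, 0.50, 0.85, 0.98])
    v = np.array([q15 - (q50 - q15), q15, q50, q85, q85 + (q85 - q50)])
    return u, v


def _inverse_cdf(u: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Piecewise-linear quantile function with linear extrapolated tails."""
    ku, kv = _quantile_knots(q)
    out = np.interp(u, ku, kv)
    lo, hi = u < ku[0], u > ku[-1]
    if lo.any():
        s = (kv[1] - kv[0]) / (ku[1] - ku[0])
        out[lo] = kv[0] + s * (u[lo] - ku[0])
    if hi.any():
        s = (kv[-1] - kv[-2]) / (ku[-1] - ku[-2])
        out[hi] = kv[-1] + s * (u[hi] - ku[-1])
    return out


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_arrivals(params: ArrivalTrendParams, seed
                      ) -> list[np.ndarray]:
    """Draw true arrival occasions for every simulated year.

    Returns one integer array per year, each value in [1, k].  Per-year
    random streams are derived deterministically from the master seed, so
    year y's cohort does not depend on the sizes of earlier cohorts.
    """
    streams = _as_seedseq(seed).spawn(params.n_years)
    sizes = params.cohort_sizes()
    arrivals = []
    for y, (ss, n) in enumerate(zip(streams, sizes)):
        rng = np.random.default_rng(ss)
        u = rng.uniform(size=n)
        days = _inverse_cdf(u, params.quantiles_at(y))
        arrivals.append(np.clip(np.rint(days), 1, params.season_length_k)
                        .astype(int))
    return arrivals


def simulate_capture_histories(arrivals: list[np.ndarray],
                               sd_params: StopoverDetectParams,
                               k: int,
                               seed: int,
                               species: str = "SYN",
                               season: str = "spring",
                               start_year: int = 1970,
                               ) -> tuple[dict[int, CaptureHistoryMatrix],
                                          SimulationTruth]:
    """Overlay stay and detection processes on true arrivals.

    Each individual is present from its arrival occasion and remains each
    subsequent day independently with probability phi_y (geometric stay);
    each present day within the season is detected independently with
    probability p_y.  Individuals never detected are discarded, as in real
    mist-net data.  Returns capture-history matrices keyed by calendar
    year (years with no detected individual are omitted) plus the truth.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n_years = len(arrivals)
    root = _as_seedseq(seed)
    rng_year = np.random.default_rng(root.spawn(1)[0])
    phi_y, p_y = sd_params.realize(n_years, rng_year)
    streams = root.spawn(n_years + 1)[1:]

    frames = []
    matrices: dict[int, CaptureHistoryMatrix] = {}
    for y, (arr, ss) in enumerate(zip(arrivals, streams)):
        rng = np.random.default_rng(ss)
        n = len(arr)
        if n == 0:
            continue
        if np.any((arr < 1) | (arr > k)):
            raise ValueError(f"year {y}: arrivals outside [1, {k}]")
        # geometric stay: number of days present >= 1
        stay = rng.geometric(1.0 - phi_y[y], size=n)
        departure = arr + stay - 1
        occ = np.arange(1, k + 1)
        present = (occ >= arr[:, None]) & (occ <= departure[:, None])
        detect = present & (rng.uniform(size=(n, k)) < p_y[y])
        seen = detect.any(axis=1)
        frames.append(pd.DataFrame({"year_index": y, "individual": np.arange(n),
                                    "arrival": arr, "departure": departure,
                                    "detected": seen}))
        if seen.any():
            bands = [f"{species}-{start_year + y}-{i:06d}"
                     for i in np.flatnonzero(seen)]
            matrices[start_year + y] = CaptureHistoryMatrix(
                species, season, start_year + y, bands,
                detect[seen].astype(np.uint8))
    cols = ["year_index", "individual", "arrival", "departure", "detected"]
    truth = SimulationTruth(
        arrival_params=None, stopover_params=sd_params,
        phi_y=phi_y, p_y=p_y,
        individuals=(pd.concat(frames, ignore_index=True) if frames
                     else pd.DataFrame(columns=cols)))
    return matrices, truth


def export_records(histories: dict[int, CaptureHistoryMatrix],
                   window: SeasonWindow,
                   hour: int = 6) -> pd.DataFrame:
    """Flatten capture-history matrices to raw capture-record rows.

    One row per detection; occasion t maps to the window's t-th calendar
    day of the matrix's year; band ids are stable per individual.  The
    result round-trips through :func:`stopover.banding.preprocess` and
    :func:`stopover.banding.build_capture_histories` bit-exactly.
    """
    rows = []
    for year in sorted(histories):
        m = histories[year]
        if m.k != window.k:
            raise ValueError(f"matrix k={m.k} does not match window k={window.k}")
        for band, hist in zip(m.band_ids, m.matrix):
            for t in np.flatnonzero(hist):
                rows.append((band, m.species,
                             window.date_of_occasion(year, int(t) + 1).isoformat(),
                             hour))
    return pd.DataFrame(rows, columns=["band_id", "species", "date", "hour"])


def simulate_banding_dataset(arrival_params: ArrivalTrendParams,
                             stopover_params: StopoverDetectParams,
                             seed: int,
                             species: str = "SYN",
                             window: SeasonWindow = SPRING,
                             start_year: int = 1970,
                             ) -> tuple[pd.DataFrame, SimulationTruth]:
    """End-to-end convenience: arrivals -> histories -> raw records."""
    if arrival_params.season_length_k != window.k:
        raise ValueError("arrival_params.season_length_k must equal window.k")
    seq = _as_seedseq(seed).spawn(2)
    arrivals = simulate_arrivals(arrival_params, seed=seq[0])
    matrices, truth = simulate_capture_histories(
        arrivals, stopover_params, k=window.k,
        seed=seq[1], species=species,
        season=window.label, start_year=start_year)
    truth.arrival_params = arrival_params
    records = export_records(matrices, window)
    return records, truth
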