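"""Linear trends in arrival-date quantiles and passage-duration change.

Migration timing is summarized by three conditional quantiles of
first-capture day versus year — 0.15 (early arrivals), 0.50 (median) and
0.85 (late arrivals) — each fit by quantile regression, i.e. by
minimizing the check loss

    sum_i rho_tau(d_i - a - b * year_i),   rho_tau(u) = u * (tau - 1[u < 0]).

Slopes are reported in days per decade (per-year slope x 10).  The
derived contrast slope(0.85) - slope(0.15) measures the rate of change
of passage duration: positive means the site is occupied for more days
each season over time (diverging tails), negative means fewer.
Uncertainty comes from case-resampling bootstrap with percentile
intervals; the contrast is computed within each replicate so its
interval respects the correlation between tail slopes.

The point fits solve the exact quantile-regression linear program (dual
form, HiGHS); among tied optima the lexicographically smallest
(slope, intercept) vertex is returned.  Bootstrap replicates may use a
fast iteratively-reweighted fallback at large n, whose objective agrees
with the exact solution to ~1e-10 relative in practice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

__all__ = [
    "Scenario",
    "QuantileTrendFit",
    "TrendCI",
    "PassageChange",
    "BootstrapTrends",
    "fit_quantile_trend",
    "bootstrap_quantile_trends",
    "classify_scenario",
    "empirical_passage_duration",
    "check_loss",
    "PhenologyTrendModel",
    "PhenologyTrendResults",
]

DEFAULT_TAUS = (0.15, 0.50, 0.85)


class Scenario(enum.Enum):
    """Joint classification of tail-quantile trends (see module docstring)."""

    NO_CHANGE = "no_change"
    PARALLEL = "parallel"
    EXPANSION = "expansion"
    CONTRACTION = "contraction"


@dataclass(frozen=True)
class QuantileTrendFit:
    """One fitted conditional-quantile line.

    slope is in days per decade; intercept is the fitted day at
    ``ref_year`` (the mean of the observed years, used internally to
    center the predictor); objective is the minimized check loss.
    """

    tau: float
    slope: float
    intercept: float
    ref_year: float
    n: int
    objective: float

    @property
    def slope_per_year(self) -> float:
        return self.slope / 10.0

    def predict(self, years) -> np.ndarray:
        return self.intercept + self.slope_per_year * (np.asarray(years, float)
                                                       - self.ref_year)


@dataclass(frozen=True)
class TrendCI:
    """Percentile bootstrap confidence interval for a slope (days/decade)."""

    lower: float
    upper: float
    n_boot: int
    level: float = 0.95
    boot_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def significant(self) -> bool:
        """True when the interval excludes zero."""
        return not (self.lower <= 0.0 <= self.upper)


@dataclass(frozen=True)
class PassageChange:
    """Rate of change of passage duration: slope(0.85) - slope(0.15)."""

    delta_slope: float
    ci: TrendCI
    scenario: Scenario


def check_loss(residuals: np.ndarray, tau: float) -> float:
    u = np.asarray(residuals, float)
    return float(np.sum(u * (tau - (u < 0))))


def _solve_qr_exact(x: np.ndarray, y: np.ndarray, tau: float
                    ) -> tuple[float, float, float]:
    """Exact 2-parameter quantile regression via the dual LP.

    Dual:  max y'd  s.t.  sum(d) = 0, sum(x*d) = 0, tau-1 <= d <= tau.
    The equality constraints' dual marginals recover (intercept, slope);
    if the recovered pair does not reproduce the LP optimum (degenerate
    bases), fall back to the line through the basic observations.
    """
    n = len(y)
    A = sparse.csr_matrix(np.vstack([np.ones(n), x]))
    res = linprog(-y, A_eq=A, b_eq=[0.0, 0.0], bounds=(tau - 1.0, tau),
                  method="highs")
    if res.status != 0:  # pragma: no cover - HiGHS is reliable on this LP
        raise RuntimeError(f"quantile-regression LP failed: {res.message}")
    opt = -res.fun
    a, b = (-res.eqlin.marginals).tolist()
    tol = 1e-7 * (1.0 + abs(opt))
    if abs(check_loss(y - a - b * x, tau) - opt) <= tol:
        return a, b, opt
    # degenerate marginals: optimal line passes through >=2 sample points
    # whose dual variables are strictly between their bounds
    d = res.x
    interior = np.flatnonzero((d > tau - 1.0 + 1e-9) & (d < tau - 1e-9))
    best = None
    for i in interior:
        for j in interior:
            if x[j] == x[i]:
                continue
            bb = (y[j] - y[i]) / (x[j] - x[i])
            aa = y[i] - bb * x[i]
            o = check_loss(y - aa - bb * x, tau)
            if best is None or o < best[2]:
                best = (aa, bb, o)
    if best is not None and abs(best[2] - opt) <= tol:
        return best
    raise RuntimeError("could not recover primal quantile-regression solution")


def _lexicographic_refine(x: np.ndarray, y: np.ndarray, tau: float,
                          opt: float) -> tuple[float, float]:
    """Among optimal (a, b), return the pair with smallest b, then smallest a.

    Solves two primal LPs over variables (a, b, u, v) with the check loss
    constrained to the known optimum (plus a small slack for numerics).
    """
    n = len(y)
    slack = 1e-9 * (1.0 + abs(opt))
    ones, I = np.ones(n), sparse.identity(n, format="csr")
    # columns: a, b, u_1..u_n, v_1..v_n ; rows: a + b x + u - v = y
    A_eq = sparse.hstack([sparse.csr_matrix(ones[:, None]),
                          sparse.csr_matrix(x[:, None]), I, -I], format="csr")
    loss_row = sparse.hstack(
        [sparse.csr_matrix(np.zeros((1, 2))),
         sparse.csr_matrix(tau * ones[None, :]),
         sparse.csr_matrix((1.0 - tau) * ones[None, :])], format="csr")
    bounds = [(None, None), (None, None)] + [(0, None)] * (2 * n)

    def _solve(c, extra_ub=None):
        A_ub, b_ub = loss_row, [opt + slack]
        if extra_ub is not None:
            A_ub = sparse.vstack([loss_row, extra_ub[0]], format="csr")
            b_ub = [opt + slack, extra_ub[1]]
        r = linprog(c, A_eq=A_eq, b_eq=y, A_ub=A_ub, b_ub=b_ub,
                    bounds=bounds, method="highs")
        return r

    c_b = np.zeros(2 + 2 * n); c_b[1] = 1.0
    r1 = _solve(c_b)
    if r1.status != 0:  # pragma: no cover
        raise RuntimeError("tie-break LP (slope) failed")
    b_min = r1.x[1]
    brow = sparse.csr_matrix(c_b[None, :])
    c_a = np.zeros(2 + 2 * n); c_a[0] = 1.0
    r2 = _solve(c_a, extra_ub=(brow, b_min + 1e-9 * (1 + abs(b_min))))
    if r2.status != 0:  # pragma: no cover
        raise RuntimeError("tie-break LP (intercept) failed")
    return float(r2.x[0]), float(r2.x[1])


def _snap_to_vertex(x: np.ndarray, y: np.ndarray, tau: float,
                    a: float, b: float, opt: float, m: int = 15
                    ) -> tuple[float, float, float]:
    """Snap an approximate solution to an exact optimal vertex.

    An optimal line passes through >= 2 sample points; among lines through
    pairs of the m points nearest the approximate fit that attain the
    known optimum (within float tolerance), return the lexicographically
    smallest (slope, intercept).  Falls back to the input if no such pair
    is found (degenerate vertical candidates).
    """
    r = y - a - b * x
    near = np.argsort(np.abs(r))[:m]
    xs, ys = x[near], y[near]
    tol = 1e-9 * (1.0 + abs(opt))
    cands = []
    for i in range(len(near)):
        dx = xs - xs[i]
        for j in np.flatnonzero(dx):
            bb = (ys[j] - ys[i]) / dx[j]
            aa = ys[i] - bb * xs[i]
            o = check_loss(y - aa - bb * x, tau)
            if o <= opt + tol:
                cands.append((bb, aa, o))
    if not cands:
        return a, b, check_loss(r, tau)
    bb, aa, o = min(cands)
    return aa, bb, o


def _fit_irls(x: np.ndarray, y: np.ndarray, tau: float
              ) -> tuple[float, float, float]:
    """Fast fit via statsmodels' IRLS quantile regression, vertex-polished.

    IRLS lands within float noise of the optimum but not exactly on it;
    the polish step snaps to the best line through two of the sample
    points nearest the IRLS fit, so exact ties (e.g. a zero slope in
    day-resolution data) are returned exactly.
    """
    import warnings

    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = sm.QuantReg(y, X).fit(q=tau, max_iter=2000)
    a, b = (float(v) for v in m.params)
    best = (a, b, check_loss(y - a - b * x, tau))
    near = np.argsort(np.abs(y - a - b * x))[:15]
    xs, ys = x[near], y[near]
    for i in range(len(near)):
        dx = xs - xs[i]
        for j in np.flatnonzero(dx):
            bb = (ys[j] - ys[i]) / dx[j]
            aa = ys[i] - bb * xs[i]
            o = check_loss(y - aa - bb * x, tau)
            if o < best[2]:
                best = (aa, bb, o)
    return best


def _validate_xy(years, days):
    years = np.asarray(years, float)
    days = np.asarray(days, float)
    if years.shape != days.shape or years.ndim != 1:
        raise ValueError("years and days must be equal-length 1-D arrays")
    if len(years) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(years) == 0:
        raise ValueError("degenerate predictor: all years identical")
    return years, days


#: n up to which "auto" tie-breaking runs the lexicographic refinement.
_LEX_CUTOFF = 2000


def fit_quantile_trend(years, days, tau: float,
                       tie_break: str = "auto") -> QuantileTrendFit:
    """Fit one conditional-quantile line of day versus year.

    Years are centered internally; the returned slope is in days per
    decade and the intercept is the fitted day at the mean observed year.
    The solution attains the exact check-loss minimum.  When the optimal
    face is flat (possible with day-resolution data), ``"lexicographic"``
    tie-breaking returns the vertex with the smallest (slope, intercept);
    ``"none"`` returns the solver's (deterministic) vertex.  The default
    ``"auto"`` refines up to n = 2000 — ties are a small-sample
    phenomenon and the refinement LP is costly at large n — and is
    deterministic either way.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    years, days = _validate_xy(years, days)
    ref = float(years.mean())
    xc = years - ref
    a, b, opt = _solve_qr_exact(xc, days, tau)
    if tie_break == "auto":
        tie_break = "lexicographic" if len(days) <= _LEX_CUTOFF else "none"
    if tie_break == "lexicographic":
        a, b = _lexicographic_refine(xc, days, tau, opt)
        a, b, o = _snap_to_vertex(xc, days, tau, a, b, opt)
        opt = min(opt, o)
    elif tie_break == "none":
        a, b, opt = _snap_to_vertex(xc, days, tau, a, b, opt)
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return QuantileTrendFit(tau=tau, slope=10.0 * b, intercept=a,
                            ref_year=ref, n=len(days), objective=opt)


#: n above which bootstrap replicates switch to the IRLS fast path.
_IRLS_CUTOFF = 2000


def _boot_slope(x: np.ndarray, y: np.ndarray, tau: float, method: str) -> float:
    if method == "exact" or (method == "auto" and len(y) <= _IRLS_CUTOFF):
        a, b, opt = _solve_qr_exact(x, y, tau)
        _, b, _ = _snap_to_vertex(x, y, tau, a, b, opt)
    else:
        _, b, _ = _fit_irls(x, y, tau)
    return 10.0 * b


@dataclass
class BootstrapTrends:
    """Bootstrap output: per-tau slope CIs plus the 0.85-0.15 contrast."""

    taus: tuple[float, ...]
    cis: dict[float, TrendCI]
    contrast_ci: TrendCI | None
    slopes: dict[float, np.ndarray]
    contrast_slopes: np.ndarray | None
    n_redrawn: int
    ci_flavor: str = "percentile"


def bootstrap_quantile_trends(years, days, taus=DEFAULT_TAUS,
                              n_boot: int = 1000, level: float = 0.95,
                              seed=None, method: str = "auto"
                              ) -> BootstrapTrends:
    """Case-resampling bootstrap of quantile-trend slopes.

    (year, day) pairs are resampled with replacement; every tau is refit
    on each replicate so the 0.85-0.15 contrast is computed within
    replicates.  A replicate whose resampled years are all identical is
    redrawn (capped at 10x n_boot attempts).  Intervals are percentile.
    """
    years, days = _validate_xy(years, days)
    if len(years) < 10:
        raise ValueError("bootstrap requires n >= 10")
    taus = tuple(taus)
    rng = np.random.default_rng(seed)
    n = len(years)
    slopes = {t: np.empty(n_boot) for t in taus}
    n_redrawn = 0
    done = 0
    attempts = 0
    while done < n_boot:
        attempts += 1
        if attempts > 10 * n_boot:
            raise RuntimeError("too many degenerate bootstrap replicates")
        idx = rng.integers(0, n, n)
        ys = years[idx]
        if np.ptp(ys) == 0:
            n_redrawn += 1
            continue
        xc = ys - ys.mean()
        ds = days[idx]
        for t in taus:
            slopes[t][done] = _boot_slope(xc, ds, t, method)
        done += 1

    alpha = (1.0 - level) / 2.0

    def _ci(arr):
        lo, hi = np.quantile(arr, [alpha, 1.0 - alpha])
        return TrendCI(float(lo), float(hi), n_boot, level,
                       boot_sd=float(np.std(arr, ddof=1)))

    cis = {t: _ci(slopes[t]) for t in taus}
    contrast_ci = contrast = None
    if 0.15 in taus and 0.85 in taus:
        contrast = slopes[0.85] - slopes[0.15]
        contrast_ci = _ci(contrast)
    return BootstrapTrends(taus=taus, cis=cis, contrast_ci=contrast_ci,
                           slopes=slopes, contrast_slopes=contrast,
                           n_redrawn=n_redrawn)


def classify_scenario(ci_low_tail: TrendCI, ci_high_tail: TrendCI,
                      contrast_ci: TrendCI) -> Scenario:
    """Decision tree over the tail-slope and contrast intervals.

    A significantly positive contrast is an expansion of passage duration,
    a significantly negative one a contraction; otherwise a significant
    trend in either tail is a parallel shift, and no significance anywhere
    is no change.
    """
    if contrast_ci.significant:
        return Scenario.EXPANSION if contrast_ci.lower > 0 else Scenario.CONTRACTION
    if ci_low_tail.significant or ci_high_tail.significant:
        return Scenario.PARALLEL
    return Scenario.NO_CHANGE


def empirical_passage_duration(days) -> float:
    """Empirical 0.85 minus 0.15 quantile of pooled first-capture days.

    Quantiles use the standard linear-interpolation definition
    (numpy's default, type 7).
    """
    days = np.asarray(days, float)
    if len(days) < 2:
        raise ValueError("need at least 2 observations")
    lo, hi = np.quantile(days, [0.15, 0.85])
    return float(hi - lo)


class PhenologyTrendModel:
    """Quantile-regression trend model for one species-season dataset.

    Parameters
    ----------
    years, days : array-like
        One entry per individual: calendar year and first-capture day
        (day-of-year or occasion — any consistent day scale).
    species, season : str, optional
        Labels carried through to results and reports.
    """

    def __init__(self, years, days, species: str | None = None,
                 season: str | None = None):
        self.years, self.days = _validate_xy(years, days)
        self.species = species
        self.season = season

    @classmethod
    def from_first_captures(cls, table: pd.DataFrame, species: str,
                            season: str, day_column: str = "doy"
                            ) -> "PhenologyTrendModel":
        """Build from a first-capture table (see ``stopover.banding``)."""
        sub = table[(table["species"] == species) & (table["season"] == season)]
        if sub.empty:
            raise ValueError(f"no first captures for {species} {season}")
        return cls(sub["year"].to_numpy(), sub[day_column].to_numpy(),
                   species=species, season=season)

    def fit(self, taus=DEFAULT_TAUS, n_boot: int = 1000, level: float = 0.95,
            seed=None, method: str = "auto") -> "PhenologyTrendResults":
        """Fit all quantile trends and bootstrap their uncertainty."""
        taus = tuple(taus)
        fits = {t: fit_quantile_trend(self.years, self.days, t) for t in taus}
        boot = bootstrap_quantile_trends(self.years, self.days, taus,
                                         n_boot=n_boot, level=level,
                                         seed=seed, method=method)
        return PhenologyTrendResults(self, fits, boot)


class PhenologyTrendResults:
    """Fitted quantile trends, bootstrap intervals, and the passage contrast."""

    def __init__(self, model: PhenologyTrendModel,
                 fits: dict[float, QuantileTrendFit], boot: BootstrapTrends):
        self.model = model
        self.fits = fits
        self.boot = boot
        self.passage_change: PassageChange | None = None
        if boot.contrast_ci is not None:
            delta = fits[0.85].slope - fits[0.15].slope
            scenario = classify_scenario(boot.cis[0.15], boot.cis[0.85],
                                         boot.contrast_ci)
            self.passage_change = PassageChange(delta, boot.contrast_ci, scenario)

    @property
    def scenario(self) -> Scenario | None:
        return self.passage_change.scenario if self.passage_change else None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per tau plus a contrast row."""
        rows = []
        for t, f in self.fits.items():
            ci = self.boot.cis[t]
            rows.append({"species": self.model.species,
                         "season": self.model.season, "quantity": f"tau={t}",
                         "slope_dpd": f.slope, "ci_lo": ci.lower,
                         "ci_hi": ci.upper, "boot_sd": ci.boot_sd,
                         "significant": ci.significant, "n": f.n})
        pc = self.passage_change
        if pc is not None:
            rows.append({"species": self.model.species,
                         "season": self.model.season,
                         "quantity": "passage_change",
                         "slope_dpd": pc.delta_slope, "ci_lo": pc.ci.lower,
                         "ci_hi": pc.ci.upper, "boot_sd": pc.ci.boot_sd,
                         "significant": pc.ci.significant,
                         "n": self.fits[0.15].n})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        label = " ".join(s for s in (self.model.species, self.model.season) if s)
        head = f"Quantile trends{' — ' + label if label else ''}"
        lines = [head, "=" * len(head),
                 f"n = {len(self.model.days)} first captures, "
                 f"bootstrap n_boot = {next(iter(self.boot.cis.values())).n_boot} "
                 f"({self.boot.ci_flavor} CIs)", ""]
        lines.append(f"{'quantity':>16} {'slope d/dec':>12} {'95% CI':>20} sig")
        for t, f in self.fits.items():
            ci = self.boot.cis[t]
            lines.append(f"{'tau=' + format(t, '.2f'):>16} {f.slope:12.3f} "
                         f"[{ci.lower:8.3f}, {ci.upper:8.3f}] "
                         f"{'*' if ci.significant else ' '}")
        pc = self.passage_change
        if pc is not None:
            ci = pc.ci
            lines.append(f"{'passage change':>16} {pc.delta_slope:12.3f} "
                         f"[{ci.lower:8.3f}, {ci.upper:8.3f}] "
                         f"{'*' if ci.significant else ' '}")
            lines.append(f"\nscenario: {pc.scenario.value}")
        return "\n".join(lines)
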