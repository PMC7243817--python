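"""Stopover-duration trends and their comparison with passage duration.

The mechanistic hypothesis under test: because mist-netting samples only
a fraction of the birds present each day, a longer stopover raises the
chance an individual is observed at all, widening the spread of observed
first-capture dates.  If systematic change in stopover duration drives
the observed change in passage duration, the two rates (both in days per
decade) should fall along the 1:1 line — same sign, and stopover change
at least as large.  The comparison reports the Pearson correlation,
per-pair deviations from the identity line, a sign-concordance table,
and the magnitude ratio between the two sets of rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StopoverTrendResult", "ComparisonResult", "stopover_trend",
           "compare_trends"]


@dataclass(frozen=True)
class StopoverTrendResult:
    """OLS trend of annual stopover-duration estimates.

    slope and se are in days per decade (the per-year OLS coefficient
    times ten).  With a single predictor the type II analysis-of-variance
    F test coincides with the ordinary regression F, and F = (slope/se)^2.
    """

    species: str | None
    season: str | None
    slope: float
    se: float
    F: float
    p_value: float
    n_years: int
    units: str = "days_per_decade"


def stopover_trend(annual_estimates, species: str | None = None,
                   season: str | None = None) -> StopoverTrendResult:
    """Regress annual stopover estimates on year (unweighted OLS).

    ``annual_estimates`` is a frame with columns ``year`` and ``S_median``
    (as produced by :meth:`stopover.cjs.CJSResults.annual_stopover`) or a
    (years, values) pair.  Needs at least 3 years.
    """
    import statsmodels.api as sm

    if isinstance(annual_estimates, pd.DataFrame):
        years = annual_estimates["year"].to_numpy(float)
        vals = annual_estimates["S_median"].to_numpy(float)
    else:
        years, vals = (np.asarray(a, float) for a in annual_estimates)
    if len(years) < 3:
        raise ValueError("stopover trend needs >= 3 years")
    scale = max(1.0, float(np.abs(vals).max()))
    if np.allclose(vals, vals.mean(), rtol=0.0, atol=1e-12 * scale):
        # constant series: the 0/0 F-ratio is defined as "no trend"
        return StopoverTrendResult(species=species, season=season, slope=0.0,
                                   se=0.0, F=0.0, p_value=1.0,
                                   n_years=len(years))
    X = sm.add_constant(years - years.mean())
    fit = sm.OLS(vals, X).fit()
    slope, se = 10.0 * fit.params[1], 10.0 * fit.bse[1]
    t = fit.tvalues[1]
    return StopoverTrendResult(species=species, season=season,
                               slope=float(slope), se=float(se),
                               F=float(t * t), p_value=float(fit.pvalues[1]),
                               n_years=len(years))


@dataclass
class ComparisonResult:
    """Passage-duration change versus stopover-duration trend, paired."""

    table: pd.DataFrame
    pearson_r: float
    p_value: float
    magnitude_ratio: float
    sign_concordance: pd.DataFrame

    def summary(self) -> str:
        n = len(self.table)
        lines = [f"Passage vs stopover trends ({n} species-season pairs)",
                 f"Pearson r = {self.pearson_r:.3f} (p = {self.p_value:.3f})",
                 f"mean |passage change| / mean |stopover slope| = "
                 f"{self.magnitude_ratio:.1f}",
                 "", self.sign_concordance.to_string(index=False)]
        return "\n".join(lines)


def compare_trends(passage_changes: pd.DataFrame,
                   stopover_trends) -> ComparisonResult:
    """Pair passage-duration and stopover-duration rates and correlate.

    ``passage_changes`` needs columns species, season, passage_change_dpd;
    ``stopover_trends`` is an iterable of :class:`StopoverTrendResult` or a
    frame with species, season, slope.  Pairs missing on either side are
    dropped; at least 3 matched pairs are required.
    """
    if not isinstance(stopover_trends, pd.DataFrame):
        stopover_trends = pd.DataFrame(
            [{"species": t.species, "season": t.season, "slope": t.slope}
             for t in stopover_trends])
    merged = passage_changes.merge(
        stopover_trends.rename(columns={"slope": "stopover_slope_dpd"}),
        on=["species", "season"])
    if len(merged) < 3:
        raise ValueError("need >= 3 matched species-season pairs")
    x = merged["stopover_slope_dpd"].to_numpy(float)
    y = merged["passage_change_dpd"].to_numpy(float)
    r, p = sps.pearsonr(x, y)
    merged = merged.assign(identity_residual=y - x)

    mean_abs_stop = np.abs(x).mean()
    ratio = np.abs(y).mean() / mean_abs_stop if mean_abs_stop > 0 else np.inf
    sign = pd.DataFrame({
        "stopover_sign": np.sign(x).astype(int),
        "passage_sign": np.sign(y).astype(int)})
    concord = (sign.value_counts().rename("n_pairs").reset_index()
               .sort_values(["stopover_sign", "passage_sign"])
               .reset_index(drop=True))
    return ComparisonResult(table=merged.reset_index(drop=True),
                            pearson_r=float(r), p_value=float(p),
                            magnitude_ratio=float(ratio),
                            sign_concordance=concord)
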