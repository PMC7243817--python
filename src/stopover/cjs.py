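"""Hierarchical Bayesian Cormack-Jolly-Seber stopover model.

The CJS model conditions on each individual's first capture and jointly
estimates a daily apparent-survival probability phi (here: persistence
at the stopover site) and a recapture probability p, both constant
within a banding season.  The likelihood is marginalized over the latent
departure day with the chi recursion

    chi_t = (1 - phi) + phi * (1 - p) * chi_{t+1},    chi_k = 1,

where chi_t is the probability that a bird present at occasion t is
never detected again.  An individual first captured at occasion f and
last captured at occasion l contributes

    phi^(l-f) * p^(d) * (1-p)^(l-f-d) * chi_l,

with d its number of recaptures between f+1 and l.

Years share logit-normal random effects:

    logit(phi_y) ~ Normal(mu_phi, sigma_phi^2)
    logit(p_y)   ~ Normal(mu_p,   sigma_p^2)

with diffuse Normal(0, variance 1000) priors on the hyper-means and
Uniform(0, 5) priors on the logit-scale SDs.  Sampling is adaptive
random-walk Metropolis-within-Gibbs on the marginalized likelihood
(hyper-means are conjugate and drawn exactly); proposal scales adapt
toward a 44% acceptance rate during burn-in and are frozen afterwards.

Assuming mortality during stopover is negligible, phi measures daily
departure risk, and expected stopover duration after first capture is
the continuous-time life expectancy -1/ln(phi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .banding import CaptureHistoryMatrix

__all__ = [
    "CJSConfig",
    "CJSResults",
    "HierarchicalCJSModel",
    "cjs_loglik",
    "chi_vector",
    "fit_hierarchical_cjs",
    "gelman_rubin",
    "stopover_from_phi",
]


@dataclass(frozen=True)
class CJSConfig:
    """MCMC schedule and priors.

    hyper_mean_prior_var is the variance of the logit-scale Normal prior
    on mu_phi and mu_p (the precision parameterization Normal(0, 0.001)
    means variance 1000); sigma_prior_upper bounds the Uniform prior on
    the logit-scale random-effect SDs.
    """

    chains: int = 3
    iterations: int = 30_000
    burn_in: int = 10_000
    thin: int = 3
    rhat_threshold: float = 1.05
    hyper_mean_prior_var: float = 1000.0
    sigma_prior_upper: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.rhat_threshold <= 1:
            raise ValueError("rhat_threshold must exceed 1")
        if self.hyper_mean_prior_var <= 0 or self.sigma_prior_upper <= 0:
            raise ValueError("prior scales must be positive")

    @property
    def retained_per_chain(self) -> int:
        """Post burn-in draws kept per chain (every thin-th iteration)."""
        return (self.iterations - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# marginalized likelihood


def chi_vector(phi: float, p: float, k: int) -> np.ndarray:
    """chi_t for t = 1..k: P(never detected after t | present at t).

    Index 0 of the returned array is chi_1; chi_k = 1 exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    chi = np.empty(k)
    chi[k - 1] = 1.0
    q = phi * (1.0 - p)
    for t in range(k - 2, -1, -1):
        chi[t] = (1.0 - phi) + q * chi[t + 1]
    return chi


@dataclass(frozen=True)
class _HistoryStats:
    """Sufficient statistics of one capture-history matrix.

    With f/l an individual's first/last capture occasion and d its
    recaptures in (f, l]: T = sum(l - f), D = sum(d), M = T - D, and
    last_pairs counts individuals by last-capture occasion.
    """

    n: int
    k: int
    T: float
    D: float
    M: float
    last_pairs: tuple[tuple[int, int], ...]  # (occasion l, count)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "_HistoryStats":
        m = np.asarray(matrix)
        n, k = m.shape
        if n == 0:
            return cls(0, k, 0.0, 0.0, 0.0, ())
        if not (m.sum(axis=1) >= 1).all():
            raise ValueError("capture history with no detection violates "
                             "conditioning on first capture")
        first = m.argmax(axis=1)
        last = k - 1 - m[:, ::-1].argmax(axis=1)
        span = (last - first).sum()
        d = (m.sum(axis=1) - 1).sum()
        ls, cs = np.unique(last + 1, return_counts=True)
        return cls(int(n), int(k), float(span), float(d), float(span - d),
                   tuple(zip(ls.tolist(), cs.tolist())))


def _loglik_stats(stats: _HistoryStats, phi: float, p: float) -> float:
    if stats.n == 0:
        return 0.0
    if not (0.0 < phi < 1.0 and 0.0 < p < 1.0):
        return -math.inf
    k = stats.k
    chi = [0.0] * (k + 1)
    chi[k] = 1.0
    q = phi * (1.0 - p)
    for t in range(k - 1, 0, -1):
        chi[t] = (1.0 - phi) + q * chi[t + 1]
    ll = (stats.T * math.log(phi) + stats.D * math.log(p)
          + stats.M * math.log(1.0 - p))
    for l, c in stats.last_pairs:
        ll += c * math.log(chi[l])
    return ll


def cjs_loglik(matrix, phi: float, p: float) -> float:
    """Conditional-on-first-capture CJS log-likelihood, constant (phi, p).

    ``matrix`` is a :class:`~stopover.banding.CaptureHistoryMatrix` or a
    binary ndarray.  Every row must contain at least one detection.
    """
    if not (0.0 < phi < 1.0 and 0.0 < p < 1.0):
        raise ValueError("phi and p must lie strictly in (0, 1)")
    m = matrix.matrix if isinstance(matrix, CaptureHistoryMatrix) else matrix
    return _loglik_stats(_HistoryStats.from_matrix(m), phi, p)


# ---------------------------------------------------------------------------
# diagnostics and transforms


def gelman_rubin(chains) -> float:
    """Classic potential-scale-reduction factor R-hat.

    For m chains of length n with within-chain variance W (mean of the
    per-chain sample variances) and between-chain variance B (n times the
    variance of the chain means):  Vhat = (n-1)/n * W + B/n and
    R-hat = sqrt(Vhat / W).
    """
    c = np.asarray(chains, float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = c.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful R-hat")
    W = c.var(axis=1, ddof=1).mean()
    B_over_n = c.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0
    vhat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(vhat / W))


def stopover_from_phi(phi):
    """Expected stopover duration -1/ln(phi) in days; monotone in phi."""
    arr = np.asarray(phi, float)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise ValueError("phi must lie strictly in (0, 1)")
    out = -1.0 / np.log(arr)
    return float(out) if np.isscalar(phi) else out


# ---------------------------------------------------------------------------
# model and results


def _log_normal_pdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd)


class HierarchicalCJSModel:
    """Year-stratified CJS model with shared logit-normal hyperpriors.

    Parameters
    ----------
    matrices : mapping or iterable
        Capture-history matrices for one species-season, keyed by (or
        carrying) their year.  Years with zero individuals contribute no
        likelihood; their parameters are drawn from the hyperdistribution.
    config : CJSConfig, optional
    """

    def __init__(self, matrices, config: CJSConfig | None = None):
        if isinstance(matrices, dict):
            items = sorted(matrices.items())
        else:
            items = sorted((m.year, m) for m in matrices)
        if len(items) < 2:
            raise ValueError("hierarchical model needs >= 2 years")
        self.years = [y for y, _ in items]
        self.matrices = [m for _, m in items]
        arrs = [m.matrix if isinstance(m, CaptureHistoryMatrix) else np.asarray(m)
                for m in self.matrices]
        self.stats = [_HistoryStats.from_matrix(a) for a in arrs]
        if all(s.n == 0 for s in self.stats):
            raise ValueError("no individuals in any year")
        self.config = config or CJSConfig()
        lab = next((m for m in self.matrices
                    if isinstance(m, CaptureHistoryMatrix)), None)
        self.species = lab.species if lab else None
        self.season = lab.season if lab else None

    # -- initial values ----------------------------------------------------
    def _moment_init(self) -> tuple[float, float]:
        """Pooled moment-style starting values for (phi, p).

        p from recaptures per occupied day after first capture, phi from
        the geometric relation between observed spans and cohort size.
        """
        T = sum(s.T for s in self.stats)
        D = sum(s.D for s in self.stats)
        N = sum(s.n for s in self.stats)
        p0 = D / T if T > 0 else 0.3
        phi0 = T / (T + N) if T + N > 0 else 0.5
        clip = lambda v: min(max(v, 0.05), 0.95)
        return clip(phi0), clip(p0)

    # -- sampler -----------------------------------------------------------
    def _run_chain(self, seed: np.random.SeedSequence,
                   store: dict[str, np.ndarray], chain_idx: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(seed)
        Y = len(self.years)
        phi0, p0 = self._moment_init()

        for attempt in range(10):
            lphi = np.full(Y, logit(phi0)) + (attempt > 0) * rng.normal(0, 0.3, Y)
            lp = np.full(Y, logit(p0)) + (attempt > 0) * rng.normal(0, 0.3, Y)
            ll = np.array([_loglik_stats(s, expit(lphi[y]), expit(lp[y]))
                           for y, s in enumerate(self.stats)])
            if np.isfinite(ll).all():
                break
        else:
            raise RuntimeError("could not initialize chain at finite likelihood")
        mu_phi, mu_p = float(lphi.mean()), float(lp.mean())
        sig_phi = sig_p = 0.5

        s_phi = np.full(Y, 0.3)
        s_p = np.full(Y, 0.3)
        s_sig = [0.3, 0.3]
        acc_phi = np.zeros(Y); acc_p = np.zeros(Y); acc_sig = [0.0, 0.0]
        window = 50

        prior_var = cfg.hyper_mean_prior_var
        keep = 0
        for it in range(cfg.iterations):
            # year-level random-walk updates
            for y in range(Y):
                prop = lphi[y] + rng.normal(0.0, s_phi[y])
                ll_new = _loglik_stats(self.stats[y], expit(prop), expit(lp[y]))
                delta = (ll_new - ll[y]
                         + _log_normal_pdf(prop, mu_phi, sig_phi)
                         - _log_normal_pdf(lphi[y], mu_phi, sig_phi))
                if math.log(rng.uniform()) < delta:
                    lphi[y] = prop; ll[y] = ll_new; acc_phi[y] += 1

                prop = lp[y] + rng.normal(0.0, s_p[y])
                ll_new = _loglik_stats(self.stats[y], expit(lphi[y]), expit(prop))
                delta = (ll_new - ll[y]
                         + _log_normal_pdf(prop, mu_p, sig_p)
                         - _log_normal_pdf(lp[y], mu_p, sig_p))
                if math.log(rng.uniform()) < delta:
                    lp[y] = prop; ll[y] = ll_new; acc_p[y] += 1

            # conjugate hyper-mean updates
            for mu_name in (0, 1):
                vals, sig = (lphi, sig_phi) if mu_name == 0 else (lp, sig_p)
                prec = Y / sig**2 + 1.0 / prior_var
                mean = vals.sum() / sig**2 / prec
                draw = rng.normal(mean, 1.0 / math.sqrt(prec))
                if mu_name == 0:
                    mu_phi = draw
                else:
                    mu_p = draw

            # random-walk updates of the random-effect SDs
            for si in (0, 1):
                vals, mu = (lphi, mu_phi) if si == 0 else (lp, mu_p)
                cur = sig_phi if si == 0 else sig_p
                prop = cur + rng.normal(0.0, s_sig[si])
                if 0.0 < prop < cfg.sigma_prior_upper:
                    delta = (sum(_log_normal_pdf(v, mu, prop) for v in vals)
                             - sum(_log_normal_pdf(v, mu, cur) for v in vals))
                    if math.log(rng.uniform()) < delta:
                        if si == 0:
                            sig_phi = prop
                        else:
                            sig_p = prop
                        acc_sig[si] += 1

            # proposal-scale adaptation, burn-in only
            if it < cfg.burn_in and (it + 1) % window == 0:
                s_phi *= np.exp((acc_phi / window - 0.44).clip(-1, 1) * 0.5)
                s_p *= np.exp((acc_p / window - 0.44).clip(-1, 1) * 0.5)
                for si in (0, 1):
                    s_sig[si] *= math.exp(
                        max(-1, min(1, acc_sig[si] / window - 0.44)) * 0.5)
                acc_phi[:] = 0; acc_p[:] = 0; acc_sig = [0.0, 0.0]

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                if keep < store["mu_phi"].shape[1]:
                    store["mu_phi"][chain_idx, keep] = mu_phi
                    store["sigma_phi"][chain_idx, keep] = sig_phi
                    store["mu_p"][chain_idx, keep] = mu_p
                    store["sigma_p"][chain_idx, keep] = sig_p
                    store["logit_phi"][chain_idx, keep] = lphi
                    store["logit_p"][chain_idx, keep] = lp
                    keep += 1

    def fit(self, seed=None, progress: bool = False) -> "CJSResults":
        """Run all chains and collect the posterior.

        seed feeds a SeedSequence; chains get independent child streams.
        """
        cfg = self.config
        Y = len(self.years)
        nd = cfg.retained_per_chain
        store = {
            "mu_phi": np.empty((cfg.chains, nd)),
            "sigma_phi": np.empty((cfg.chains, nd)),
            "mu_p": np.empty((cfg.chains, nd)),
            "sigma_p": np.empty((cfg.chains, nd)),
            "logit_phi": np.empty((cfg.chains, nd, Y)),
            "logit_p": np.empty((cfg.chains, nd, Y)),
        }
        root = (seed if isinstance(seed, np.random.SeedSequence)
                else np.random.SeedSequence(seed))
        seeds = root.spawn(cfg.chains)
        for c, ss in enumerate(seeds):
            self._run_chain(ss, store, c)
            if progress:  # pragma: no cover
                print(f"chain {c + 1}/{cfg.chains} done")
        return CJSResults(self, store)


class CJSResults:
    """Posterior draws, convergence diagnostics, and stopover summaries."""

    def __init__(self, model: HierarchicalCJSModel, draws: dict[str, np.ndarray]):
        self.model = model
        self.draws = draws
        self.years = model.years
        self.config = model.config

    # -- draw access -------------------------------------------------------
    def parameter_names(self) -> list[str]:
        names = ["mu_phi", "sigma_phi", "mu_p", "sigma_p"]
        names += [f"logit_phi[{y}]" for y in self.years]
        names += [f"logit_p[{y}]" for y in self.years]
        return names

    def chains(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, draws_per_chain)."""
        if name in self.draws:
            return self.draws[name]
        base, _, rest = name.partition("[")
        year = int(rest.rstrip("]"))
        return self.draws[base][:, :, self.years.index(year)]

    def flat(self, name: str) -> np.ndarray:
        return self.chains(name).reshape(-1)

    def phi_draws(self, year: int) -> np.ndarray:
        return expit(self.flat(f"logit_phi[{year}]"))

    def p_draws(self, year: int) -> np.ndarray:
        return expit(self.flat(f"logit_p[{year}]"))

    def posterior_mean(self, name: str, transform=None) -> float:
        x = self.flat(name)
        return float((transform(x) if transform else x).mean())

    # -- diagnostics -------------------------------------------------------
    def rhat(self) -> dict[str, float]:
        return {n: gelman_rubin(self.chains(n)) for n in self.parameter_names()}

    def ess(self) -> dict[str, float]:
        """Bulk effective sample sizes (via arviz)."""
        import arviz as az

        ds = az.convert_to_dataset({n.replace("[", "_").replace("]", ""):
                                    self.chains(n)
                                    for n in self.parameter_names()})
        e = az.ess(ds)
        return {n: float(e[n.replace("[", "_").replace("]", "")].values)
                for n in self.parameter_names()}

    def converged(self) -> bool:
        return max(self.rhat().values()) < self.config.rhat_threshold

    def diagnostics(self) -> pd.DataFrame:
        rh, es = self.rhat(), self.ess()
        return pd.DataFrame({"parameter": list(rh), "rhat": list(rh.values()),
                             "ess": [es[n] for n in rh]})

    # -- stopover summaries ------------------------------------------------
    def annual_stopover(self, level: float = 0.95) -> pd.DataFrame:
        """Per-year posterior median and central interval of -1/ln(phi_y).

        Because the transform is monotone, the median of transformed draws
        equals the transform of the median phi draw.
        """
        a = (1.0 - level) / 2.0
        rows = []
        for y in self.years:
            s = stopover_from_phi(self.phi_draws(y))
            lo, med, hi = np.quantile(s, [a, 0.5, 1.0 - a])
            rows.append({"year": y, "S_median": med, "lo": lo, "hi": hi,
                         "phi_median": float(np.median(self.phi_draws(y)))})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, draw, parameter, value."""
        frames = []
        for n in self.parameter_names():
            c = self.chains(n)
            m, nd = c.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(m), nd),
                "draw": np.tile(np.arange(nd), m),
                "parameter": n, "value": c.reshape(-1)}))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        rh = self.rhat()
        pooled_phi = self.posterior_mean("mu_phi", expit)
        pooled_p = self.posterior_mean("mu_p", expit)
        lab = " ".join(s for s in (self.model.species, self.model.season) if s)
        head = f"Hierarchical CJS{' — ' + lab if lab else ''}"
        lines = [head, "=" * len(head),
                 f"years: {self.years[0]}–{self.years[-1]} "
                 f"({len(self.years)}), individuals: "
                 f"{sum(s.n for s in self.model.stats)}",
                 f"chains: {self.config.chains}, retained draws/chain: "
                 f"{self.config.retained_per_chain}",
                 f"pooled phi (inv-logit mu_phi): {pooled_phi:.3f}   "
                 f"pooled p: {pooled_p:.3f}",
                 f"pooled stopover -1/ln(phi): "
                 f"{stopover_from_phi(pooled_phi):.2f} days",
                 f"max R-hat: {max(rh.values()):.4f} "
                 f"({'<' if self.converged() else '>='} "
                 f"{self.config.rhat_threshold})"]
        return "\n".join(lines)


def fit_hierarchical_cjs(matrices, config: CJSConfig | None = None,
                         seed=None) -> CJSResults:
    """Functional wrapper: build the model and sample the posterior."""
    return HierarchicalCJSModel(matrices, config).fit(seed=seed)
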