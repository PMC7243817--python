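"""Shared fixtures and independent oracles.

The oracles here deliberately use brute force — pairwise-line
enumeration for quantile regression, exhaustive summation over latent
departure days for the CJS likelihood — so they stay independent of the
code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


def qr_enumeration_minimum(x: np.ndarray, y: np.ndarray, tau: float) -> float:
    """Minimum check loss over all lines through pairs of sample points.

    An optimal two-parameter quantile-regression line can always be taken
    to pass through at least two observations, so enumerating all pairs
    (plus horizontal lines through single points, covering the degenerate
    tied-x case) yields the exact global minimum.
    """
    best = np.inf
    n = len(y)
    for i in range(n):
        # horizontal line through point i
        u = y - y[i]
        best = min(best, float(np.sum(u * (tau - (u < 0)))))
        for j in range(i + 1, n):
            if x[j] == x[i]:
                continue
            b = (y[j] - y[i]) / (x[j] - x[i])
            a = y[i] - b * x[i]
            u = y - a - b * x
            best = min(best, float(np.sum(u * (tau - (u < 0)))))
    return best


def cjs_single_history_bruteforce(history: np.ndarray, phi: float,
                                  p: float) -> float:
    """CJS likelihood of one capture history by enumerating departure days.

    Sums over the latent last-present occasion d: present from the first
    capture f through d (prob phi^(d-f) * (1-phi), or phi^(k-f) when the
    bird outlasts the season), with independent Bernoulli(p) detection on
    each present day after f matching the observed history.
    """
    h = np.asarray(history, int)
    k = len(h)
    f = int(np.argmax(h))
    lik = 0.0
    # D = last occasion present (0-based); D = k-1 merges "departed after
    # the last occasion" with "outlasted the season": P(D >= k-1) = phi^(k-1-f)
    for D in range(f, k):
        stay_prob = (phi ** (D - f) * (1.0 - phi) if D < k - 1
                     else phi ** (k - 1 - f))
        if np.any(h[D + 1:]):  # detected after presumed departure
            continue
        det = 1.0
        for t in range(f + 1, D + 1):
            det *= p if h[t] else (1.0 - p)
        lik += stay_prob * det
    return lik


def all_continuation_histories(k: int, f: int):
    """All binary histories of length k with first capture at occasion f."""
    for tail in itertools.product((0, 1), repeat=k - f - 1):
        h = np.zeros(k, dtype=int)
        h[f] = 1
        h[f + 1:] = tail
        yield h


@pytest.fixture(scope="session")
def small_synthetic():
    """A small simulated banding dataset shared across tests."""
    import stopover as so

    ap = so.ArrivalTrendParams((10, 20, 30), (0.0, 0.5, 1.0), n_years=10,
                               cohort_size=250, season_length_k=so.SPRING.k)
    sp = so.StopoverDetectParams(phi_mean=0.6, p_mean=0.4)
    records, truth = so.simulate_banding_dataset(ap, sp, seed=20260930)
    return records, truth
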