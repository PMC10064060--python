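"""Bayesian population prevalence of within-subject effects.

Given k of n subjects significant at a first-level false-positive rate
alpha, the probability that a single subject shows a significant result is
theta = alpha + (1 - alpha) * gamma, where gamma is the population
prevalence of the effect (first-level sensitivity is taken as 1 for
subjects who truly carry the effect).  With a uniform prior on gamma the
posterior density is proportional to theta^k (1 - theta)^(n - k) on
gamma in [0, 1]; its mode has the closed form
max(0, (k/n - alpha) / (1 - alpha)), and highest-posterior-density
intervals are computed numerically by a water-level search (the density can
be monotone, e.g. at k = n, so equal-tail logic would be wrong).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, simpson
from scipy.optimize import brentq

from .stats import first_level_ttests

__all__ = [
    "PrevalencePosterior",
    "prevalence_map",
    "prevalence_hpdi",
    "prevalence_from_cohort",
]

_GRID_N = 100_001


def _check(k: int, n: int, alpha: float):
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")


def prevalence_map(k: int, n: int, alpha: float) -> float:
    """Posterior mode of the prevalence: max(0, (k/n - alpha)/(1 - alpha))."""
    _check(k, n, alpha)
    return max(0.0, (k / n - alpha) / (1.0 - alpha))


@dataclass(frozen=True)
class PrevalencePosterior:
    """Posterior over the population prevalence gamma."""

    k: int
    n: int
    alpha: float

    def __post_init__(self):
        _check(self.k, self.n, self.alpha)

    def log_density_unnorm(self, gamma):
        g = np.asarray(gamma, dtype=float)
        theta = self.alpha + (1.0 - self.alpha) * g
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.zeros_like(theta)
            if self.k > 0:
                ll = ll + self.k * np.log(theta)
            if self.n - self.k > 0:
                ll = ll + (self.n - self.k) * np.log1p(-theta)
        return np.where((g < 0) | (g > 1), -np.inf, ll)

    def density(self, gamma):
        """Normalized posterior density on [0, 1] (numerical normalization)."""
        grid = np.linspace(0.0, 1.0, _GRID_N)
        f = np.exp(self.log_density_unnorm(grid) - self.log_density_unnorm(grid).max())
        z = simpson(f, x=grid)
        g = np.asarray(gamma, dtype=float)
        out = np.exp(
            self.log_density_unnorm(g) - self.log_density_unnorm(grid).max()
        ) / z
        return out

    @property
    def map(self) -> float:
        return prevalence_map(self.k, self.n, self.alpha)

    def hpdi(self, mass: float = 0.96):
        return prevalence_hpdi(self.k, self.n, self.alpha, mass)

    def to_dict(self, masses=(0.5, 0.96)) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "alpha": self.alpha,
            "map": self.map,
            "hpdi": {str(m): list(self.hpdi(m)) for m in masses},
        }


def prevalence_hpdi(k: int, n: int, alpha: float, mass: float = 0.96):
    """Smallest interval holding ``mass`` of the prevalence posterior.

    Water-level search: for a level c, the super-level region
    {gamma : f(gamma) >= c} of this unimodal-or-monotone density is an
    interval whose endpoints are found by bracketing on a grid and
    polishing with Brent root-finding; the level itself is solved so the
    interval holds exactly the requested mass (adaptive quadrature, so the
    endpoints are accurate well beyond the bracketing grid).  Degenerate
    request mass >= 1 returns [0, 1] with a warning.
    """
    _check(k, n, alpha)
    if not (0 < mass):
        raise ValueError("mass must be positive")
    if mass >= 1:
        warnings.warn("HPDI mass >= 1 is degenerate; returning [0, 1]")
        return (0.0, 1.0)

    post = PrevalencePosterior(k, n, alpha)
    grid = np.linspace(0.0, 1.0, 20_001)
    logf = post.log_density_unnorm(grid)
    shift = logf.max()
    fg = np.exp(logf - shift)

    def dens(g):
        return float(np.exp(post.log_density_unnorm(g) - shift))

    total = quad(dens, 0.0, 1.0, limit=200)[0]
    imax = int(np.argmax(fg))

    def endpoints(c):
        if fg[0] >= c:
            lo = 0.0
        else:  # fg is increasing on [0, imax]
            j = int(np.searchsorted(fg[: imax + 1], c))
            lo = brentq(lambda g: dens(g) - c, grid[j - 1], grid[j], xtol=1e-14)
        if fg[-1] >= c:
            hi = 1.0
        else:  # fg is decreasing on [imax, end]
            tail = fg[imax:]
            jj = tail.size - int(np.searchsorted(tail[::-1], c))
            hi = brentq(
                lambda g: dens(g) - c, grid[imax + jj - 1], grid[imax + jj], xtol=1e-14
            )
        return lo, hi

    def mass_at(c):
        lo, hi = endpoints(c)
        if hi <= lo:
            return 0.0
        return quad(dens, lo, hi, limit=200)[0] / total

    c_star = brentq(
        lambda c: mass_at(c) - mass,
        0.0,
        float(fg.max()) * (1.0 - 1e-12),
        xtol=1e-13,
        rtol=1e-12,
    )
    lo, hi = endpoints(c_star)
    return (float(lo), float(hi))


def prevalence_from_cohort(
    trials,
    pair,
    alpha: float = 0.05,
    variable: str = "rt_ms",
) -> tuple:
    """Prevalence posterior from trial-level first-level tests.

    Runs the per-subject Welch test between the two conditions, counts
    significant subjects, and returns ``(posterior, decisions)`` where
    ``decisions`` is the per-subject first-level table.
    """
    decisions = first_level_ttests(trials, pair, alpha=alpha, variable=variable)
    if decisions.empty:
        raise ValueError("no subjects in trial table")
    k = int(decisions["significant"].sum())
    n = int(len(decisions))
    return PrevalencePosterior(k=k, n=n, alpha=alpha), decisions
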