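"""Synthetic grouped samples with known ground truth.

Every calibration, recovery and coverage test in the suite draws from here:
a named continuous distribution is sampled, the draws are binned on a given
grid with the same left-closed convention the data model uses, and the
truth handle exposes the exact density, distribution and index values so
estimates can be checked against them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.stats import logistic, norm, weibull_min

from .grouped_data import GroupedSample

__all__ = ["TruthSpec", "Truth", "simulate_grouped", "truth_indices"]

_SQRT_PI = np.sqrt(np.pi)


@dataclass(frozen=True)
class TruthSpec:
    """Recipe for a synthetic grouped sample.

    ``edges`` may be an explicit grid or a ``(k, (lo, hi))`` pair for k
    equal bins.  ``family`` is one of normal, weibull, logistic,
    normal_mixture (params: weights, means, sds).
    """

    family: str
    params: dict
    n: int
    edges: object
    seed: int = 0

    def grid(self) -> np.ndarray:
        if isinstance(self.edges, tuple) and len(self.edges) == 2 and np.isscalar(self.edges[0]):
            k, (lo, hi) = self.edges
            if k < 2:
                raise ValueError("need at least 2 bins")
            return np.linspace(lo, hi, int(k) + 1)
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 3:
            raise ValueError("need at least 2 bins")
        return e


class Truth:
    """Exact density/distribution/moments of a TruthSpec's family."""

    def __init__(self, spec: TruthSpec):
        self.spec = spec
        p = spec.params
        fam = spec.family
        if fam == "normal":
            self._dist = norm(loc=p["mean"], scale=p["sd"])
        elif fam == "weibull":
            self._dist = weibull_min(p["shape"], scale=p["scale"])
        elif fam == "logistic":
            self._dist = logistic(loc=p["location"], scale=p["scale"])
        elif fam == "normal_mixture":
            self._dist = None
            self._w = np.asarray(p["weights"], float)
            self._m = np.asarray(p["means"], float)
            self._s = np.asarray(p["sds"], float)
            if not np.isclose(self._w.sum(), 1.0):
                raise ValueError("mixture weights must sum to 1")
        else:
            raise ValueError(f"unknown family {fam!r}")

    def pdf(self, x):
        if self._dist is not None:
            return self._dist.pdf(x)
        x = np.asarray(x, float)
        return np.sum(self._w * norm.pdf(x[..., None], self._m, self._s), axis=-1)

    def cdf(self, x):
        if self._dist is not None:
            return self._dist.cdf(x)
        x = np.asarray(x, float)
        return np.sum(self._w * norm.cdf(x[..., None], self._m, self._s), axis=-1)

    def rvs(self, n, rng):
        if self._dist is not None:
            return self._dist.rvs(size=n, random_state=rng)
        comp = rng.choice(len(self._w), size=n, p=self._w)
        return rng.normal(self._m[comp], self._s[comp])

    def moments(self):
        if self._dist is not None:
            mean, var = self._dist.stats(moments="mv")
            mu = float(mean)
            m4 = quad(lambda x: (x - mu) ** 4 * self.pdf(x), *self._support())[0]
            return mu, float(var), float(m4)
        mu = float(self._w @ self._m)
        var = float(self._w @ (self._s**2 + self._m**2) - mu**2)
        m4 = quad(lambda x: (x - mu) ** 4 * self.pdf(x), *self._support())[0]
        return mu, var, float(m4)

    def _support(self):
        if self.spec.family == "weibull":
            p = self.spec.params
            return 0.0, float(weibull_min(p["shape"], scale=p["scale"]).ppf(1.0 - 1e-12))
        lo = float(self.ppf(1e-12))
        hi = float(self.ppf(1.0 - 1e-12))
        return lo, hi

    def ppf(self, q):
        if self._dist is not None:
            return self._dist.ppf(q)
        from scipy.optimize import brentq

        lo = float(np.min(self._m - 12 * self._s))
        hi = float(np.max(self._m + 12 * self._s))
        return brentq(lambda x: self.cdf(x) - q, lo, hi)


def simulate_grouped(spec: TruthSpec) -> tuple[GroupedSample, Truth]:
    """Draw n values, bin them left-closed on the grid, return sample + truth.

    Draws outside the grid are clipped into the end bins; if more than 1% of
    the mass needed clipping that is an error (the grid should cover the
    support), below that a warning.
    """
    truth = Truth(spec)
    edges = spec.grid()
    rng = np.random.default_rng(spec.seed)
    x = truth.rvs(spec.n, rng)
    n_out = int(np.sum((x < edges[0]) | (x >= edges[-1])))
    if n_out > 0.01 * spec.n:
        raise ValueError(f"{n_out}/{spec.n} draws outside the grid; widen the edges")
    if n_out:
        warnings.warn(f"clipped {n_out} draws into the end bins")
    x = np.clip(x, edges[0], np.nextafter(edges[-1], -np.inf))
    idx = np.searchsorted(edges, x, side="right") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1)
    gs = GroupedSample(edges=edges, counts=counts, label=f"{spec.family} n={spec.n}")
    return gs, truth


def truth_indices(spec: TruthSpec) -> tuple[float, float, float, float]:
    """Exact (I1, I2, J1, J2) of the generating distribution.

    Normal families use closed forms (J1 = 1/(4 sqrt(pi)),
    J2 = 3/(8 sqrt(pi)), I2 = 3); other families use adaptive quadrature on
    the analytic derivative of the density.
    """
    truth = Truth(spec)
    if spec.family == "weibull" and spec.params["shape"] <= 0.5:
        raise ValueError("int f'(x)^2 diverges for weibull shape <= 1/2")
    mu, var, m4 = truth.moments()
    sd = np.sqrt(var)
    i1, i2 = sd / mu, m4 / var**2
    if spec.family == "normal":
        return float(i1), 3.0, 1.0 / (4.0 * _SQRT_PI), 3.0 / (8.0 * _SQRT_PI)
    if spec.family == "normal_mixture":
        from .indices import _mixture_psi

        rf1 = -_mixture_psi(truth._w, truth._m, truth._s, 2)
        rf2 = _mixture_psi(truth._w, truth._m, truth._s, 4)
        return float(i1), float(i2), float(sd**3 * rf1), float(sd**5 * rf2)
    lo, hi = truth._support()
    eps = 1e-5 * sd

    def dpdf(x):
        return (truth.pdf(x + eps) - truth.pdf(x - eps)) / (2 * eps)

    def d2pdf(x):
        return (truth.pdf(x + eps) - 2 * truth.pdf(x) + truth.pdf(x - eps)) / eps**2

    rf1 = quad(lambda x: dpdf(x) ** 2, lo, hi, limit=400)[0]
    rf2 = quad(lambda x: d2pdf(x) ** 2, lo, hi, limit=400)[0]
    return float(i1), float(i2), float(sd**3 * rf1), float(sd**5 * rf2)
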