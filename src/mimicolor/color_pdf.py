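"""Bivariate probability density functions for intraspecific flower colour.

A species' colour cloud in the hexagon plane is modelled by two univariate
marginal distributions (one per coordinate) joined by a copula:

.. math:: f(x, y) = f_X(x)\\, f_Y(y)\\, c\\big(F_X(x), F_Y(y)\\big)

Marginals may be normal (mean/std), gamma (shape/rate) or Weibull
(shape/scale); the copula families live in :mod:`mimicolor.copulas`.  High
joint density identifies "typical" colours of a species; the tails hold
less frequent and rare colour variants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .copulas import CopulaModel, fit_copula

__all__ = [
    "MarginalModel",
    "BivariatePDF",
    "fit_marginal",
    "ad_gof_test",
    "CopulaModel",
    "fit_copula",
]

_CLIP = 1e-12  # CDF clipping bound before copula evaluation


@dataclass(frozen=True)
class MarginalModel:
    """A univariate marginal: ``normal`` (mean, std), ``gamma``
    (shape, rate) or ``weibull`` (shape, scale)."""

    family: str
    params: tuple[float, float]
    se: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "gamma", "weibull"):
            raise ValueError(f"unknown marginal family {self.family!r}")
        a, b = self.params
        if self.family == "normal":
            if b <= 0:
                raise ValueError("normal std must be positive")
        elif a <= 0 or b <= 0:
            raise ValueError(f"{self.family} parameters must be positive")

    @property
    def _dist(self):
        a, b = self.params
        if self.family == "normal":
            return stats.norm(loc=a, scale=b)
        if self.family == "gamma":
            return stats.gamma(a=a, scale=1.0 / b)  # shape / rate
        return stats.weibull_min(c=a, scale=b)      # shape / scale

    def pdf(self, x):
        return self._dist.pdf(x)

    def cdf(self, x):
        return self._dist.cdf(x)

    def ppf(self, q):
        return self._dist.ppf(q)

    def sample(self, n: int, rng) -> np.ndarray:
        return self._dist.rvs(size=n, random_state=rng)

    @property
    def mean(self) -> float:
        return float(self._dist.mean())

    @property
    def std(self) -> float:
        return float(self._dist.std())

    def to_dict(self) -> dict:
        out = {"family": self.family, "params": list(self.params)}
        if self.se is not None:
            out["se"] = list(self.se)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalModel":
        return cls(
            family=d["family"],
            params=tuple(float(p) for p in d["params"]),
            se=tuple(d["se"]) if d.get("se") else None,
        )


def fit_marginal(samples, family: str) -> MarginalModel:
    """Maximum-likelihood fit of a marginal family, with asymptotic
    standard errors from the observed information matrix.

    Normal uses the closed-form ML solution (1/n variance); gamma and
    Weibull use numeric ML with the location fixed at zero and require
    strictly positive data.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValueError("marginal fitting needs at least 5 samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    if family == "normal":
        mu = float(np.mean(x))
        sd = float(np.std(x))  # ML (1/n) estimator
        se = (sd / math.sqrt(x.size), sd / math.sqrt(2.0 * x.size))
        return MarginalModel("normal", (mu, sd), se=se)
    if np.any(x <= 0):
        raise ValueError(f"{family} requires strictly positive samples")
    if family == "gamma":
        shape, _, scale = stats.gamma.fit(x, floc=0.0)
        params = (float(shape), float(1.0 / scale))
    elif family == "weibull":
        shape, _, scale = stats.weibull_min.fit(x, floc=0.0)
        params = (float(shape), float(scale))
    else:
        raise ValueError(f"unknown marginal family {family!r}")
    se = _marginal_se(x, family, params)
    return MarginalModel(family, params, se=se)


def _marginal_se(x, family, params, eps=1e-5):
    def nll(p):
        try:
            m = MarginalModel(family, (p[0], p[1]))
        except ValueError:
            return 1e12
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(m.pdf(x), 1e-300))
        return -float(np.sum(lp))

    p = np.asarray(params, dtype=float)
    H = np.empty((2, 2))
    steps = eps * np.maximum(np.abs(p), 1.0)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = steps[i]
            ej = np.zeros(2); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                nll(p + ei + ej) - nll(p + ei - ej) - nll(p - ei + ej) + nll(p - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    try:
        cov = np.linalg.inv(H)
        return tuple(float(s) for s in np.sqrt(np.maximum(np.diag(cov), 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        return None


# ---------------------------------------------------------------------------
# Anderson-Darling goodness of fit (fully specified null)
# ---------------------------------------------------------------------------

def _ad_inf(z: float) -> float:
    """Asymptotic CDF of the A-squared statistic (Marsaglia & Marsaglia 2004)."""
    if z < 2.0:
        return (
            math.exp(-1.2337141 / z)
            / math.sqrt(z)
            * (2.00012 + (0.247105 - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * z) * z) * z) * z) * z)
        )
    return math.exp(
        -math.exp(1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z) * z) * z) * z) * z)
    )


def _ad_errfix(n: int, x: float) -> float:
    """Finite-n correction to the asymptotic AD CDF (same source)."""
    if x > 0.8:
        return (-130.2137 + (745.2337 - (1705.091 - (1950.646 - (1116.360 - 255.7844 * x) * x) * x) * x) * x) / n
    c = 0.01265 + 0.1757 / n
    if x < c:
        t = x / c
        t = math.sqrt(t) * (1.0 - t) * (49.0 * t - 102.0)
        return t * (0.0037 / n**3 + 0.00078 / n**2 + 0.00006 / n) / n
    t = (x - c) / (0.8 - c)
    t = -0.00022633 + (6.54034 - (14.6538 - (14.458 - (8.259 - 1.91864 * t) * t) * t) * t) * t
    return t * (0.04213 + 0.01365 / n) / n


def ad_gof_test(samples, marginal: MarginalModel) -> tuple[float, float]:
    """Anderson-Darling test of ``samples`` against a fully specified
    fitted marginal; returns (A-squared, p-value)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    z = np.clip(marginal.cdf(x), _CLIP, 1.0 - _CLIP)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2.0 * i - 1.0) * (np.log(z) + np.log1p(-z[::-1])))
    cdf = _ad_inf(float(a2))
    cdf = min(max(cdf + _ad_errfix(n, cdf), 0.0), 1.0)
    return float(a2), float(1.0 - cdf)


# ---------------------------------------------------------------------------
# Joint model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BivariatePDF:
    """Two marginals plus a copula: the colour PDF of one flower region."""

    margin_x: MarginalModel
    margin_y: MarginalModel
    copula: CopulaModel

    def density(self, x, y):
        """Joint density ``d = f_x(x) f_y(y) c(F_x(x), F_y(y))``.

        Points outside a marginal's support return 0.  CDF values are
        clipped to ``[1e-12, 1 - 1e-12]`` before the copula evaluation to
        avoid log(0) in extreme tails.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        fx = self.margin_x.pdf(x)
        fy = self.margin_y.pdf(y)
        u = np.clip(self.margin_x.cdf(x), _CLIP, 1.0 - _CLIP)
        v = np.clip(self.margin_y.cdf(y), _CLIP, 1.0 - _CLIP)
        out = fx * fy * self.copula.density(u, v)
        out = np.where(np.isfinite(out), out, 0.0)
        return float(out) if np.ndim(x) == 0 and np.ndim(y) == 0 else out

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` loci: copula pairs by conditional inversion, then the
        marginal quantile transforms.  Returns an (n, 2) array."""
        uv = self.copula.sample(n, seed=seed)
        if n == 0:
            return uv
        x = self.margin_x.ppf(np.clip(uv[:, 0], _CLIP, 1.0 - _CLIP))
        y = self.margin_y.ppf(np.clip(uv[:, 1], _CLIP, 1.0 - _CLIP))
        return np.column_stack([x, y])

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "margin_x": self.margin_x.to_dict(),
            "margin_y": self.margin_y.to_dict(),
            "copula": self.copula.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BivariatePDF":
        return cls(
            margin_x=MarginalModel.from_dict(d["margin_x"]),
            margin_y=MarginalModel.from_dict(d["margin_y"]),
            copula=CopulaModel.from_dict(d["copula"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BivariatePDF":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
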