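"""Sampling-distribution specifications and moment-matching constructors.

Uncertain parameters carry one of four families: Beta for probabilities and
utilities, Gamma for costs, LogNormal for hazard ratios (parameterised from a
printed 95% CI), and Fixed for quantities excluded from uncertainty analysis.
Beta and Gamma are constructed by method of moments from (mean, SE), the
standard practice in health-technology-assessment models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "lognormal_from_ci",
]

_Z95 = 1.959964  # two-sided 95% normal quantile


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the given mean and standard error.

    Method of moments: ``nu = m(1-m)/se^2 - 1``, ``alpha = m*nu``,
    ``beta = (1-m)*nu``. Requires ``0 < mean < 1`` and
    ``se^2 < mean*(1-mean)`` (the Bernoulli variance bound).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"Beta mean must lie in (0, 1), got {mean}")
    if se <= 0.0:
        raise ValueError(f"Beta SE must be positive, got {se}")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"SE {se} too large for a Beta with mean {mean}: "
            f"variance must be below mean*(1-mean) = {mean * (1 - mean):.6g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Gamma(shape, scale) with the given mean and standard error.

    Method of moments: ``shape = (mean/se)^2``, ``scale = se^2/mean``.
    """
    if mean <= 0.0:
        raise ValueError(f"Gamma mean must be positive, got {mean}")
    if se <= 0.0:
        raise ValueError(f"Gamma SE must be positive, got {se}")
    return (mean / se) ** 2, se * se / mean


def lognormal_from_ci(point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """LogNormal(mu, sigma) from a point estimate and its 95% CI.

    ``mu = ln(point)``; ``sigma`` is the log-scale CI width divided by two
    95% normal quantiles. A degenerate CI (low = high) yields sigma 0.
    """
    if ci_low <= 0.0 or ci_high <= 0.0 or point <= 0.0:
        raise ValueError("LogNormal point estimate and CI bounds must be positive")
    if not ci_low <= point <= ci_high:
        raise ValueError(
            f"point {point} must lie inside the CI [{ci_low}, {ci_high}]"
        )
    sigma = (math.log(ci_high) - math.log(ci_low)) / (2.0 * _Z95)
    return math.log(point), sigma


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one model parameter.

    ``family`` is one of ``"beta"``, ``"gamma"``, ``"lognormal"``,
    ``"fixed"``. Beta/Gamma take (mean, se); LogNormal takes the point
    estimate as ``mean`` plus ``ci_low``/``ci_high``.
    """

    family: str
    mean: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "lognormal", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma"):
            if self.se is None:
                raise ValueError(f"{self.family} spec requires a standard error")
            # constructor validates ranges eagerly
            self._params()
        elif self.family == "lognormal":
            if self.ci_low is None or self.ci_high is None:
                raise ValueError("lognormal spec requires ci_low and ci_high")
            self._params()

    def _params(self) -> tuple[float, float]:
        if self.family == "beta":
            return beta_from_mean_se(self.mean, self.se)
        if self.family == "gamma":
            return gamma_from_mean_se(self.mean, self.se)
        if self.family == "lognormal":
            return lognormal_from_ci(self.mean, self.ci_low, self.ci_high)
        raise ValueError("fixed spec has no distribution parameters")

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value (the mean itself for a fixed spec)."""
        if self.family == "fixed":
            return self.mean
        a, b = self._params()
        if self.family == "beta":
            return float(rng.beta(a, b))
        if self.family == "gamma":
            return float(rng.gamma(a, b))
        return float(math.exp(rng.normal(a, b)))

    def percentile(self, q: float) -> float:
        """Quantile of the spec's distribution, used for one-way DSA bounds.

        For a lognormal spec the printed CI bounds are returned at the 2.5th
        and 97.5th percentiles (they are the published interval).
        """
        if self.family == "fixed":
            return self.mean
        if self.family == "lognormal":
            if q <= 0.025:
                return self.ci_low
            if q >= 0.975:
                return self.ci_high
            mu, sigma = self._params()
            return float(math.exp(stats.norm.ppf(q, mu, sigma)))
        a, b = self._params()
        dist = stats.beta(a, b) if self.family == "beta" else stats.gamma(a, scale=b)
        return float(dist.ppf(q))

    def to_dict(self) -> dict:
        d = {"family": self.family, "mean": self.mean}
        if self.se is not None:
            d["se"] = self.se
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low
            d["ci_high"] = self.ci_high
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(
            family=d["family"],
            mean=d["mean"],
            se=d.get("se"),
            ci_low=d.get("ci_low"),
            ci_high=d.get("ci_high"),
        )
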