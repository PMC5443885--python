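"""Clinical-trial sample-size estimation from atrophy rates.

Per-arm sample size for detecting a proportional reduction in the mean
annualised atrophy rate with a two-arm comparison:

    n = (u + v)^2 * (sigma1^2 + sigma2^2) / (mu1 - mu2)^2

with u the normal quantile for power (0.84 at 80%), v for the two-sided
significance level (1.96 at 5%), equal arm SDs assumed (sigma1 = sigma2 =
placebo SD) and mu1 - mu2 = reduction * mu.  Bootstrap CIs resample subjects'
annualised rates and recompute n per replicate (percentile interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the per-arm sample-size formula.

    ``u``/``v`` default to the printed-precision quantiles (0.84, 1.96);
    set ``high_precision=True`` for 0.8416/1.9600.
    """

    mu: float
    sigma: float
    reduction: float = 0.25
    power: float = 0.80
    alpha: float = 0.05
    u: float = 0.84
    v: float = 1.96
    high_precision: bool = False

    def __post_init__(self) -> None:
        if self.mu == 0:
            raise ValueError("mu must be nonzero (infinite sample size)")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.reduction <= 1:
            raise ValueError("reduction must lie in (0, 1]")
        if self.high_precision:
            object.__setattr__(self, "u", 0.8416)
            object.__setattr__(self, "v", 1.9600)


@dataclass(frozen=True)
class SampleSizeResult:
    n_per_arm: int
    n_raw: float
    ci_low: int | None = None
    ci_high: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_arm != math.ceil(self.n_raw) or self.n_per_arm < 1:
            raise ValueError("n_per_arm must be the ceiling of n_raw and >= 1")


def sample_size_per_arm(spec: PowerSpec) -> SampleSizeResult:
    """Per-arm n = (u + v)^2 * 2 sigma^2 / (reduction * mu)^2, rounded up."""
    effect = spec.reduction * spec.mu
    n_raw = (spec.u + spec.v) ** 2 * 2.0 * spec.sigma ** 2 / effect ** 2
    return SampleSizeResult(n_per_arm=math.ceil(n_raw), n_raw=n_raw)


def _n_from_rates(rates: np.ndarray, spec: PowerSpec) -> float | None:
    mu = float(rates.mean())
    sigma = float(rates.std(ddof=1))
    if mu == 0 or sigma == 0:
        return None
    s = replace(spec, mu=mu, sigma=sigma)
    return sample_size_per_arm(s).n_raw


def bootstrap_sample_size_ci(rates, spec: PowerSpec, n_boot: int = 2000,
                             seed: int = 0) -> SampleSizeResult:
    """Sample size from observed per-subject rates with a bootstrap 95% CI.

    Resamples subjects with replacement, recomputes (mu, sigma, n) per
    replicate and takes the 2.5/97.5 percentiles of the replicate n.
    Degenerate replicates (mu = 0) are dropped; more than 10% dropped is an
    error.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 10:
        raise ValueError("at least 10 per-subject rates are required")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    point = _n_from_rates(rates, spec)
    if point is None:
        raise ValueError("degenerate rates: zero mean or zero SD")
    rng = np.random.default_rng(seed)
    reps = []
    dropped = 0
    for _ in range(n_boot):
        n = _n_from_rates(rng.choice(rates, size=rates.size, replace=True), spec)
        if n is None:
            dropped += 1
        else:
            reps.append(n)
    if dropped > 0.1 * n_boot:
        raise RuntimeError(f"{dropped}/{n_boot} degenerate bootstrap replicates")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return SampleSizeResult(n_per_arm=math.ceil(point), n_raw=point,
                            ci_low=math.ceil(lo), ci_high=math.ceil(hi))


def compare_protocol_sample_sizes(rates_a, rates_na, spec: PowerSpec,
                                  n_boot: int = 2000, seed: int = 0):
    """Paired comparison of sample sizes from accelerated vs non-accelerated rates.

    Rates must be matched per subject (equal length, same order); the paired
    bootstrap resamples subjects jointly.  Returns
    ``(n_a, n_na, difference, (ci_lo, ci_hi))`` with difference =
    non-accelerated − accelerated in whole subjects per arm.
    """
    ra = np.asarray(rates_a, dtype=float)
    rn = np.asarray(rates_na, dtype=float)
    if ra.shape != rn.shape:
        raise ValueError("rate vectors must be matched per subject")
    na_raw = _n_from_rates(ra, spec)
    nn_raw = _n_from_rates(rn, spec)
    if na_raw is None or nn_raw is None:
        raise ValueError("degenerate rates")
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, ra.size, size=ra.size)
        da = _n_from_rates(ra[idx], spec)
        dn = _n_from_rates(rn[idx], spec)
        if da is None or dn is None:
            continue
        diffs.append(math.ceil(dn) - math.ceil(da))
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return (math.ceil(na_raw), math.ceil(nn_raw),
            math.ceil(nn_raw) - math.ceil(na_raw), (float(lo), float(hi)))
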