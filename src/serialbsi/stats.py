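"""Paired agreement and group-comparison statistics.

Covers the statistics used when comparing accelerated with non-accelerated
acquisitions: paired t-test, Pitman–Morgan test for equal variances in paired
samples, Bland–Altman limits of agreement, McNemar's test for paired
proportions, Cohen's kappa for rater reliability, and covariate-adjusted
group differences with bias-corrected and accelerated (BCa) bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PairedSample:
    """Matched measurements under two conditions (e.g. non-accelerated x,
    accelerated y), one entry per subject."""

    x: np.ndarray
    y: np.ndarray
    ids: tuple | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class PairedBinary:
    """2x2 paired pass/fail counts for (accelerated, non-accelerated):
    a = pass/pass, b = pass/fail, c = fail/pass, d = fail/fail."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @classmethod
    def from_fail_flags(cls, fail_a, fail_na) -> "PairedBinary":
        fa = np.asarray(fail_a, dtype=bool)
        fn = np.asarray(fail_na, dtype=bool)
        return cls(a=int((~fa & ~fn).sum()), b=int((~fa & fn).sum()),
                   c=int((fa & ~fn).sum()), d=int((fa & fn).sum()))


def paired_mean_test(s: PairedSample):
    """Classical paired t-test on d = x − y.

    Returns ``(mean_diff, (ci_lo, ci_hi), p)``.  Exactly constant nonzero
    differences yield p = 0 (infinite t); constant zero differences p = 1.
    """
    if s.n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = s.x - s.y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        return mean, (mean, mean), p
    se = sd / np.sqrt(s.n)
    t = mean / se
    p = float(2.0 * sps.t.sf(abs(t), df=s.n - 1))
    half = sps.t.ppf(0.975, df=s.n - 1) * se
    return mean, (mean - half, mean + half), p


def pitman_variance_test(s: PairedSample):
    """Pitman–Morgan test for equal variances in paired samples.

    Under equal variances the sums x + y and differences x − y are
    uncorrelated; the test refers r·√(n−2)/√(1−r²) to t with n−2 df.
    Returns ``(stat, p)``.
    """
    if s.n < 4:
        raise ValueError("Pitman's test needs at least four pairs")
    u = s.x + s.y
    v = s.x - s.y
    if u.std() == 0 or v.std() == 0:
        raise ValueError("degenerate pairs: sums or differences are constant")
    r = float(np.corrcoef(u, v)[0, 1])
    stat = r * np.sqrt(s.n - 2) / np.sqrt(max(1.0 - r * r, 1e-300))
    p = float(2.0 * sps.t.sf(abs(stat), df=s.n - 2))
    return float(stat), p


def limits_of_agreement(s: PairedSample):
    """Bland–Altman limits: mean difference ± 1.96·SD of the differences."""
    if s.n < 2:
        raise ValueError("limits of agreement need at least two pairs")
    d = s.x - s.y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def mcnemar_paired_proportions(t: PairedBinary, method: str = "exact"):
    """McNemar's test on the discordant counts b, c.

    ``exact``: two-sided binomial tail of b out of b + c at p = ½ (capped at
    1); ``chi2``: (b − c)²/(b + c); ``chi2_cc``: continuity-corrected.
    Returns ``(stat, p)`` where stat is b for the exact method.
    """
    b, c = t.b, t.c
    n = b + c
    if method == "exact":
        if n == 0:
            return float(b), 1.0
        p = 2.0 * min(sps.binom.cdf(b, n, 0.5), sps.binom.sf(b - 1, n, 0.5))
        return float(b), float(min(p, 1.0))
    if method in ("chi2", "chi2_cc"):
        if n == 0:
            raise ValueError("no discordant pairs; use method='exact' (p = 1)")
        num = (abs(b - c) - 1.0) ** 2 if method == "chi2_cc" else (b - c) ** 2
        stat = num / n
        return float(stat), float(sps.chi2.sf(stat, df=1))
    raise ValueError(f"unknown method {method!r}")


def cohen_kappa(r1, r2):
    """Cohen's kappa and observed agreement between two raters.

    kappa = (p_o − p_e)/(1 − p_e) with chance agreement p_e from the product
    of marginals.  When both raters are constant (p_e = 1) kappa is undefined
    and returned as NaN alongside the observed agreement.
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size == 0:
        raise ValueError("label vectors must be 1-D, non-empty, equal length")
    labels = np.unique(np.concatenate([r1, r2]))
    n = r1.size
    p_o = float(np.mean(r1 == r2))
    p_e = sum(float(np.mean(r1 == l)) * float(np.mean(r2 == l)) for l in labels)
    if p_e >= 1.0 - 1e-15:
        return float("nan"), p_o
    return (p_o - p_e) / (1.0 - p_e), p_o


# ---------------------------------------------------------------------------
# covariate-adjusted group differences with BCa bootstrap

def _fit_group_coef(outcome, group, covariates):
    if covariates is not None and covariates.size:
        X = np.column_stack([np.ones_like(outcome), group, covariates])
    else:
        X = np.column_stack([np.ones_like(outcome), group])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient adjustment design")
    coef, *_ = np.linalg.lstsq(X, outcome, rcond=None)
    return float(coef[1])


def _bca_interval(theta_hat, boot, jack, alpha=0.05):
    boot = np.asarray(boot, dtype=float)
    prop = np.mean(boot < theta_hat)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), 1.0 - 1.0 / (len(boot) + 1))
    z0 = sps.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    out = []
    for z in (sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        out.append(float(np.percentile(boot, 100.0 * sps.norm.cdf(adj))))
    return out[0], out[1]


def adjusted_group_difference(outcome, group_indicator, covariates=None,
                              n_boot: int = 2000, seed: int = 0,
                              family: str = "linear"):
    """Covariate-adjusted group difference with a BCa bootstrap 95% CI.

    The point estimate is the group coefficient from least squares of the
    outcome on the group indicator plus covariates (``family='logistic'``
    returns the log odds ratio from a logistic fit instead, for binary
    outcomes such as cognitive impairment).  The CI resamples subjects with
    replacement; bias correction comes from the bootstrap distribution's
    position of the point estimate and acceleration from jackknife skewness.
    Returns ``(adjusted_diff, (ci_lo, ci_hi))``.
    """
    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group_indicator, dtype=float)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    n = outcome.size
    n_cov = 0 if cov is None else cov.shape[1]
    if n <= n_cov + 2:
        raise ValueError("too few subjects for the adjustment model")
    if np.unique(group).size < 2:
        raise ValueError("group indicator must have both levels")

    if family == "logistic":
        import statsmodels.api as sm
        def estimate(idx):
            X = sm.add_constant(np.column_stack(
                [group[idx]] + ([cov[idx]] if cov is not None else [])))
            return float(sm.Logit(outcome[idx], X).fit(disp=0).params[1])
    elif family == "linear":
        def estimate(idx):
            return _fit_group_coef(outcome[idx], group[idx],
                                   cov[idx] if cov is not None else None)
    else:
        raise ValueError(f"unknown family {family!r}")

    all_idx = np.arange(n)
    theta_hat = estimate(all_idx)
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot.append(estimate(idx))
        except np.linalg.LinAlgError:
            continue
    if len(boot) < 0.9 * n_boot:
        raise RuntimeError("too many degenerate bootstrap replicates")
    jack = np.array([estimate(np.delete(all_idx, i)) for i in range(n)])
    ci = _bca_interval(theta_hat, np.asarray(boot), jack)
    return theta_hat, ci
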