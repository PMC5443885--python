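"""Linear mixed models for repeated direct-change measures.

A direct-change outcome y_ijk (the measured ml change between visits j and k
of subject i) follows

    y_ijk = (β0 + β1·scantype + β2·EMCI + β3·LMCI + β4·AD + b_i)·t_ijk
            − u_ij + u_ik + ε_ijk

with a per-subject random slope b_i ~ N(0, σ²_b,dx(i)) whose variance is
diagnosis-specific, signed visit random effects u_ij ~ N(0, σ²_u) (a change
spanning visits j→k loads −u_ij + u_ik), and residuals whose variance may
differ by scan type (accelerated vs non-accelerated).  Both scan types of a
session share b_i and u_ij.  Estimation is by maximum likelihood with the
variance parameters log-parametrized and the fixed effects profiled out by
generalized least squares; scan-type-specific measurement error is tested by
a likelihood ratio between the separate- and common-residual-variance models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .phantom import ACCELERATED, DIAGNOSES, NON_ACCELERATED

_LOGVAR_BOUNDS = (-16.0, 16.0)

_BETA_LABELS = {"CN": "beta0", "EMCI": "beta2", "LMCI": "beta3", "AD": "beta4"}


@dataclass
class _SubjectGroup:
    """Subjects sharing an identical record pattern (same V up to σ's)."""

    dx_index: int
    t: np.ndarray          # (n_i,) intervals
    st: np.ndarray         # (n_i,) 0 = accelerated, 1 = non-accelerated
    W: np.ndarray          # (n_i, q) signed visit incidence
    X: np.ndarray          # (n_i, p) fixed design
    Y: np.ndarray          # (n_i, m) stacked outcomes, one column per subject


@dataclass
class ChangeDesign:
    groups: list[_SubjectGroup]
    beta_names: list[str]
    present_dx: list[str]
    n_records: int
    n_subjects: int
    n_resid_classes: int   # 1 if only one scan type occurs


@dataclass
class LmmFit:
    """Maximum-likelihood fit of the direct-change mixed model."""

    beta: dict[str, float]
    beta_se: dict[str, float]
    beta_cov: np.ndarray
    beta_names: list[str]
    var_slope: dict[str, float]
    var_visit: float
    var_resid: dict[str, float]
    loglik: float
    converged: bool
    n_records: int
    n_subjects: int
    present_dx: list[str] = field(default_factory=list)
    theta: np.ndarray | None = None

    def summary(self) -> str:
        lines = ["Direct-change mixed model (ML)",
                 f"  records: {self.n_records}, subjects: {self.n_subjects}",
                 f"  log-likelihood: {self.loglik:.4f}  converged: {self.converged}",
                 "  fixed effects (ml/yr):"]
        for name in self.beta_names:
            lines.append(f"    {name:>22s} = {self.beta[name]:9.4f}"
                         f"  (SE {self.beta_se[name]:.4f})")
        lines.append("  variance components:")
        for dx, v in self.var_slope.items():
            lines.append(f"    slope SD [{dx:>4s}] = {np.sqrt(v):.4f} ml/yr")
        lines.append(f"    visit SD         = {np.sqrt(self.var_visit):.4f} ml")
        for st, v in self.var_resid.items():
            lines.append(f"    residual SD [{st}] = {np.sqrt(v):.4f} ml")
        return "\n".join(lines)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "diagnosis", "visit_j", "visit_k", "t_years",
                "scan_type", "y_ml"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table is missing columns: {sorted(missing)}")
    if (records["t_years"] <= 0).any():
        raise ValueError("all intervals t_years must be positive")
    if (records["visit_j"] >= records["visit_k"]).any():
        raise ValueError("visit_j must precede visit_k")
    dup = records.duplicated(["subject_id", "scan_type", "visit_j", "visit_k"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject, scan_type, visit pair) at row {dup.idxmax()}")
    ndx = records.groupby("subject_id")["diagnosis"].nunique()
    if (ndx > 1).any():
        raise ValueError("diagnosis must be constant within subject")
    return records


def build_change_design(records: pd.DataFrame,
                        diagnosis_specific_slopes: bool = True,
                        share_random_effects: bool = True) -> ChangeDesign:
    """Assemble fixed design, signed visit incidence and subject grouping.

    Fixed-effect columns are t, scantype·t and one dx·t column per non-control
    diagnosis present.  Subjects with identical record patterns are grouped so
    the marginal covariance is factorized once per pattern.
    """
    records = _validate_records(records.copy())
    present_dx = [d for d in DIAGNOSES if (records["diagnosis"] == d).any()]
    if not present_dx:  # labels outside the ADNI strata: treat as one stratum
        present_dx = sorted(records["diagnosis"].unique())[:1]
        records = records.assign(diagnosis=present_dx[0])
    # offsets are relative to the first diagnosis present (CN when available)
    extra_dx = present_dx[1:]
    beta_names = ["beta0 (rate, accel)", "beta1 (non-accel offset)"] + \
        [f"{_BETA_LABELS.get(d, 'beta_dx')} ({d} offset)" for d in extra_dx]
    if records["scan_type"].nunique() == 1:
        # scan-type contrast inestimable with a single scan type
        beta_names = [beta_names[0]] + beta_names[2:]
    has_st = len(records["scan_type"].unique()) > 1

    group_key = records["subject_id"].astype(str)
    if not share_random_effects:
        group_key = group_key + "//" + records["scan_type"].astype(str)
    records = records.assign(_grp=group_key)

    buckets: dict[bytes, _SubjectGroup] = {}
    order: list[bytes] = []
    n_subjects = 0
    for _, sub in sorted(records.groupby("_grp"), key=lambda kv: kv[0]):
        n_subjects += 1
        sub = sub.sort_values(["visit_j", "visit_k", "scan_type"])
        t = sub["t_years"].to_numpy(float)
        st = (sub["scan_type"] == NON_ACCELERATED).to_numpy(int)
        visits = np.unique(sub[["visit_j", "visit_k"]].to_numpy())
        vidx = {v: i for i, v in enumerate(visits)}
        W = np.zeros((len(sub), len(visits)))
        for r, (j, k) in enumerate(zip(sub["visit_j"], sub["visit_k"])):
            W[r, vidx[j]] = -1.0
            W[r, vidx[k]] = 1.0
        dx = sub["diagnosis"].iloc[0]
        dx_index = present_dx.index(dx) if diagnosis_specific_slopes else 0
        cols = [t]
        if has_st:
            cols.append(st * t)
        for d in extra_dx:
            cols.append(t * (1.0 if dx == d else 0.0))
        X = np.column_stack(cols)
        y = sub["y_ml"].to_numpy(float)
        key = (dx_index, t.tobytes(), st.tobytes(), W.shape, W.tobytes(),
               X.tobytes())
        kb = repr(key).encode()
        if kb in buckets:
            g = buckets[kb]
            g.Y = np.column_stack([g.Y, y])
        else:
            buckets[kb] = _SubjectGroup(dx_index, t, st, W, X, y[:, None])
            order.append(kb)
    n_slope = len(present_dx) if diagnosis_specific_slopes else 1
    return ChangeDesign(
        groups=[buckets[kb] for kb in order],
        beta_names=beta_names,
        present_dx=present_dx,
        n_records=len(records),
        n_subjects=n_subjects,
        n_resid_classes=2 if has_st else 1,
    )


def _profiled_loglik(theta: np.ndarray, design: ChangeDesign, n_slope: int,
                     separate_residuals: bool):
    """Log-likelihood with β profiled out by GLS; returns (ll, β, cov_β)."""
    sb2 = np.exp(theta[:n_slope])
    su2 = np.exp(theta[n_slope])
    if separate_residuals:
        se2 = np.exp(theta[n_slope + 1: n_slope + 3])
    else:
        se2 = np.exp(np.array([theta[n_slope + 1], theta[n_slope + 1]]))
    p = design.groups[0].X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    n_total = 0
    for g in design.groups:
        m = g.Y.shape[1]
        sb = sb2[g.dx_index] if g.dx_index < n_slope else sb2[0]
        V = sb * np.outer(g.t, g.t) + su2 * (g.W @ g.W.T) \
            + np.diag(se2[g.st])
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        A = solve_triangular(L, g.X, lower=True)
        B = solve_triangular(L, g.Y, lower=True)
        XtVX += m * (A.T @ A)
        XtVy += A.T @ B.sum(axis=1)
        yty += float((B * B).sum())
        logdet += m * 2.0 * float(np.sum(np.log(np.diag(L))))
        n_total += m * len(g.t)
    try:
        c = cho_factor(XtVX)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    beta = cho_solve(c, XtVy)
    quad = yty - 2.0 * beta @ XtVy + beta @ XtVX @ beta
    ll = -0.5 * (n_total * np.log(2.0 * np.pi) + logdet + quad)
    cov = cho_solve(c, np.eye(p))
    return ll, beta, cov


def _moment_start(design: ChangeDesign, n_slope: int) -> np.ndarray:
    ys, ts = [], []
    for g in design.groups:
        ys.append(g.Y.ravel())
        ts.append(np.tile(g.t, g.Y.shape[1]))
    y = np.concatenate(ys)
    t = np.concatenate(ts)
    rate_var = max(np.var(y / t), 1e-6)
    v = max(np.var(y), 1e-6)
    sb2 = np.full(n_slope, rate_var / 3.0)
    return np.log(np.concatenate([sb2, [v / 6.0, v / 3.0]]))


def fit_change_lmm(records: pd.DataFrame, separate_residuals: bool = True,
                   diagnosis_specific_slopes: bool = True,
                   share_random_effects: bool = True,
                   extra_starts: list[np.ndarray] | None = None,
                   gtol: float = 1e-8) -> LmmFit:
    """ML fit of the direct-change mixed model.

    ``separate_residuals`` fits scan-type-specific residual variances;
    ``diagnosis_specific_slopes`` fits one random-slope variance per diagnosis
    present.  Multi-start quasi-Newton optimization on the log-variances with
    β profiled out per candidate covariance.
    """
    design = build_change_design(records, diagnosis_specific_slopes,
                                 share_random_effects)
    if design.n_subjects < 2:
        raise ValueError("at least two subjects are required")
    separate = separate_residuals and design.n_resid_classes == 2
    n_slope = len(design.present_dx) if diagnosis_specific_slopes else 1

    base = _moment_start(design, n_slope)
    if separate:
        base = np.append(base, base[-1])
    starts = [base, base + np.log(0.3), base + np.log(3.0)]
    for s in (extra_starts or []):
        starts.append(np.asarray(s, dtype=float))

    def neg_ll(theta):
        ll, _, _ = _profiled_loglik(theta, design, n_slope, separate)
        return np.inf if not np.isfinite(ll) else -ll

    best = None
    for s0 in starts:
        s0 = np.clip(s0, *_LOGVAR_BOUNDS)
        res = optimize.minimize(
            neg_ll, s0, method="L-BFGS-B",
            bounds=[_LOGVAR_BOUNDS] * len(s0),
            options={"maxiter": 500, "gtol": gtol, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    ll, beta, cov = _profiled_loglik(theta, design, n_slope, separate)
    if beta is None:
        raise np.linalg.LinAlgError("singular marginal covariance at optimum")
    se = np.sqrt(np.diag(cov))
    sb2 = np.exp(theta[:n_slope])
    if diagnosis_specific_slopes:
        var_slope = {d: float(sb2[i]) for i, d in enumerate(design.present_dx)}
    else:
        var_slope = {d: float(sb2[0]) for d in design.present_dx}
    if separate:
        var_resid = {ACCELERATED: float(np.exp(theta[n_slope + 1])),
                     NON_ACCELERATED: float(np.exp(theta[n_slope + 2]))}
    else:
        v = float(np.exp(theta[n_slope + 1]))
        var_resid = {ACCELERATED: v, NON_ACCELERATED: v}
    return LmmFit(
        beta={n: float(b) for n, b in zip(design.beta_names, beta)},
        beta_se={n: float(s) for n, s in zip(design.beta_names, se)},
        beta_cov=cov,
        beta_names=design.beta_names,
        var_slope=var_slope,
        var_visit=float(np.exp(theta[n_slope])),
        var_resid=var_resid,
        loglik=float(ll),
        converged=bool(best.success),
        n_records=design.n_records,
        n_subjects=design.n_subjects,
        present_dx=design.present_dx,
        theta=theta,
    )


def lrt_residual_variances(records: pd.DataFrame,
                           diagnosis_specific_slopes: bool = True):
    """Likelihood-ratio test for scan-type-specific residual variance.

    Compares the common-residual-variance model against the model with
    separate accelerated / non-accelerated residual variances (1 df).  The
    separate model is additionally started at the common model's optimum, so
    the nesting inequality holds by construction.
    Returns ``(chi2_stat, df, p_value, fit_common, fit_separate)``.
    """
    fit_common = fit_change_lmm(records, separate_residuals=False,
                                diagnosis_specific_slopes=diagnosis_specific_slopes)
    extra = [np.append(fit_common.theta, fit_common.theta[-1])]
    fit_separate = fit_change_lmm(records, separate_residuals=True,
                                  diagnosis_specific_slopes=diagnosis_specific_slopes,
                                  extra_starts=extra)
    stat = 2.0 * (fit_separate.loglik - fit_common.loglik)
    tol = 1e-6 * max(1.0, abs(fit_common.loglik))
    if stat < -tol:
        raise RuntimeError(
            "optimizer failure: nested model attained higher likelihood")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return stat, 1, p, fit_common, fit_separate


def adjusted_group_rates(fit: LmmFit, diagnosis: str, scan_type: str):
    """Model-implied mean annualised rate (ml/yr) for a group and scan type.

    Controls/accelerated = β0; controls/non-accelerated = β0 + β1; other
    diagnoses add their offset.  SE by the delta method (linear contrast of
    the fixed-effect covariance).
    """
    if diagnosis not in fit.present_dx:
        raise ValueError(f"diagnosis {diagnosis!r} absent from the fit")
    if scan_type not in (ACCELERATED, NON_ACCELERATED):
        raise ValueError(f"unknown scan type {scan_type!r}")
    contrast = np.zeros(len(fit.beta_names))
    contrast[0] = 1.0
    for i, name in enumerate(fit.beta_names):
        if scan_type == NON_ACCELERATED and name.startswith("beta1"):
            contrast[i] = 1.0
        if f"({diagnosis} offset)" in name:
            contrast[i] = 1.0
    rate = float(contrast @ np.array([fit.beta[n] for n in fit.beta_names]))
    se = float(np.sqrt(contrast @ fit.beta_cov @ contrast))
    return rate, se
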