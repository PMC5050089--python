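"""Method-of-moments estimation of the intervention effect (Buonaccorsi approach).

Two component estimators of the intervention effect ``theta = muT2 - muT1``:

* ``theta_bio`` — difference between arms of the sub-study means of the
  per-individual biomarker replicate averages.  Unbiased because the biomarker
  follows a classical error model.
* ``theta_sr`` — a bias-corrected estimator built from the self-reports, using
  errors-in-variables slope estimates ``alpha1 = cov(Q, Mbar) / cov(M1, M2)``
  computed in the calibration sub-study (per arm under differential error,
  pooled across arms under non-differential error).

The two are combined by an inverse-variance-weighted average whose weights use
the full 2x2 variance matrix of ``(theta_bio, theta_sr)``, estimated by a
stacked-estimating-equation sandwich: one estimating equation per first or
second moment entering the estimators, empirical outer-product meat, and a
delta-method map onto the two effect estimators.  At the solution the bread
matrix is exactly diagonal (every cross term is a centered sample mean), which
the test-suite verifies against a numerical Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ErrorModelSpec, TrialDataset, ValidationError

# ---------------------------------------------------------------------------
# sub-study views and raw moments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _GroupData:
    q_all: np.ndarray   # self-report, everyone in the arm
    q_sub: np.ndarray   # self-report, sub-study members
    m1: np.ndarray      # first biomarker replicate, sub-study
    m2: np.ndarray      # second biomarker replicate, sub-study


def _group_data(d: TrialDataset, group: int) -> _GroupData:
    in_g = d.group == group
    sub = in_g & d.in_substudy
    m1 = d.m[sub, 0]
    m2 = d.m[sub, 1]
    if np.isnan(m1).any() or np.isnan(m2).any():
        raise ValidationError(
            "method-of-moments estimation uses the first two biomarker replicates; "
            f"sub-study rows in group {group} have them missing"
        )
    return _GroupData(q_all=d.q[in_g], q_sub=d.q[sub], m1=m1, m2=m2)


def _cov(x: np.ndarray, y: np.ndarray, ddof: int = 1) -> float:
    """Sample covariance with explicit denominator convention (default n-1)."""
    n = x.size
    return float(np.dot(x - x.mean(), y - y.mean()) / (n - ddof))


@dataclass(frozen=True)
class AlphaEstimates:
    """Self-report calibration-model estimates and the moment behind the slope."""

    alpha0: np.ndarray      # per arm (differential) or length-1 (non-differential)
    alpha1: np.ndarray
    cov_m1m2: np.ndarray    # slope denominator(s); non-positive => degenerate
    pooled: bool

    @property
    def valid(self) -> bool:
        return bool(np.all(self.cov_m1m2 > 0) and np.all(np.isfinite(self.alpha1)))


# ---------------------------------------------------------------------------
# component estimators
# ---------------------------------------------------------------------------


def estimate_theta_bio(d: TrialDataset) -> tuple[float, float]:
    """Biomarker-only effect estimate and its variance.

    Returns ``(Mbar2 - Mbar1, s^2_1/n1 + s^2_2/n2)`` where the means and
    sample variances (n-1 denominator) are of the per-individual replicate
    averages among calibration sub-study members.
    """
    means, vars_ = [], []
    for g in (1, 2):
        gd = _group_data(d, g)
        mbar = (gd.m1 + gd.m2) / 2.0
        if mbar.size < 2:
            raise ValidationError(f"group {g} needs >= 2 sub-study members")
        means.append(mbar.mean())
        vars_.append(mbar.var(ddof=1) / mbar.size)
    return means[1] - means[0], vars_[0] + vars_[1]


def estimate_alpha_differential(d: TrialDataset) -> AlphaEstimates:
    """Arm-specific errors-in-variables intercepts and slopes.

    ``alpha1_i = cov(Q, Mbar) / cov(M1, M2)`` and
    ``alpha0_i = Qbar_i(sub) - alpha1_i * Mbar_i``, with sample covariances
    over sub-study members of arm ``i``.  A non-positive slope denominator is
    reported through ``cov_m1m2`` (callers flag the fit invalid).
    """
    a0, a1, cmm = [], [], []
    for g in (1, 2):
        gd = _group_data(d, g)
        if gd.m1.size < 3:
            raise ValidationError(f"group {g} needs >= 3 sub-study members")
        mbar = (gd.m1 + gd.m2) / 2.0
        c_mm = _cov(gd.m1, gd.m2)
        slope = _cov(gd.q_sub, mbar) / c_mm if c_mm != 0 else np.inf
        a1.append(slope)
        a0.append(gd.q_sub.mean() - slope * mbar.mean())
        cmm.append(c_mm)
    return AlphaEstimates(np.array(a0), np.array(a1), np.array(cmm), pooled=False)


def estimate_alpha_nondifferential(d: TrialDataset) -> AlphaEstimates:
    """Shared intercept/slope from the two arms' sub-study data combined.

    The covariances pool the individuals of both arms into one sample (the
    between-arm spread contributes, and cancels in the slope ratio exactly
    when the error really is non-differential).
    """
    g1, g2 = _group_data(d, 1), _group_data(d, 2)
    q = np.concatenate([g1.q_sub, g2.q_sub])
    m1 = np.concatenate([g1.m1, g2.m1])
    m2 = np.concatenate([g1.m2, g2.m2])
    if q.size < 3:
        raise ValidationError("need >= 3 pooled sub-study members")
    mbar = (m1 + m2) / 2.0
    c_mm = _cov(m1, m2)
    slope = _cov(q, mbar) / c_mm if c_mm != 0 else np.inf
    a0 = q.mean() - slope * mbar.mean()
    return AlphaEstimates(np.array([a0]), np.array([slope]), np.array([c_mm]), pooled=True)


def estimate_theta_sr(d: TrialDataset, spec: ErrorModelSpec,
                      alphas: AlphaEstimates) -> float:
    """Self-report-based effect estimator.

    Differential: ``(Qbar2 - Qbar2s)/a12 - (Qbar1 - Qbar1s)/a11 + Mbar2 - Mbar1``
    (full-sample minus sub-study self-report means, slope-corrected, anchored
    on the sub-study biomarker means).  Non-differential:
    ``(Qbar2 - Qbar1) / alpha1`` with the pooled slope.
    """
    if np.any(alphas.alpha1 == 0) or not np.all(np.isfinite(alphas.alpha1)):
        raise ZeroDivisionError("self-report estimator undefined: zero/non-finite slope")
    g1, g2 = _group_data(d, 1), _group_data(d, 2)
    if spec.is_differential:
        if alphas.pooled:
            raise ValueError("differential structure needs arm-specific alphas")
        mbar1 = (g1.m1 + g1.m2).mean() / 2.0
        mbar2 = (g2.m1 + g2.m2).mean() / 2.0
        return float(
            (g2.q_all.mean() - g2.q_sub.mean()) / alphas.alpha1[1]
            - (g1.q_all.mean() - g1.q_sub.mean()) / alphas.alpha1[0]
            + mbar2 - mbar1
        )
    if not alphas.pooled:
        raise ValueError("non-differential structure needs the pooled alpha")
    return float((g2.q_all.mean() - g1.q_all.mean()) / alphas.alpha1[0])


def estimate_error_variances(d: TrialDataset, spec: ErrorModelSpec,
                             alphas: AlphaEstimates) -> tuple[np.ndarray, np.ndarray]:
    """Moment estimates of the biomarker and self-report error variances.

    ``sigma2_M = var(M) - cov(M1, M2)`` (replicate variance averaged over the
    two columns, same n-1 convention as the covariance, so identical
    replicates give exactly zero) and
    ``sigma2_Q = var(Q) - alpha1^2 cov(M1, M2)``, per arm under the
    differential structure, pooled over both arms' sub-study data otherwise.
    Negative estimates are returned as-is; callers flag them.
    """
    groups = [_group_data(d, g) for g in (1, 2)]
    if spec.is_differential:
        s2m, s2q = [], []
        for gd, a1 in zip(groups, alphas.alpha1):
            c_mm = _cov(gd.m1, gd.m2)
            var_m = 0.5 * (gd.m1.var(ddof=1) + gd.m2.var(ddof=1))
            s2m.append(var_m - c_mm)
            s2q.append(gd.q_sub.var(ddof=1) - a1**2 * c_mm)
        return np.array(s2m), np.array(s2q)
    m1 = np.concatenate([g.m1 for g in groups])
    m2 = np.concatenate([g.m2 for g in groups])
    q = np.concatenate([g.q_sub for g in groups])
    c_mm = _cov(m1, m2)
    s2m = 0.5 * (m1.var(ddof=1) + m2.var(ddof=1)) - c_mm
    s2q = q.var(ddof=1) - alphas.alpha1[0] ** 2 * c_mm
    return np.array([s2m]), np.array([s2q])


# ---------------------------------------------------------------------------
# estimating-equation sandwich for (theta_bio, theta_sr)
# ---------------------------------------------------------------------------


def _ee_system_differential(d: TrialDataset):
    """Per-individual estimating functions, their (diagonal) bread, and the
    moment-parameter solution for the differential structure.

    Parameters per arm: mean of Q over everyone; mean of Q, M1, M2 over the
    sub-study; sub-study covariances cov(Q, Mbar) and cov(M1, M2)
    (n-denominator, so the solution zeroes the equations exactly).
    """
    n = len(d)
    beta, diag, cols = [], [], []
    for g in (1, 2):
        in_g = d.group == g
        sub = in_g & d.in_substudy
        m1 = np.where(sub, d.m[:, 0], 0.0)   # zero-filled: every use is gated by s
        m2 = np.where(sub, d.m[:, 1], 0.0)
        mu_q = d.q[in_g].mean()
        mu_qs = d.q[sub].mean()
        mu_1 = m1[sub].mean()
        mu_2 = m2[sub].mean()
        mbar = (m1 + m2) / 2.0
        mu_m = (mu_1 + mu_2) / 2.0
        c_qm = float(np.mean((d.q[sub] - mu_qs) * (mbar[sub] - mu_m)))
        c_mm = float(np.mean((m1[sub] - mu_1) * (m2[sub] - mu_2)))
        beta += [mu_q, mu_qs, mu_1, mu_2, c_qm, c_mm]
        p_g = in_g.mean()
        f_g = sub.mean()
        diag += [-p_g, -f_g, -f_g, -f_g, -f_g, -f_g]
        s = sub.astype(float)
        cols += [
            np.where(in_g, d.q - mu_q, 0.0),
            s * (d.q - mu_qs),
            s * (m1 - mu_1),
            s * (m2 - mu_2),
            s * ((d.q - mu_qs) * (mbar - mu_m) - c_qm),
            s * ((m1 - mu_1) * (m2 - mu_2) - c_mm),
        ]
    psi = np.column_stack(cols)
    return np.array(beta), np.array(diag), psi


def _g_differential(beta: np.ndarray) -> np.ndarray:
    (mu_q1, mu_q1s, mu11, mu21, cqm1, cmm1,
     mu_q2, mu_q2s, mu12, mu22, cqm2, cmm2) = beta
    a11 = cqm1 / cmm1
    a12 = cqm2 / cmm2
    theta_bio = (mu12 + mu22) / 2.0 - (mu11 + mu21) / 2.0
    theta_sr = (mu_q2 - mu_q2s) / a12 - (mu_q1 - mu_q1s) / a11 + theta_bio
    return np.array([theta_bio, theta_sr])


def _ee_system_nondifferential(d: TrialDataset):
    """As :func:`_ee_system_differential` for the pooled (non-differential)
    structure: arm means of Q, arm sub-study means of Mbar, plus combined
    sub-study means of Q, M1, M2 and combined covariances."""
    sub = d.in_substudy
    m1 = np.where(sub, d.m[:, 0], 0.0)   # zero-filled: every use is gated by s
    m2 = np.where(sub, d.m[:, 1], 0.0)
    mbar_obs = (m1 + m2) / 2.0
    mu_q = [d.q[d.group == g].mean() for g in (1, 2)]
    mu_m = [mbar_obs[(d.group == g) & sub].mean() for g in (1, 2)]
    mu_qs = d.q[sub].mean()
    nu1 = m1[sub].mean()
    nu2 = m2[sub].mean()
    nubar = (nu1 + nu2) / 2.0
    c_qm = float(np.mean((d.q[sub] - mu_qs) * (mbar_obs[sub] - nubar)))
    c_mm = float(np.mean((m1[sub] - nu1) * (m2[sub] - nu2)))
    beta = np.array([mu_q[0], mu_q[1], mu_m[0], mu_m[1], mu_qs, nu1, nu2, c_qm, c_mm])
    s = sub.astype(float)
    in1 = (d.group == 1).astype(float)
    in2 = (d.group == 2).astype(float)
    diag = -np.array([
        in1.mean(), in2.mean(), (in1 * s).mean(), (in2 * s).mean(),
        s.mean(), s.mean(), s.mean(), s.mean(), s.mean(),
    ])
    cols = [
        in1 * (d.q - mu_q[0]),
        in2 * (d.q - mu_q[1]),
        in1 * s * (mbar_obs - mu_m[0]),
        in2 * s * (mbar_obs - mu_m[1]),
        s * (d.q - mu_qs),
        s * (m1 - nu1),
        s * (m2 - nu2),
        s * ((d.q - mu_qs) * (mbar_obs - nubar) - c_qm),
        s * ((m1 - nu1) * (m2 - nu2) - c_mm),
    ]
    psi = np.column_stack(cols)
    return beta, diag, psi


def _g_nondifferential(beta: np.ndarray) -> np.ndarray:
    mu_q1, mu_q2, mu_m1, mu_m2, _mu_qs, _nu1, _nu2, c_qm, c_mm = beta
    theta_bio = mu_m2 - mu_m1
    theta_sr = (mu_q2 - mu_q1) * c_mm / c_qm
    return np.array([theta_bio, theta_sr])


def _numerical_jacobian(fun, x: np.ndarray) -> np.ndarray:
    out = []
    for k in range(x.size):
        h = 1e-6 * max(1.0, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        out.append((fun(xp) - fun(xm)) / (2 * h))
    return np.column_stack(out)


def effect_vcov_ee(d: TrialDataset, spec: ErrorModelSpec) -> np.ndarray:
    """Sandwich 2x2 variance matrix of ``(theta_bio, theta_sr)``.

    ``V = G A^{-1} B A^{-T} G^T / N`` with ``A`` the averaged estimating-
    function Jacobian (diagonal at the solution), ``B`` the empirical outer
    product of the per-individual estimating functions, and ``G`` the
    delta-method gradient of the two effect estimators.
    """
    if spec.is_differential:
        beta, diag, psi = _ee_system_differential(d)
        g_fun = _g_differential
    else:
        beta, diag, psi = _ee_system_nondifferential(d)
        g_fun = _g_nondifferential
    n = psi.shape[0]
    b = psi.T @ psi / n
    v_beta = b / np.outer(diag, diag) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        # degenerate moments (cov(M1,M2) <= 0) surface as NaN entries and are
        # flagged invalid by the caller rather than raising here
        g_grad = _numerical_jacobian(g_fun, beta)
        return g_grad @ v_beta @ g_grad.T


# ---------------------------------------------------------------------------
# combination and full fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombinedEstimate:
    theta: float
    var: float
    weight_bio: float
    valid: bool
    degenerate: bool = False   # theta_sr coincides with theta_bio (100% calibration)


def combine_estimates(theta_bio: float, theta_sr: float, var_bio: float,
                      var_sr: float, cov_bio_sr: float) -> CombinedEstimate:
    """Minimum-variance weighted average of the two effect estimators.

    ``w = (var_sr - cov) / (var_bio + var_sr - 2 cov)`` on ``theta_bio``;
    combined variance ``(var_bio var_sr - cov^2) / (var_bio + var_sr - 2 cov)``.
    Weights are not clipped to [0, 1].  When the two estimators coincide
    (100% calibration under differential error) the denominator degenerates
    and the biomarker estimator is returned unchanged.
    """
    denom = var_bio + var_sr - 2.0 * cov_bio_sr
    scale = max(abs(var_bio), abs(var_sr), 1e-300)
    if abs(denom) <= 1e-9 * scale:
        return CombinedEstimate(theta_bio, var_bio, 1.0,
                                valid=var_bio > 0, degenerate=True)
    ok = var_bio > 0 and var_sr > 0 and denom > 0 \
        and var_bio * var_sr - cov_bio_sr**2 > -1e-12 * scale**2
    w = (var_sr - cov_bio_sr) / denom
    theta = w * theta_bio + (1.0 - w) * theta_sr
    var = (var_bio * var_sr - cov_bio_sr**2) / denom
    return CombinedEstimate(float(theta), float(var), float(w),
                            valid=bool(ok and var > 0))


@dataclass
class MoMFit:
    """Result of the method-of-moments analysis under one error structure."""

    spec: ErrorModelSpec
    theta_bio: float
    var_bio_direct: float          # s^2/n1 + s^2/n2 of per-individual means
    theta_sr: float
    alpha0: np.ndarray
    alpha1: np.ndarray
    sigma2_m: np.ndarray
    sigma2_q: np.ndarray
    var_bio: float                 # EE sandwich entries
    var_sr: float
    cov_bio_sr: float
    weight_bio: float
    theta_combined: float
    var_combined: float
    valid: bool
    messages: list[str] = field(default_factory=list)

    @property
    def se_combined(self) -> float:
        return float(np.sqrt(self.var_combined)) if self.var_combined > 0 else np.nan

    @property
    def se_bio(self) -> float:
        return float(np.sqrt(self.var_bio_direct))

    def to_dict(self) -> dict:
        out = {
            "structure": self.spec.structure,
            "theta_bio": self.theta_bio,
            "se_bio": self.se_bio,
            "theta_sr": self.theta_sr,
            "theta_combined": self.theta_combined,
            "se_combined": self.se_combined,
            "weight_bio": self.weight_bio,
            "valid": self.valid,
        }
        labels = ("", ) if self.alpha0.size == 1 else ("_1", "_2")
        for i, lab in enumerate(labels):
            out[f"alpha0{lab}"] = float(self.alpha0[i])
            out[f"alpha1{lab}"] = float(self.alpha1[i])
        labels = ("", ) if self.sigma2_m.size == 1 else ("_1", "_2")
        for i, lab in enumerate(labels):
            out[f"sigma2_m{lab}"] = float(self.sigma2_m[i])
            out[f"sigma2_q{lab}"] = float(self.sigma2_q[i])
        return out


def fit_mom(d: TrialDataset, spec: ErrorModelSpec | None = None) -> MoMFit:
    """Full Buonaccorsi analysis: component estimators, sandwich variance
    matrix, error variances, and the inverse-variance-weighted combination.

    The fit is flagged ``valid=False`` (never silently truncated) when any
    moment used degenerates: non-positive ``cov(M1, M2)``, negative error
    variance estimate, or a non-positive-definite combination matrix.
    """
    spec = spec or ErrorModelSpec()
    messages: list[str] = []
    theta_bio, var_bio_direct = estimate_theta_bio(d)
    alphas = (estimate_alpha_differential(d) if spec.is_differential
              else estimate_alpha_nondifferential(d))
    ok = alphas.valid
    if not ok:
        messages.append("non-positive biomarker replicate covariance (slope denominator)")
    try:
        theta_sr = estimate_theta_sr(d, spec, alphas)
    except ZeroDivisionError:
        theta_sr = np.nan
        ok = False
        messages.append("self-report estimator undefined (zero slope)")
    s2m, s2q = estimate_error_variances(d, spec, alphas)
    if np.any(s2m <= 0):
        ok = False
        messages.append("non-positive biomarker error variance estimate")
    if np.any(s2q <= 0):
        ok = False
        messages.append("non-positive self-report error variance estimate")
    v = effect_vcov_ee(d, spec)
    comb = combine_estimates(theta_bio, theta_sr, v[0, 0], v[1, 1], v[0, 1])
    if not comb.valid:
        messages.append("combination variance matrix not positive definite")
    return MoMFit(
        spec=spec,
        theta_bio=float(theta_bio),
        var_bio_direct=float(var_bio_direct),
        theta_sr=float(theta_sr),
        alpha0=alphas.alpha0,
        alpha1=alphas.alpha1,
        sigma2_m=s2m,
        sigma2_q=s2q,
        var_bio=float(v[0, 0]),
        var_sr=float(v[1, 1]),
        cov_bio_sr=float(v[0, 1]),
        weight_bio=comb.weight_bio,
        theta_combined=comb.theta,
        var_combined=comb.var,
        valid=bool(ok and comb.valid),
        messages=messages,
    )


def bootstrap_effect_vcov(d: TrialDataset, spec: ErrorModelSpec, n_boot: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Empirical 2x2 covariance of ``(theta_bio, theta_sr)`` over bootstrap
    resamples stratified by arm and sub-study membership (sub-study sizes are
    design constants, so strata are resampled separately)."""
    strata = [np.flatnonzero((d.group == g) & (d.in_substudy == s))
              for g in (1, 2) for s in (True, False) ]
    strata = [ix for ix in strata if ix.size]
    ests = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(ix, size=ix.size, replace=True) for ix in strata])
        db = TrialDataset(group=d.group[idx], q=d.q[idx], m=d.m[idx])
        theta_bio, _ = estimate_theta_bio(db)
        alphas = (estimate_alpha_differential(db) if spec.is_differential
                  else estimate_alpha_nondifferential(db))
        ests[b, 0] = theta_bio
        ests[b, 1] = estimate_theta_sr(db, spec, alphas)
    return np.cov(ests.T, ddof=1)
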