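"""Maximum-likelihood estimation of the joint normal measurement model.

For arm ``i`` the sub-study triple ``(M1, M2, Q)`` is modelled as trivariate
normal with mean ``(muT_i, muT_i, alpha0_i + alpha1_i muT_i)`` and covariance

    [[s2T + s2M,  s2T,        a1 s2T      ],
     [s2T,        s2T + s2M,  a1 s2T      ],
     [a1 s2T,     a1 s2T,     a1^2 s2T + s2Q]]

(compound-symmetric biomarker block from the classical error model, cross
terms scaled by the self-report slope).  Individuals outside the sub-study
contribute a univariate normal for ``Q`` alone.  The likelihood factorizes
over arms, so the fit works from per-arm sufficient statistics and is cheap
regardless of sample size.

Because the model is linear in first and second moments, the MLEs are moment
estimators and remain consistent under non-normal true intake; the
model-based variance does not, which is what the sandwich variance is for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .data import ErrorModelSpec, TrialDataset, ValidationError
from . import mom as _mom

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GroupParams:
    mu_t: float
    sigma2_t: float
    sigma2_m: float
    sigma2_q: float
    alpha0: float
    alpha1: float


def build_moments(params: GroupParams) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of ``(M1, M2, Q)`` for one arm."""
    if min(params.sigma2_t, params.sigma2_m, params.sigma2_q) < 0:
        raise ValueError("variance parameters must be non-negative")
    s2t, s2m, s2q = params.sigma2_t, params.sigma2_m, params.sigma2_q
    a0, a1, mu = params.alpha0, params.alpha1, params.mu_t
    mean = np.array([mu, mu, a0 + a1 * mu])
    cov = np.array([
        [s2t + s2m, s2t, a1 * s2t],
        [s2t, s2t + s2m, a1 * s2t],
        [a1 * s2t, a1 * s2t, a1**2 * s2t + s2q],
    ])
    return mean, cov


# ---------------------------------------------------------------------------
# free-parameter layout under an ErrorModelSpec
# ---------------------------------------------------------------------------


def param_names(spec: ErrorModelSpec) -> list[str]:
    names = ["mu_t1", "mu_t2"]
    names += ["sigma2_t"] if spec.equal_sigma_t else ["sigma2_t1", "sigma2_t2"]
    names += ["sigma2_m"] if spec.equal_sigma_m else ["sigma2_m1", "sigma2_m2"]
    if spec.is_differential:
        names += ["alpha0_1", "alpha1_1", "alpha0_2", "alpha1_2"]
    else:
        names += ["alpha0", "alpha1"]
    names += ["sigma2_q"] if spec.equal_sigma_q else ["sigma2_q1", "sigma2_q2"]
    return names


def _expand(theta: np.ndarray, spec: ErrorModelSpec) -> tuple[GroupParams, GroupParams]:
    it = iter(theta)
    mu1, mu2 = next(it), next(it)
    if spec.equal_sigma_t:
        s2t1 = s2t2 = next(it)
    else:
        s2t1, s2t2 = next(it), next(it)
    if spec.equal_sigma_m:
        s2m1 = s2m2 = next(it)
    else:
        s2m1, s2m2 = next(it), next(it)
    if spec.is_differential:
        a01, a11, a02, a12 = next(it), next(it), next(it), next(it)
    else:
        a01 = a02 = next(it)
        a11 = a12 = next(it)
    if spec.equal_sigma_q:
        s2q1 = s2q2 = next(it)
    else:
        s2q1, s2q2 = next(it), next(it)
    return (
        GroupParams(mu1, s2t1, s2m1, s2q1, a01, a11),
        GroupParams(mu2, s2t2, s2m2, s2q2, a02, a12),
    )


def _is_variance(name: str) -> bool:
    return name.startswith("sigma2")


def _to_working(theta: np.ndarray, names: list[str]) -> np.ndarray:
    z = theta.copy()
    for k, nm in enumerate(names):
        if _is_variance(nm):
            z[k] = np.log(max(theta[k], 1e-12))
    return z


def _from_working(z: np.ndarray, names: list[str]) -> np.ndarray:
    theta = z.copy()
    for k, nm in enumerate(names):
        if _is_variance(nm):
            theta[k] = np.exp(z[k])
    return theta


# ---------------------------------------------------------------------------
# sufficient statistics and log-likelihood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _GroupStats:
    n_sub: int
    mean3: np.ndarray      # sub-study mean of (M1, M2, Q)
    scatter: np.ndarray    # sum of centered outer products, 3x3
    n_out: int
    q_mean_out: float
    q_ss_out: float        # sum of squared deviations outside the sub-study


def _suff_stats(d: TrialDataset) -> list[_GroupStats]:
    out = []
    for g in (1, 2):
        in_g = d.group == g
        sub = in_g & d.in_substudy
        x = np.column_stack([d.m[sub, 0], d.m[sub, 1], d.q[sub]])
        if np.isnan(x).any():
            raise ValidationError("likelihood uses the first two replicates; missing in sub-study")
        mean3 = x.mean(axis=0)
        xc = x - mean3
        rest = in_g & ~d.in_substudy
        q_out = d.q[rest]
        out.append(_GroupStats(
            n_sub=x.shape[0],
            mean3=mean3,
            scatter=xc.T @ xc,
            n_out=q_out.size,
            q_mean_out=float(q_out.mean()) if q_out.size else 0.0,
            q_ss_out=float(((q_out - q_out.mean()) ** 2).sum()) if q_out.size else 0.0,
        ))
    return out


def _loglik(theta: np.ndarray, spec: ErrorModelSpec, stats_: list[_GroupStats]) -> float:
    total = 0.0
    for gp, st in zip(_expand(theta, spec), stats_):
        mean, cov = build_moments(gp)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            return -np.inf
        cinv = np.linalg.inv(cov)
        diff = st.mean3 - mean
        n = st.n_sub
        total += -0.5 * n * (3 * _LOG2PI + logdet) \
            - 0.5 * np.sum(cinv * st.scatter) \
            - 0.5 * n * diff @ cinv @ diff
        if st.n_out:
            v = gp.alpha1**2 * gp.sigma2_t + gp.sigma2_q
            if v <= 0:
                return -np.inf
            mu_q = gp.alpha0 + gp.alpha1 * gp.mu_t
            m = st.n_out
            total += -0.5 * m * (_LOG2PI + np.log(v)) \
                - 0.5 * (st.q_ss_out + m * (st.q_mean_out - mu_q) ** 2) / v
    return float(total)


def loglik(d: TrialDataset, theta: np.ndarray, spec: ErrorModelSpec) -> float:
    """Joint log-likelihood of the dataset at natural parameters ``theta``."""
    return _loglik(np.asarray(theta, float), spec, _suff_stats(d))


def _start_values(d: TrialDataset, spec: ErrorModelSpec) -> np.ndarray:
    """Moment-based starting values (MoM estimates where well defined)."""
    stats_ = _suff_stats(d)
    mu = [st.mean3[:2].mean() for st in stats_]
    s2t, s2m = [], []
    for st in stats_:
        cov = st.scatter / max(st.n_sub - 1, 1)
        s2t.append(max(cov[0, 1], 1e-3))
        s2m.append(max(0.5 * (cov[0, 0] + cov[1, 1]) - cov[0, 1], 1e-3))
    try:
        fit = fit_mom_for_start(d, spec)
        a0, a1, s2q = fit
    except Exception:
        a0 = [0.0, 0.0]
        a1 = [1.0, 1.0]
        s2q = [1.0, 1.0]
    theta = [mu[0], mu[1]]
    theta += [np.mean(s2t)] if spec.equal_sigma_t else s2t
    theta += [np.mean(s2m)] if spec.equal_sigma_m else s2m
    if spec.is_differential:
        theta += [a0[0], a1[0], a0[1], a1[1]]
    else:
        theta += [np.mean(a0), np.mean(a1)]
    theta += [np.mean(s2q)] if spec.equal_sigma_q else list(s2q)
    return np.array(theta, dtype=float)


def fit_mom_for_start(d: TrialDataset, spec: ErrorModelSpec):
    alphas = (_mom.estimate_alpha_differential(d) if spec.is_differential
              else _mom.estimate_alpha_nondifferential(d))
    if not alphas.valid:
        raise ValidationError("degenerate moments")
    _s2m, s2q = _mom.estimate_error_variances(d, spec, alphas)
    a0 = alphas.alpha0 if alphas.alpha0.size == 2 else np.repeat(alphas.alpha0, 2)
    a1 = alphas.alpha1 if alphas.alpha1.size == 2 else np.repeat(alphas.alpha1, 2)
    s2q = np.clip(s2q, 1e-3, None)
    s2q = s2q if s2q.size == 2 else np.repeat(s2q, 2)
    return list(a0), list(a1), list(s2q)


def _degenerate_fit(d: TrialDataset, spec: ErrorModelSpec,
                    stats_: list["_GroupStats"], names: list[str]) -> "MLFit":
    """Exact limit of the MLE when a measurement-error variance is zero.

    With noise-free data the likelihood is unbounded along a variance
    boundary but the location/slope estimates converge to plain moments:
    group means of the replicate averages, exact regression of Q on Mbar.
    """
    mu, s2t, s2m, s2q, a0, a1 = [], [], [], [], [], []
    for st in stats_:
        cov = st.scatter / st.n_sub       # n-denominator: the ML convention
        mbar_mean = st.mean3[:2].mean()
        v_mbar = 0.25 * (cov[0, 0] + cov[1, 1] + 2 * cov[0, 1])
        c_qm = 0.5 * (cov[0, 2] + cov[1, 2])
        slope = c_qm / v_mbar if v_mbar > 0 else 0.0
        mu.append(mbar_mean)
        s2t.append(max(cov[0, 1], 0.0))
        s2m.append(max(0.5 * (cov[0, 0] + cov[1, 1]) - cov[0, 1], 0.0))
        a1.append(slope)
        a0.append(st.mean3[2] - slope * mbar_mean)
        s2q.append(max(cov[2, 2] - slope * c_qm, 0.0))
    vals = {"mu_t1": mu[0], "mu_t2": mu[1],
            "sigma2_t": np.mean(s2t), "sigma2_t1": s2t[0], "sigma2_t2": s2t[1],
            "sigma2_m": np.mean(s2m), "sigma2_m1": s2m[0], "sigma2_m2": s2m[1],
            "sigma2_q": np.mean(s2q), "sigma2_q1": s2q[0], "sigma2_q2": s2q[1],
            "alpha0": np.mean(a0), "alpha0_1": a0[0], "alpha0_2": a0[1],
            "alpha1": np.mean(a1), "alpha1_1": a1[0], "alpha1_2": a1[1]}
    theta = np.array([vals[nm] for nm in names])
    p = len(names)
    return MLFit(spec=spec, names=names, theta=theta, loglik=np.inf,
                 vcov_model=np.full((p, p), np.nan), converged=True,
                 n_obs=len(d),
                 messages=["degenerate (noise-free) data: exact moment solution, "
                           "likelihood unbounded, no variance matrix"])


@dataclass
class MLFit:
    """Maximum-likelihood fit of the joint measurement model."""

    spec: ErrorModelSpec
    names: list[str]
    theta: np.ndarray              # natural-scale estimates, ordered as names
    loglik: float
    vcov_model: np.ndarray         # inverse observed information, natural scale
    converged: bool
    n_obs: int
    vcov_sandwich: np.ndarray | None = None
    messages: list[str] = field(default_factory=list)

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.theta)))

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def group_params(self) -> tuple[GroupParams, GroupParams]:
        return _expand(self.theta, self.spec)

    def _effect_contrast(self) -> np.ndarray:
        c = np.zeros(self.n_params)
        c[self.names.index("mu_t2")] = 1.0
        c[self.names.index("mu_t1")] = -1.0
        return c

    @property
    def effect(self) -> float:
        return float(self.params["mu_t2"] - self.params["mu_t1"])

    def effect_se(self, robust: bool = False) -> float:
        v = self.vcov_sandwich if robust else self.vcov_model
        if v is None:
            raise ValueError("sandwich variance not computed; call sandwich_vcov first")
        c = self._effect_contrast()
        return float(np.sqrt(c @ v @ c))

    def summary(self) -> str:
        lines = [f"ML fit ({self.spec.structure}), loglik = {self.loglik:.4f}, "
                 f"converged = {self.converged}"]
        ses = np.sqrt(np.clip(np.diag(self.vcov_model), 0, None))
        for nm, est, se in zip(self.names, self.theta, ses):
            lines.append(f"  {nm:>10s} = {est:10.4f}  (SE {se:.4f})")
        lines.append(f"  effect mu_t2 - mu_t1 = {self.effect:.4f} (SE {self.effect_se():.4f})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ses = np.sqrt(np.clip(np.diag(self.vcov_model), 0, None))
        out = {"structure": self.spec.structure, "loglik": self.loglik,
               "converged": self.converged, "effect": self.effect,
               "se_effect": self.effect_se()}
        for nm, est, se in zip(self.names, self.theta, ses):
            out[nm] = float(est)
            out[f"se_{nm}"] = float(se)
        return out


def fit_mle(d: TrialDataset, spec: ErrorModelSpec | None = None,
            start: np.ndarray | None = None) -> MLFit:
    """Maximize the joint likelihood (sub-study trivariate + main-study
    univariate contributions).

    Variances are optimized on the log scale to stay positive; the reported
    variance matrix is the inverse observed information on the natural scale.
    Non-convergence and near-boundary variances are flagged, not hidden.
    """
    spec = spec or ErrorModelSpec()
    stats_ = _suff_stats(d)
    names = param_names(spec)
    degenerate = any(
        np.linalg.eigvalsh(st.scatter / max(st.n_sub - 1, 1)).min()
        <= 1e-10 * max(np.trace(st.scatter) / max(st.n_sub - 1, 1), 1.0)
        for st in stats_)
    if degenerate:
        return _degenerate_fit(d, spec, stats_, names)
    theta0 = np.asarray(start, float) if start is not None else _start_values(d, spec)
    if theta0.size != len(names):
        raise ValueError(f"start vector needs {len(names)} entries {names}")
    z0 = _to_working(theta0, names)

    def nll(z: np.ndarray) -> float:
        return -_loglik(_from_working(z, names), spec, stats_)

    res = optimize.minimize(nll, z0, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    # polish with Nelder-Mead if the quasi-Newton step stalled
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-10,
                                          "maxiter": 20000})
        if res2.fun <= res.fun:
            res = res2
    theta_hat = _from_working(res.x, names)
    messages = []
    converged = bool(np.isfinite(res.fun))
    if not res.success:
        messages.append(f"optimizer: {res.message}")
    boundary = [nm for nm, v in zip(names, theta_hat) if _is_variance(nm) and v < 1e-8]
    if boundary:
        converged = False
        messages.append(f"variance at boundary: {boundary}")

    def nll_nat(t: np.ndarray) -> float:
        return -_loglik(t, spec, stats_)

    hess = approx_hess1(theta_hat, nll_nat)
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov = np.full((len(names), len(names)), np.nan)
        converged = False
        messages.append("singular observed information")
    return MLFit(spec=spec, names=names, theta=theta_hat, loglik=float(-res.fun),
                 vcov_model=vcov, converged=converged, n_obs=len(d),
                 messages=messages)


# ---------------------------------------------------------------------------
# robust variance and tests
# ---------------------------------------------------------------------------


def _individual_logliks(d: TrialDataset, theta: np.ndarray,
                        spec: ErrorModelSpec) -> np.ndarray:
    """Per-individual log-density contributions (vector of length N)."""
    out = np.empty(len(d))
    for g, gp in zip((1, 2), _expand(theta, spec)):
        mean, cov = build_moments(gp)
        in_g = d.group == g
        sub = in_g & d.in_substudy
        if sub.any():
            x = np.column_stack([d.m[sub, 0], d.m[sub, 1], d.q[sub]]) - mean
            cinv = np.linalg.inv(cov)
            _, logdet = np.linalg.slogdet(cov)
            out[sub] = -0.5 * (3 * _LOG2PI + logdet + np.einsum("ij,jk,ik->i", x, cinv, x))
        rest = in_g & ~d.in_substudy
        if rest.any():
            v = gp.alpha1**2 * gp.sigma2_t + gp.sigma2_q
            mu_q = gp.alpha0 + gp.alpha1 * gp.mu_t
            out[rest] = -0.5 * (_LOG2PI + np.log(v) + (d.q[rest] - mu_q) ** 2 / v)
    return out


def sandwich_vcov(d: TrialDataset, fit: MLFit) -> np.ndarray:
    """Robust variance ``A^{-1} B A^{-T}`` with ``A`` the (total) negative
    Hessian and ``B`` the sum of per-individual score outer products.

    Stores the result on ``fit.vcov_sandwich`` and returns it.  Valid for the
    point estimates under non-normal data, where the model-based variance is
    not.
    """
    if not fit.converged:
        raise ValueError("sandwich variance requires a converged fit")
    theta = fit.theta
    p = theta.size
    scores = np.empty((len(d), p))
    for k in range(p):
        h = 1e-5 * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        scores[:, k] = (_individual_logliks(d, tp, fit.spec)
                        - _individual_logliks(d, tm, fit.spec)) / (2 * h)
    b = scores.T @ scores
    stats_ = _suff_stats(d)

    def nll_nat(t: np.ndarray) -> float:
        return -_loglik(t, fit.spec, stats_)

    a = approx_hess1(theta, nll_nat)
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(f"bread matrix ill-conditioned (cond={cond:.3g})")
    a_inv = np.linalg.inv(a)
    fit.vcov_sandwich = a_inv @ b @ a_inv.T
    return fit.vcov_sandwich


def lrt(fit_full: MLFit, fit_restricted: MLFit, df: int | None = None):
    """Likelihood-ratio test of a nested restriction.

    Returns ``(statistic, p_value)`` with the statistic ``2 (l1 - l0)``
    referred to chi-square on ``df`` (defaults to the parameter-count
    difference).  A clearly negative statistic signals non-convergence of one
    of the fits and raises.
    """
    if df is None:
        df = fit_full.n_params - fit_restricted.n_params
    if df <= 0:
        raise ValueError("restricted model must have fewer parameters")
    stat = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    if stat < -1e-6 * (1.0 + abs(fit_full.loglik)):
        raise ValueError(f"negative LR statistic ({stat:.3g}): check convergence")
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def wald_differential_test(fit: MLFit):
    """Joint Wald test of ``alpha0_1 = alpha0_2`` and ``alpha1_1 = alpha1_2``
    from a differential-error fit.  Returns ``(statistic, p_value)`` on 2 df.
    """
    if not fit.spec.is_differential:
        raise ValueError("needs a differential-error fit")
    c = np.zeros((2, fit.n_params))
    c[0, fit.names.index("alpha0_1")] = 1.0
    c[0, fit.names.index("alpha0_2")] = -1.0
    c[1, fit.names.index("alpha1_1")] = 1.0
    c[1, fit.names.index("alpha1_2")] = -1.0
    diff = c @ fit.theta
    v = c @ fit.vcov_model @ c.T
    stat = float(diff @ np.linalg.solve(v, diff))
    return stat, float(stats.chi2.sf(stat, 2))
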