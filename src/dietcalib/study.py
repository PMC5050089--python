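"""Monte-Carlo operating characteristics of the effect estimators.

For each simulated replicate the intervention effect is estimated by:

* ``gold`` — biomarker-mean difference with biomarkers on 100% of individuals
  (the unmasked dataset); reference for relative efficiency,
* ``bio`` — biomarker-mean difference in the calibration sub-study only,
* ``mom_diff`` / ``mom_nondiff`` — the combined method-of-moments estimator
  under the differential / non-differential error structure,
* optionally ``ml_diff`` / ``ml_nondiff`` — the maximum-likelihood effect.

Scenario summaries report bias, MSE, empirical SD, mean model-based SE,
95%-CI coverage and efficiency relative to the gold standard, over the
replicates where a method's variance estimates were valid (degenerate
replicates are dropped per method and counted, never truncated).

One base dataset per replicate is shared across calibration fractions
(common random numbers), so sub-studies at different fractions are nested
views of the same trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ErrorModelSpec, TrialDataset
from .mom import estimate_theta_bio, fit_mom
from .mle import fit_mle
from .simulate import ScenarioConfig, mask_calibration, replicate_rng, simulate_full_trial

MOM_METHODS = ("bio", "mom_diff", "mom_nondiff")
ML_METHODS = ("ml_diff", "ml_nondiff")

_SPEC_DIFF = ErrorModelSpec("differential")
_SPEC_NONDIFF = ErrorModelSpec("nondifferential")


@dataclass(frozen=True)
class ReplicateResult:
    estimate: float
    se: float
    valid: bool


def analyze_replicate(full: TrialDataset, masked: TrialDataset,
                      include_ml: bool = False) -> dict[str, ReplicateResult]:
    """All per-replicate estimates, including the gold standard on ``full``."""
    out: dict[str, ReplicateResult] = {}
    est, var = estimate_theta_bio(full)
    out["gold"] = ReplicateResult(est, float(np.sqrt(var)), True)
    est, var = estimate_theta_bio(masked)
    out["bio"] = ReplicateResult(est, float(np.sqrt(var)), True)
    for name, spec in (("mom_diff", _SPEC_DIFF), ("mom_nondiff", _SPEC_NONDIFF)):
        fit = fit_mom(masked, spec)
        out[name] = ReplicateResult(fit.theta_combined, fit.se_combined, fit.valid)
    if include_ml:
        for name, spec in (("ml_diff", _SPEC_DIFF), ("ml_nondiff", _SPEC_NONDIFF)):
            fit = fit_mle(masked, spec)
            out[name] = ReplicateResult(fit.effect, fit.effect_se(), fit.converged)
    return out


def run_replicate(cfg: ScenarioConfig, rep_index: int,
                  include_ml: bool = False) -> dict[str, ReplicateResult]:
    """Simulate replicate ``rep_index`` of the scenario and estimate the
    effect with every method (deterministic given ``cfg.seed``)."""
    rng = replicate_rng(cfg.seed, rep_index)
    full = simulate_full_trial(cfg, rng)
    masked = mask_calibration(full, cfg.calib_fraction, rng)
    return analyze_replicate(full, masked, include_ml=include_ml)


@dataclass(frozen=True)
class ScenarioMetrics:
    method: str
    bias: float
    mse: float
    emp_sd: float
    model_se: float
    coverage: float      # percent
    efficiency: float    # percent, gold-standard variance / method variance
    n_valid: int


def summarize_method(estimates: np.ndarray, ses: np.ndarray, valid: np.ndarray,
                     gold_estimates: np.ndarray, true_effect: float,
                     method: str) -> ScenarioMetrics:
    """Operating characteristics over the valid replicates of one method; the
    efficiency numerator uses the gold-standard variance over the same set."""
    keep = np.asarray(valid, bool)
    n_valid = int(keep.sum())
    if n_valid < 2:
        raise ValueError(f"method {method}: fewer than 2 valid replicates")
    est = estimates[keep]
    se = ses[keep]
    gold = gold_estimates[keep]
    err = est - true_effect
    covered = np.abs(err) <= 1.96 * se
    with np.errstate(invalid="ignore", divide="ignore"):
        efficiency = float(100.0 * gold.var(ddof=1) / est.var(ddof=1))
    return ScenarioMetrics(
        method=method,
        bias=float(err.mean()),
        mse=float(np.mean(err**2)),
        emp_sd=float(est.std(ddof=1)),
        model_se=float(np.sqrt(np.mean(se**2))),
        coverage=float(100.0 * covered.mean()),
        efficiency=efficiency,
        n_valid=n_valid,
    )


def run_scenario(cfg: ScenarioConfig, fractions=None, include_ml: bool = False,
                 seed_key: int = 0):
    """Run ``cfg.n_reps`` replicates, analysing each at every calibration
    fraction with shared base data.

    Returns ``(raw, summary)``: ``raw`` maps ``(fraction, method)`` to arrays
    of estimates / SEs / validity (plus ``gold`` arrays), ``summary`` is a
    long-format DataFrame of :class:`ScenarioMetrics` rows.
    """
    fractions = list(fractions) if fractions is not None else [cfg.calib_fraction]
    methods = list(MOM_METHODS) + (list(ML_METHODS) if include_ml else [])
    r = cfg.n_reps
    gold_est = np.empty(r)
    gold_se = np.empty(r)
    store = {(f, m): (np.empty(r), np.empty(r), np.empty(r, dtype=bool))
             for f in fractions for m in methods}
    for rep in range(r):
        rng = replicate_rng(cfg.seed, seed_key, rep)
        full = simulate_full_trial(cfg, rng)
        est, var = estimate_theta_bio(full)
        gold_est[rep] = est
        gold_se[rep] = np.sqrt(var)
        for fi, f in enumerate(fractions):
            mask_rng = replicate_rng(cfg.seed, seed_key, rep, 1000 + fi)
            masked = mask_calibration(full, f, mask_rng)
            res = analyze_replicate(full, masked, include_ml=include_ml)
            for m in methods:
                e, s, v = store[(f, m)]
                e[rep] = res[m].estimate
                s[rep] = res[m].se
                v[rep] = res[m].valid
    raw = {"gold": (gold_est, gold_se)}
    rows = []
    for f in fractions:
        rows.append({"calib_fraction": f,
                     **summarize_method(gold_est, gold_se,
                                        np.ones(r, bool), gold_est,
                                        cfg.true_effect, "gold").__dict__})
        for m in methods:
            e, s, v = store[(f, m)]
            raw[(f, m)] = (e, s, v)
            rows.append({"calib_fraction": f,
                         **summarize_method(e, s, v, gold_est,
                                            cfg.true_effect, m).__dict__})
    summary = pd.DataFrame(rows)[
        ["calib_fraction", "method", "bias", "mse", "emp_sd", "model_se",
         "coverage", "efficiency", "n_valid"]]
    return raw, summary


def run_grid(base_cfg: ScenarioConfig, sigma2_q_values, fractions,
             structures=("differential", "nondifferential"),
             include_ml: bool = False) -> pd.DataFrame:
    """Cross error structures x self-report error variances x calibration
    fractions; one summary row per scenario cell and method."""
    from .simulate import DIFFERENTIAL_ALPHAS, NONDIFFERENTIAL_ALPHAS

    frames = []
    scen = 0
    for structure in structures:
        alphas = (DIFFERENTIAL_ALPHAS if structure == "differential"
                  else NONDIFFERENTIAL_ALPHAS)
        for s2q in sigma2_q_values:
            cfg = base_cfg.with_(alpha0=alphas["alpha0"], alpha1=alphas["alpha1"],
                                 sigma2_q=(s2q, s2q))
            _, summary = run_scenario(cfg, fractions=fractions,
                                      include_ml=include_ml, seed_key=scen)
            summary.insert(0, "sigma2_q", s2q)
            summary.insert(0, "structure", structure)
            frames.append(summary)
            scen += 1
    return pd.concat(frames, ignore_index=True)


def format_table(summary: pd.DataFrame) -> str:
    """Human-readable scenario table (one block per scenario cell)."""
    lines = []
    keys = [c for c in ("structure", "sigma2_q", "calib_fraction") if c in summary]
    for vals, block in summary.groupby(keys, sort=False):
        vals = vals if isinstance(vals, tuple) else (vals,)
        lines.append("  ".join(f"{k}={v}" for k, v in zip(keys, vals)))
        lines.append(f"  {'method':<14s} {'bias':>7s} {'mse':>7s} {'emp_sd':>7s} "
                     f"{'model_se':>8s} {'cov':>6s} {'eff':>6s} {'n':>5s}")
        for _, row in block.iterrows():
            lines.append(
                f"  {row['method']:<14s} {row['bias']:7.3f} {row['mse']:7.3f} "
                f"{row['emp_sd']:7.3f} {row['model_se']:8.3f} "
                f"{row['coverage']:6.1f} {row['efficiency']:6.1f} {row['n_valid']:5d}")
        lines.append("")
    return "\n".join(lines)
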