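"""Synthetic trial generator.

Emulates a two-arm dietary intervention trial: true intake ``T`` is drawn per
arm, a single self-report ``Q = alpha0_i + alpha1_i T + eps_Q`` is observed
for everyone, and two biomarker replicates ``Mk = T + eps_M`` are observed
only inside a calibration sub-study (a stratified random fraction of each
arm).  Defaults reproduce the reference operating-characteristics study:
500 individuals per arm, ``muT = (4.6, 4.1)`` (intervention effect -0.5),
``sigma2_T = 0.1``, ``sigma2_M = 0.2``, and differential self-report error
``alpha = (0.3, 0.8)`` / ``(1.5, 0.5)`` with ``sigma2_Q = 0.09``.

An optional skewed-truth generator (gamma family, shift/scaled to the target
mean and variance) probes robustness to non-normal intake; it is a
configurable stand-in for an unspecified skewed family, with the normal model
recovered at skewness zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .data import TrialDataset, ValidationError

#: arm-specific defaults for the two canonical error structures
DIFFERENTIAL_ALPHAS = {"alpha0": (0.3, 1.5), "alpha1": (0.8, 0.5)}
NONDIFFERENTIAL_ALPHAS = {"alpha0": (0.9, 0.9), "alpha1": (0.65, 0.65)}


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings for one simulation scenario."""

    mu_t: tuple[float, float] = (4.6, 4.1)
    alpha0: tuple[float, float] = DIFFERENTIAL_ALPHAS["alpha0"]
    alpha1: tuple[float, float] = DIFFERENTIAL_ALPHAS["alpha1"]
    sigma2_t: tuple[float, float] = (0.1, 0.1)
    sigma2_m: tuple[float, float] = (0.2, 0.2)
    sigma2_q: tuple[float, float] = (0.09, 0.09)
    n_per_group: int = 500
    calib_fraction: float = 0.10
    n_reps: int = 1000
    seed: int = 0
    truth_distribution: str = "normal"   # or "nonnormal"
    skewness: float = 0.0                # gamma-family skewness when nonnormal

    def __post_init__(self) -> None:
        for name in ("sigma2_t", "sigma2_m", "sigma2_q"):
            if min(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.calib_fraction <= 1:
            raise ValueError("calib_fraction must lie in (0, 1]")
        if round(self.n_per_group * self.calib_fraction) < 3:
            raise ValueError("calibration sub-study needs >= 3 members per arm")
        if self.truth_distribution not in ("normal", "nonnormal"):
            raise ValueError(f"unknown truth_distribution {self.truth_distribution!r}")
        if self.truth_distribution == "nonnormal" and self.skewness < 0:
            raise ValueError("skewness must be >= 0 for the gamma family")

    @property
    def true_effect(self) -> float:
        return self.mu_t[1] - self.mu_t[0]

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def differential(cls, **kwargs) -> "ScenarioConfig":
        return cls(**{**DIFFERENTIAL_ALPHAS, **kwargs})

    @classmethod
    def nondifferential(cls, **kwargs) -> "ScenarioConfig":
        return cls(**{**NONDIFFERENTIAL_ALPHAS, **kwargs})


def replicate_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic independent substream for (scenario, replicate, ...) keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def _draw_truth(cfg: ScenarioConfig, mu: float, s2: float, n: int,
                rng: np.random.Generator) -> np.ndarray:
    if cfg.truth_distribution == "normal" or cfg.skewness == 0:
        return rng.normal(mu, np.sqrt(s2), size=n)
    # gamma with shape k has skewness 2/sqrt(k); standardize then shift/scale
    k = 4.0 / cfg.skewness**2
    g = rng.gamma(shape=k, scale=1.0, size=n)
    return mu + np.sqrt(s2) * (g - k) / np.sqrt(k)


def simulate_trial(cfg: ScenarioConfig, rng: np.random.Generator) -> TrialDataset:
    """Generate one fully observed trial (both biomarkers for everyone) and
    mask it to the configured calibration fraction.

    Returns the masked dataset; use :func:`simulate_full_trial` +
    :func:`mask_calibration` to keep the unmasked data for gold-standard
    comparisons.
    """
    full = simulate_full_trial(cfg, rng)
    return mask_calibration(full, cfg.calib_fraction, rng)


def simulate_full_trial(cfg: ScenarioConfig, rng: np.random.Generator) -> TrialDataset:
    """Generate the trial with biomarker replicates observed for everyone."""
    groups, qs, ms = [], [], []
    n = cfg.n_per_group
    for i in (0, 1):
        t = _draw_truth(cfg, cfg.mu_t[i], cfg.sigma2_t[i], n, rng)
        q = cfg.alpha0[i] + cfg.alpha1[i] * t + rng.normal(0, np.sqrt(cfg.sigma2_q[i]), n)
        m = t[:, None] + rng.normal(0, np.sqrt(cfg.sigma2_m[i]), (n, 2))
        groups.append(np.full(n, i + 1))
        qs.append(q)
        ms.append(m)
    return TrialDataset(group=np.concatenate(groups), q=np.concatenate(qs),
                        m=np.vstack(ms))


def mask_calibration(d: TrialDataset, fraction: float,
                     rng: np.random.Generator) -> TrialDataset:
    """Retain biomarkers for a simple random ``round(fraction * n_g)`` members
    of each arm (stratified, so sub-study sizes are non-random); all other
    rows get fully missing biomarkers.  The input dataset is not modified.
    """
    if not 0 < fraction <= 1:
        raise ValueError("calibration fraction must lie in (0, 1]")
    m = d.m.copy()
    for g in (1, 2):
        idx = np.flatnonzero(d.group == g)
        keep = round(fraction * idx.size)
        if keep < 3:
            raise ValidationError(
                f"calibration fraction {fraction} leaves < 3 sub-study members in arm {g}")
        kept = rng.choice(idx, size=keep, replace=False)
        dropped = np.setdiff1d(idx, kept)
        m[dropped, :] = np.nan
    return TrialDataset(group=d.group.copy(), q=d.q.copy(), m=m)


def simulate_nonnormal_trial(cfg: ScenarioConfig, rng: np.random.Generator) -> TrialDataset:
    """Convenience wrapper: force the skewed-truth generator."""
    if cfg.truth_distribution != "nonnormal":
        cfg = cfg.with_(truth_distribution="nonnormal")
    return simulate_trial(cfg, rng)
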