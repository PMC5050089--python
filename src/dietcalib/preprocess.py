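"""Pre-modelling transformations.

Dietary measurements are typically right-skewed; a power transform (exponent
chosen externally, e.g. by a Box-Cox analysis) brings them close to normal.
Urinary biomarkers recover only a known fraction of intake (86% for sodium),
so biomarker values are rescaled by that excretion fraction before modelling.
"""

from __future__ import annotations

import numpy as np

from .data import TrialDataset

DEFAULT_LAMBDA = 0.3
DEFAULT_EXCRETION_FRACTION = 1.0


def power_transform(x, lam: float):
    """Element-wise ``x ** lam`` for strictly positive ``x`` and ``lam != 0``."""
    if lam == 0:
        raise ValueError("power exponent must be nonzero (use a log transform instead)")
    x = np.asarray(x, dtype=float)
    if np.nanmin(x, initial=np.inf) <= 0:
        raise ValueError("power transform requires strictly positive values")
    return x**lam

def scale_biomarker(m, excretion_fraction: float):
    """Rescale biomarker values to the intake scale: ``m / excretion_fraction``."""
    if not 0 < excretion_fraction <= 1:
        raise ValueError("excretion fraction must lie in (0, 1]")
    return np.asarray(m, dtype=float) / excretion_fraction


def preprocess_dataset(
    d: TrialDataset,
    lam: float = 1.0,
    excretion_fraction: float = DEFAULT_EXCRETION_FRACTION,
) -> TrialDataset:
    """Apply the reference workflow: rescale biomarkers by the excretion
    fraction first, then power-transform all measurements.

    ``lam=1`` and ``excretion_fraction=1`` leave the data unchanged.
    """
    m = scale_biomarker(d.m, excretion_fraction)
    q = d.q
    if lam != 1.0:
        q = power_transform(q, lam)
        with np.errstate(invalid="ignore"):
            m = np.where(np.isnan(m), np.nan, np.power(np.where(np.isnan(m), 1.0, m), lam))
        if np.nanmin(d.m, initial=np.inf) <= 0:
            raise ValueError("power transform requires strictly positive biomarkers")
    return TrialDataset(group=d.group.copy(), q=q, m=m)
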