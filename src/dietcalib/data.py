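"""Trial data container, validation and CSV I/O.

A two-arm trial measures a dietary outcome in every randomized individual by
self-report (``Q``) and, inside a calibration sub-study, by ``K >= 2``
replicate unbiased biomarker measurements (``M1 .. MK``, e.g. 24-h urinary
sodium).  Group labels are ``1`` (control) and ``2`` (intervention).
Sub-study membership is not stored separately: an individual is in the
sub-study exactly when at least two biomarker replicates are observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = (1, 2)


class ValidationError(ValueError):
    """Raised when a dataset violates the trial-data invariants."""


@dataclass(frozen=True)
class ErrorModelSpec:
    """Assumed structure of the self-report error model.

    Parameters
    ----------
    structure:
        ``"differential"`` lets the intercept/slope of the self-report model
        differ by treatment arm; ``"nondifferential"`` ties them
        (``alpha0_1 = alpha0_2`` and ``alpha1_1 = alpha1_2``).
    equal_sigma_t, equal_sigma_m, equal_sigma_q:
        Tie the true-intake / biomarker-error / self-report-error variances
        across arms (likelihood fits only; method-of-moments estimation pools
        moments under the non-differential structure instead).
    """

    structure: str = "differential"
    equal_sigma_t: bool = False
    equal_sigma_m: bool = False
    equal_sigma_q: bool = False

    def __post_init__(self) -> None:
        if self.structure not in ("differential", "nondifferential"):
            raise ValueError(f"unknown error structure: {self.structure!r}")

    @property
    def is_differential(self) -> bool:
        return self.structure == "differential"


@dataclass
class TrialDataset:
    """Per-individual trial data.

    Attributes
    ----------
    group:
        integer arm label per individual, 1 = control, 2 = intervention.
    q:
        self-report outcome per individual (analysis scale), never missing.
    m:
        ``(N, K)`` biomarker replicate matrix; ``NaN`` marks missing.  Rows
        outside the calibration sub-study are entirely missing.
    """

    group: np.ndarray
    q: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int)
        self.q = np.asarray(self.q, dtype=float)
        self.m = np.atleast_2d(np.asarray(self.m, dtype=float))
        if self.m.shape[0] != self.group.shape[0]:
            self.m = self.m.T
        if not (self.group.shape[0] == self.q.shape[0] == self.m.shape[0]):
            raise ValidationError("group, q and m must have one row per individual")

    # -- derived structure -------------------------------------------------
    @property
    def n_replicates(self) -> int:
        return self.m.shape[1]

    @property
    def in_substudy(self) -> np.ndarray:
        """Boolean mask: at least two non-missing biomarker replicates."""
        return (~np.isnan(self.m)).sum(axis=1) >= 2

    def n_total(self, group: int) -> int:
        return int(np.sum(self.group == group))

    def n_substudy(self, group: int) -> int:
        return int(np.sum((self.group == group) & self.in_substudy))

    def __len__(self) -> int:
        return self.group.shape[0]

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        cols = {"group": self.group, "q": self.q}
        for k in range(self.n_replicates):
            cols[f"m{k + 1}"] = self.m[:, k]
        return pd.DataFrame(cols)


def validate_dataset(d: TrialDataset) -> list[str]:
    """Return a list of invariant violations (empty when the dataset is valid).

    Reports, never raises; use :func:`require_valid` to raise.
    """
    problems: list[str] = []
    bad_groups = sorted(set(np.unique(d.group)) - set(GROUPS))
    if bad_groups:
        problems.append(f"group labels outside {{1, 2}}: {bad_groups}")
    if np.isnan(d.q).any():
        rows = np.flatnonzero(np.isnan(d.q))
        problems.append(f"missing self-report q in rows {rows.tolist()[:10]}")
    n_obs = (~np.isnan(d.m)).sum(axis=1)
    partial = np.flatnonzero((n_obs > 0) & (n_obs < 2))
    if partial.size:
        problems.append(
            "rows with a single biomarker replicate (need >= 2 or none): "
            f"{partial.tolist()[:10]}"
        )
    for g in GROUPS:
        if d.n_total(g) < 2:
            problems.append(f"group {g} has fewer than 2 members")
        elif d.n_substudy(g) < 2:
            problems.append(f"group {g} has fewer than 2 calibration sub-study members")
    return problems


def require_valid(d: TrialDataset) -> TrialDataset:
    problems = validate_dataset(d)
    if problems:
        raise ValidationError("; ".join(problems))
    return d


def load_trial_csv(path, k: int | None = None) -> TrialDataset:
    """Read a trial dataset from CSV.

    Expected header ``group,q,m1,m2[,...mK]``; missing biomarker cells are
    empty or the literal ``NA``.  ``k`` optionally fixes the replicate count
    (defaults to the number of ``m*`` columns present).
    """
    df = pd.read_csv(path, na_values=["NA"])
    df.columns = [c.strip().lower() for c in df.columns]
    if k is None:
        k = sum(c.startswith("m") and c[1:].isdigit() for c in df.columns)
    needed = ["group", "q"] + [f"m{j + 1}" for j in range(k)]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing columns in {path}: {missing_cols}")
    d = TrialDataset(
        group=df["group"].to_numpy(),
        q=df["q"].to_numpy(dtype=float),
        m=df[[f"m{j + 1}" for j in range(k)]].to_numpy(dtype=float),
    )
    return require_valid(d)


def write_trial_csv(d: TrialDataset, path) -> None:
    """Write a dataset in the same CSV schema read by :func:`load_trial_csv`."""
    d.to_dataframe().to_csv(path, index=False, na_rep="")
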