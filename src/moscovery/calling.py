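"""Binary mLOY calling from the cohort coverage distribution.

The carrier threshold is the lower Tukey fence of the scaled chrY coverage
distribution, Q1 - 1.5 x IQR — the standard outlier rule; samples strictly
below it are mLOY carriers.  The fence is translation-equivariant, so calls
are identical whether made before or after the cohort rescale.  For broad
distributions (e.g. tumors) where the statistical fence drops implausibly
low, a fixed cell-fraction cutoff is the documented alternative: a carrier
is any sample whose implied cell fraction reaches the cutoff, i.e.
cov_scaled <= 0.5 - cf_cut/2.  Single-sample calling reuses a stored cohort
calibration from the same capture kit.

Quantiles use linear interpolation between order statistics (numpy's
default, R type 7) everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cellfraction import cf_from_coverage, coverage_from_cf
from .errors import CohortSizeError, KitMismatchError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MloyCall:
    sample_id: str
    is_mloy: bool
    threshold_used: float
    mode: str  # cohort | single_sample | fixed_cf
    cov_scaled: float | None = None


def derive_outlier_threshold(values, multiplier: float = 1.5) -> float:
    """Lower Tukey fence Q1 - multiplier x IQR of a cohort distribution.

    Quartiles by linear interpolation.  A degenerate distribution (IQR = 0)
    warns and returns Q1.
    """
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("degenerate coverage distribution: IQR = 0; threshold = Q1")
        return float(q1)
    return float(q1 - multiplier * iqr)


def _ids_and_values(estimates) -> tuple[list[str], np.ndarray]:
    """Accept a list of SampleEstimate, a DataFrame with cov_scaled, or a
    Series of cov_scaled indexed by sample id."""
    if isinstance(estimates, pd.DataFrame):
        return [str(i) for i in estimates.index], estimates["cov_scaled"].to_numpy(float)
    if isinstance(estimates, pd.Series):
        return [str(i) for i in estimates.index], estimates.to_numpy(float)
    ids = [e.sample_id for e in estimates]
    vals = np.array([e.cov_scaled for e in estimates], dtype=float)
    if np.isnan(vals).any():
        raise ValueError("estimates lack cov_scaled; rescale the cohort first")
    return ids, vals


def call_cohort(estimates, threshold: float) -> list[MloyCall]:
    """Binary calls: carrier iff cov_scaled is strictly below the threshold."""
    ids, vals = _ids_and_values(estimates)
    return [
        MloyCall(sample_id=i, is_mloy=bool(v < threshold),
                 threshold_used=float(threshold), mode="cohort", cov_scaled=float(v))
        for i, v in zip(ids, vals)
    ]


def call_fixed_cf(estimates, cf_cut: float) -> list[MloyCall]:
    """Carrier iff the implied cell fraction reaches ``cf_cut``.

    Equivalent to cov_scaled <= 0.5 - cf_cut/2 (inclusive: a sample exactly
    at the cutoff carries exactly cf_cut of cells).
    """
    if not (0 < cf_cut < 1):
        raise ValidationError(f"cf_cut must be in (0, 1), got {cf_cut}")
    cut = coverage_from_cf(cf_cut)
    ids, vals = _ids_and_values(estimates)
    # compared on the coverage scale (v <= cut), exactly equivalent to
    # cf_from_coverage(v) >= cf_cut but free of round-off at the boundary
    return [
        MloyCall(sample_id=i, is_mloy=bool(v <= cut),
                 threshold_used=float(cut), mode="fixed_cf", cov_scaled=float(v))
        for i, v in zip(ids, vals)
    ]


def single_sample_call(
    cov_raw: float,
    calibration,
    sample_id: str = "sample",
    kit_id: str | None = None,
    allow_kit_mismatch: bool = False,
):
    """Call one sample against a stored cohort calibration.

    Applies the calibration's shift (cov_scaled = cov_raw - median_raw +
    0.5) and compares on the raw scale: carrier iff cov_raw is strictly
    below threshold_raw (identical to the scaled comparison).  Panels and
    coverage profiles are kit-specific, so a calibration from a different
    capture kit is refused unless explicitly overridden.
    """
    from .normalize import SampleEstimate  # local import avoids a cycle

    if kit_id is not None and kit_id != calibration.kit_id:
        msg = (
            f"sample kit {kit_id!r} != calibration kit {calibration.kit_id!r}; "
            "normalized chrY coverage and its threshold are kit-dependent"
        )
        if not allow_kit_mismatch:
            raise KitMismatchError(msg)
        warnings.warn(msg)
    cov_scaled = cov_raw - calibration.median_raw + 0.5
    est = SampleEstimate(
        sample_id=sample_id, cov_raw=cov_raw, cov_scaled=cov_scaled, n_exons_used=0
    )
    call = MloyCall(
        sample_id=sample_id,
        is_mloy=bool(cov_raw < calibration.threshold_raw),
        threshold_used=float(calibration.threshold_raw),
        mode="single_sample",
        cov_scaled=float(cov_scaled),
    )
    return call, est


def calls_to_frame(calls: Sequence[MloyCall]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "cov_scaled": [c.cov_scaled for c in calls],
            "cell_fraction": [
                None if c.cov_scaled is None else cf_from_coverage(c.cov_scaled)
                for c in calls
            ],
            "is_mloy": [c.is_mloy for c in calls],
            "mode": [c.mode for c in calls],
            "threshold": [c.threshold_used for c in calls],
        }
    )
    return df.set_index("sample_id")


def write_calls(calls: Sequence[MloyCall], path: str | Path,
                header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        calls_to_frame(calls).to_csv(fh, sep="\t")


class MloyCaller(BaseEstimator):
    """Sklearn-style binary mLOY classifier on scaled chrY coverage.

    fit(X) derives the decision threshold from the cohort distribution —
    the lower Tukey fence (``rule="iqr"``) or a fixed cell-fraction cutoff
    (``rule="fixed_cf"``, which needs no fitting data beyond validation).
    predict(X) returns a boolean carrier array for scaled coverage values.

    X is a 1-d array/Series of cov_scaled, or an (n, 1) column.
    """

    def __init__(self, rule: str = "iqr", iqr_multiplier: float = 1.5,
                 cf_cut: float | None = None, min_cohort_size: int = 50):
        self.rule = rule
        self.iqr_multiplier = iqr_multiplier
        self.cf_cut = cf_cut
        self.min_cohort_size = min_cohort_size

    @staticmethod
    def _column(X) -> np.ndarray:
        arr = np.asarray(getattr(X, "to_numpy", lambda: X)(), dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr.ravel()
        if arr.ndim != 1:
            raise ValidationError(f"expected a single coverage column, got shape {arr.shape}")
        return arr

    def fit(self, X, y=None):
        vals = self._column(X)
        if self.rule == "iqr":
            if len(vals) < self.min_cohort_size:
                raise CohortSizeError(
                    f"cohort of {len(vals)} below min_cohort_size={self.min_cohort_size}"
                )
            self.threshold_ = derive_outlier_threshold(vals, self.iqr_multiplier)
        elif self.rule == "fixed_cf":
            if self.cf_cut is None:
                raise ValidationError("rule='fixed_cf' requires cf_cut")
            self.threshold_ = float(coverage_from_cf(self.cf_cut))
        else:
            raise ValidationError(f"unknown rule {self.rule!r}")
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        vals = self._column(X)
        if self.rule == "fixed_cf":
            return vals <= self.threshold_
        return vals < self.threshold_
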