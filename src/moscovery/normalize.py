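"""Normalized chrY coverage per sample and cohort rescaling.

Each chrY exon's median depth is divided by the median depth of its matched
autosomal exons; the median of those ratios is the sample's normalized chrY
coverage (cov_raw).  Because every diploid cell carries one chrY against two
copies of each autosome, a sample without chrY loss is expected near 0.5,
and the cohort is rescaled so its median sits exactly at 0.5 (cov_scaled =
cov_raw - cohort median + 0.5), the haploid expectation required for cell
fraction estimation.  Rescaling is a per-cohort shift: it never changes the
ranking of samples, and cohorts sequenced with different kits or in
different batches must be rescaled separately before pooling.

The cohort step is exposed as the sklearn-style transformer
:class:`CoverageNormalizer`: ``fit`` learns the cohort median (the reusable
calibration), ``transform`` maps depth matrices — including later
single-sample ones — onto the calibrated scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .calling import derive_outlier_threshold
from .errors import CohortSizeError, NormalizationError
from .regions import MatchTable

logger = logging.getLogger(__name__)


@dataclass
class SampleEstimate:
    """Per-sample normalized chrY coverage.

    ``cov_raw`` is the pre-scaling ratio; ``cov_scaled`` is filled once a
    cohort (or stored calibration) provides the median shift.
    """

    sample_id: str
    cov_raw: float
    cov_scaled: float | None = None
    n_exons_used: int = 0
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cov_raw < 0:
            raise ValueError(f"cov_raw must be >= 0, got {self.cov_raw}")


@dataclass
class CohortCalibration:
    """Reusable cohort calibration for single-sample calling.

    Stores the population median of cov_raw and the binary threshold on both
    scales (threshold_raw = threshold_scaled + median_raw - 0.5); the two
    comparisons are algebraically identical.
    """

    kit_id: str
    median_raw: float
    threshold_scaled: float
    n_samples: int

    def __post_init__(self) -> None:
        if not self.threshold_scaled < 0.5:
            raise ValueError(
                f"threshold_scaled must be < 0.5, got {self.threshold_scaled}"
            )

    @property
    def threshold_raw(self) -> float:
        return self.threshold_scaled + self.median_raw - 0.5

    def write(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["threshold_raw"] = self.threshold_raw
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "CohortCalibration":
        doc = json.loads(Path(path).read_text())
        doc.pop("threshold_raw", None)
        return cls(**doc)


def normalize_sample(
    depths: Mapping[str, float] | pd.Series,
    matches: MatchTable,
    sample_id: str = "sample",
    max_missing_fraction: float = 0.2,
) -> SampleEstimate:
    """Normalized chrY coverage (cov_raw) for one sample.

    For each chrY exon e: ratio_e = depth(e) / median(depth over e's matched
    autosomal exons); cov_raw is the median of the ratios.  Exons with
    missing depth, or whose matched-set median is 0, are dropped and
    flagged; if every exon drops, raises :class:`NormalizationError`.
    """
    depths = pd.Series(depths, dtype=float)
    ratios: list[float] = []
    flags: set[str] = set()
    n_missing = 0
    for yid, matched in matches.entries.items():
        d_y = depths.get(yid, np.nan)
        if np.isnan(d_y):
            n_missing += 1
            continue
        med = np.nanmedian(depths.reindex(matched).to_numpy())
        if np.isnan(med):
            n_missing += 1
            continue
        if med == 0:
            flags.add("zero_matched_median")
            continue
        ratios.append(d_y / med)
    n_panel = len(matches.entries)
    if n_missing and n_missing > max_missing_fraction * n_panel:
        flags.add("high_missing")
    if not ratios:
        raise NormalizationError(
            f"sample {sample_id!r}: no chrY exon usable for normalization"
        )
    return SampleEstimate(
        sample_id=sample_id,
        cov_raw=float(np.median(ratios)),
        n_exons_used=len(ratios),
        qc_flags=sorted(flags),
    )


def normalize_cohort(
    depth: pd.DataFrame,
    matches: MatchTable,
    max_missing_fraction: float = 0.2,
) -> list[SampleEstimate]:
    """Vectorized :func:`normalize_sample` over a samples x exons matrix.

    Identical arithmetic (per-exon ratio to the matched-set median, then the
    median of ratios), evaluated as one samples x chrY-exons x matches
    array; the scalar path is kept as the per-sample reference.
    """
    chry_ids = list(matches.entries)
    all_ids = chry_ids + matches.autosomal_exon_ids
    vals_df = depth.reindex(columns=all_ids)
    col_pos = {c: i for i, c in enumerate(vals_df.columns)}
    vals = vals_df.to_numpy(dtype=float)
    y_idx = np.array([col_pos[c] for c in chry_ids])
    m_idx = np.array([[col_pos[a] for a in matches.entries[yid]] for yid in chry_ids])

    d_y = vals[:, y_idx]                              # (n, n_y)
    with warnings_ignored():
        med_a = np.nanmedian(vals[:, m_idx], axis=2)  # (n, n_y)
    missing = np.isnan(d_y) | np.isnan(med_a)
    zero_med = ~missing & (med_a == 0)
    valid = ~missing & ~zero_med
    ratios = np.where(valid, d_y / np.where(valid, med_a, 1.0), np.nan)

    n_y = len(chry_ids)
    out: list[SampleEstimate] = []
    for i, sid in enumerate(depth.index):
        if not valid[i].any():
            raise NormalizationError(
                f"sample {sid!r}: no chrY exon usable for normalization"
            )
        flags: set[str] = set()
        if zero_med[i].any():
            flags.add("zero_matched_median")
        if missing[i].any() and missing[i].sum() > max_missing_fraction * n_y:
            flags.add("high_missing")
        out.append(
            SampleEstimate(
                sample_id=str(sid),
                cov_raw=float(np.nanmedian(ratios[i])),
                n_exons_used=int(valid[i].sum()),
                qc_flags=sorted(flags),
            )
        )
    return out


class warnings_ignored:
    """Silence the all-NaN-slice RuntimeWarning from nanmedian."""

    def __enter__(self):
        import warnings

        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        warnings.simplefilter("ignore", RuntimeWarning)
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


def rescale_cohort(
    estimates: Sequence[SampleEstimate],
    min_cohort_size: int = 50,
    kit_id: str = "unknown",
    iqr_multiplier: float = 1.5,
) -> tuple[list[SampleEstimate], CohortCalibration]:
    """Shift a cohort so its median cov_scaled is exactly 0.5.

    Also derives the cohort's binary threshold (lower Tukey fence on the
    scaled values) and returns both as a reusable calibration.  Refuses
    cohorts below ``min_cohort_size``: medians and quartiles from small
    cohorts are unstable — use single-sample mode with a stored calibration
    instead.
    """
    if len(estimates) < min_cohort_size:
        raise CohortSizeError(
            f"cohort of {len(estimates)} is below the minimum of {min_cohort_size} "
            "for rescaling/thresholding; use single_sample_call with a stored "
            "calibration instead"
        )
    raw = np.array([e.cov_raw for e in estimates])
    median_raw = float(np.median(raw))
    out = [
        SampleEstimate(
            sample_id=e.sample_id,
            cov_raw=e.cov_raw,
            cov_scaled=e.cov_raw - median_raw + 0.5,
            n_exons_used=e.n_exons_used,
            qc_flags=list(e.qc_flags),
        )
        for e in estimates
    ]
    scaled = np.array([e.cov_scaled for e in out])
    threshold = derive_outlier_threshold(scaled, multiplier=iqr_multiplier)
    cal = CohortCalibration(
        kit_id=kit_id,
        median_raw=median_raw,
        threshold_scaled=float(threshold),
        n_samples=len(out),
    )
    return out, cal


def combine_batches(
    per_batch_estimates: Mapping[str, Sequence[SampleEstimate]],
    min_cohort_size: int = 50,
) -> list[SampleEstimate]:
    """Rescale each batch independently, then pool.

    Batches sequenced with different kits or in different runs carry
    batch-level coverage shifts; scaling must happen within batch, never
    after pooling.  Batches below the minimum size are excluded with a
    warning.
    """
    pooled: list[SampleEstimate] = []
    for batch_id, ests in per_batch_estimates.items():
        if len(ests) < min_cohort_size:
            logger.warning(
                "combine_batches: batch %r has %d samples (< %d), excluded",
                batch_id, len(ests), min_cohort_size,
            )
            continue
        rescaled, _ = rescale_cohort(ests, min_cohort_size=min_cohort_size, kit_id=batch_id)
        pooled.extend(rescaled)
    return pooled


def estimates_to_frame(estimates: Sequence[SampleEstimate]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in estimates],
            "cov_raw": [e.cov_raw for e in estimates],
            "cov_scaled": [e.cov_scaled for e in estimates],
            "n_exons_used": [e.n_exons_used for e in estimates],
            "qc_flags": [";".join(e.qc_flags) or "." for e in estimates],
        }
    )
    return df.set_index("sample_id")


def write_estimates(
    estimates: Sequence[SampleEstimate], path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        estimates_to_frame(estimates).to_csv(fh, sep="\t")


def read_estimates(path: str | Path) -> list[SampleEstimate]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    return [
        SampleEstimate(
            sample_id=str(sid),
            cov_raw=row["cov_raw"],
            cov_scaled=None if pd.isna(row["cov_scaled"]) else row["cov_scaled"],
            n_exons_used=int(row["n_exons_used"]),
            qc_flags=[] if row["qc_flags"] == "." else str(row["qc_flags"]).split(";"),
        )
        for sid, row in df.iterrows()
    ]


class CoverageNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from depth matrices to chrY coverage.

    fit(X) computes cov_raw for every sample of a cohort depth matrix
    (samples x exon ids; a CoverageTable's ``depth``) and learns the cohort
    median — the calibration.  transform(X) returns a DataFrame with
    ``cov_raw``, ``cov_scaled`` (= cov_raw - median_ + 0.5), ``n_exons_used``
    and ``qc_flags`` per sample; after fitting it applies equally to new,
    even single-sample, matrices on the same kit.

    Parameters
    ----------
    match_table : MatchTable
        chrY exon -> matched autosomal exon ids.
    min_cohort_size : int
        Minimum number of samples required to fit (learn the median).
    max_missing_fraction : float
        Per-sample fraction of panel exons allowed missing before the
        ``high_missing`` QC flag is raised.
    """

    def __init__(
        self,
        match_table: MatchTable | None = None,
        min_cohort_size: int = 50,
        max_missing_fraction: float = 0.2,
    ):
        self.match_table = match_table
        self.min_cohort_size = min_cohort_size
        self.max_missing_fraction = max_missing_fraction

    def _estimates(self, X) -> list[SampleEstimate]:
        if self.match_table is None:
            raise ValueError("CoverageNormalizer requires a match_table")
        df = getattr(X, "depth", X)
        return normalize_cohort(
            df, self.match_table, max_missing_fraction=self.max_missing_fraction
        )

    def fit(self, X, y=None):
        ests = self._estimates(X)
        if len(ests) < self.min_cohort_size:
            raise CohortSizeError(
                f"cohort of {len(ests)} is below min_cohort_size="
                f"{self.min_cohort_size}"
            )
        self.cov_raw_ = np.array([e.cov_raw for e in ests])
        self.median_ = float(np.median(self.cov_raw_))
        self.n_samples_ = len(ests)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "median_")
        ests = self._estimates(X)
        for e in ests:
            e.cov_scaled = e.cov_raw - self.median_ + 0.5
        return estimates_to_frame(ests)
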