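"""Concordance between two mLOY call sets or quantitative estimates.

Binary agreement is summarized as a 2x2 table (both-positive, first-only,
second-only, both-negative) with the cross-product odds ratio and Fisher's
exact two-sided p value (probability-mass rule, margins fixed).
Quantitative estimates are compared with Pearson correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwo:
    """Cross-tabulation of two binary call sets over the same samples."""

    a: int  # both positive
    b: int  # first only
    c: int  # second only
    d: int  # both negative

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _as_bool_map(calls) -> dict[str, bool]:
    if isinstance(calls, Mapping):
        return {str(k): bool(v) for k, v in calls.items()}
    if isinstance(calls, pd.Series):
        return {str(k): bool(v) for k, v in calls.items()}
    return {c.sample_id: bool(c.is_mloy) for c in calls}


def build_2x2(calls_a, calls_b) -> TwoByTwo:
    """Cross-tabulate two call sets on their shared samples.

    Accepts lists of calls, mappings, or boolean Series keyed by sample id.
    Samples present in only one set are excluded and logged; an empty
    intersection is an error.
    """
    ma, mb = _as_bool_map(calls_a), _as_bool_map(calls_b)
    common = set(ma) & set(mb)
    if not common:
        raise ValidationError("the two call sets share no sample ids")
    dropped = (set(ma) | set(mb)) - common
    if dropped:
        logger.warning("build_2x2: %d samples present in only one set, excluded", len(dropped))
    a = b = c = d = 0
    for s in common:
        if ma[s] and mb[s]:
            a += 1
        elif ma[s]:
            b += 1
        elif mb[s]:
            c += 1
        else:
            d += 1
    return TwoByTwo(a, b, c, d)


def odds_ratio_fisher(t: TwoByTwo) -> tuple[float, float]:
    """Cross-product odds ratio and two-sided exact p for a 2x2 table.

    OR = (a*d)/(b*c) with no continuity correction; a zero off-diagonal
    product yields an infinite OR with a warning.  The p value sums
    hypergeometric probabilities no larger than the observed table's, with
    margins fixed.
    """
    if t.b * t.c == 0:
        warnings.warn("zero off-diagonal cell: odds ratio is infinite")
        oratio = float("inf")
    else:
        oratio = (t.a * t.d) / (t.b * t.c)
    _, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return float(oratio), float(p)


def estimate_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Product-moment correlation between paired estimates, with p value."""
    if method != "pearson":
        raise ValidationError(f"unsupported method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d and paired")
    if len(x) < 3:
        raise ValidationError("correlation needs at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
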