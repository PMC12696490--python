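"""Closed-form conversions between chrY dosage signals and mLOY cell fraction.

Two signals index chrY dosage: normalized scaled chrY coverage (covY;
expected 0.5 when every diploid cell retains its single chrY) and the median
log-R ratio over MSY genotyping probes (mLRRY; expected 0 without loss).  If
a fraction CF of cells lack chrY, expected chrY dosage is (1 - CF) of the
haploid level, giving

    covY  = 0.5 * (1 - CF)            =>  CF = 1 - 2 * covY
    mLRRY = log2(1 - CF) / 2          =>  CF = 1 - 2 ** (2 * mLRRY)

Internally cell fractions are fractions in [0, 1]; the mLRRY conversion is
conventionally reported in percent, controlled by ``as_percent``.
Values outside the physical domain clamp silently to the nearest bound.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def cf_from_coverage(covy):
    """Fraction of cells with mLOY implied by normalized scaled chrY coverage.

    Piecewise: 0 for covY >= 0.5, 1 for covY <= 0, else 1 - 2*covY.
    Accepts scalars or arrays; total on the reals.
    """
    covy = np.asarray(covy, dtype=float)
    cf = np.clip(1.0 - 2.0 * covy, 0.0, 1.0)
    return cf.item() if cf.ndim == 0 else cf


def cf_from_mlrry(mlrry, as_percent: bool = True):
    """Fraction of cells with mLOY implied by the median log-R ratio over MSY.

    CF(%) = 100 * (1 - 2 ** (2 * mLRRY)), clamped to [0, 100]; positive
    mLRRY (a gain signal) clamps to 0.
    """
    mlrry = np.asarray(mlrry, dtype=float)
    cf = np.clip(1.0 - 2.0 ** (2.0 * mlrry), 0.0, 1.0)
    if as_percent:
        cf = 100.0 * cf
    return cf.item() if cf.ndim == 0 else cf


def coverage_from_cf(cf):
    """Normalized scaled chrY coverage corresponding to a cell fraction.

    Inverse of :func:`cf_from_coverage` on [0, 1]: covY = 0.5 - CF/2.
    """
    arr = np.asarray(cf, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError(f"cell fraction outside [0, 1]: {cf}")
    covy = 0.5 - arr / 2.0
    return covy.item() if covy.ndim == 0 else covy
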