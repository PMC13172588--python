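"""Closed-form bench-assay formulas.

Small, exact calculations used alongside the sequencing analyses:
wound-healing migration rate, 3D spheroid invasion area, the composite
immunohistochemistry (IHC) score, and relative qPCR quantification by
2^-ddCt.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["migration_rate", "invasion_area", "ihc_score", "area_grade", "ddct_fold"]

# Staining-area bands -> grade. Left-open/right-closed: exactly 5% is still
# grade 0, strictly above 5% begins grade 1, and so on; >75% is grade 4.
AREA_BANDS = (0.05, 0.25, 0.50, 0.75)


def migration_rate(w0: float, w1: float) -> float:
    """Wound-closure migration rate in percent: ``(w0 - w1) / w0 * 100``.

    ``w0`` is the initial wound width, ``w1`` the final width (same units;
    the result is a pure ratio). Negative rates (wound widening) are
    reported with a warning, not clamped.
    """
    if w0 <= 0:
        raise ValueError("initial wound width w0 must be positive")
    if w1 < 0:
        raise ValueError("final wound width w1 must be non-negative")
    rate = (w0 - w1) / w0 * 100.0
    if rate < 0:
        warnings.warn("negative migration rate: wound widened", stacklevel=2)
    return rate


def invasion_area(i0: float, i1: float) -> float:
    """Spheroid invasion area: final area minus initial area (sign preserved)."""
    if i0 < 0 or i1 < 0:
        raise ValueError("spheroid areas must be non-negative")
    diff = i1 - i0
    if diff < 0:
        warnings.warn("negative invasion area: spheroid shrank", stacklevel=2)
    return diff


def area_grade(area_fraction: float) -> int:
    """Grade (0-4) of the stained area fraction.

    Bands: 0 for (0, 5%], 1 for (5%, 25%], 2 for (25%, 50%],
    3 for (50%, 75%], 4 for >75%.
    """
    if not 0.0 <= area_fraction <= 1.0:
        raise ValueError("area_fraction must lie in [0, 1]")
    grade = 0
    for bound in AREA_BANDS:
        if area_fraction > bound:
            grade += 1
    return grade


def ihc_score(area_fraction: float, intensity_grade: int) -> int:
    """Composite IHC score: area grade (0-4) times intensity grade (0-3).

    The score ranges from 0 to 12.
    """
    if intensity_grade not in (0, 1, 2, 3):
        raise ValueError("intensity_grade must be one of {0, 1, 2, 3}")
    return area_grade(area_fraction) * intensity_grade


def ddct_fold(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression fold change by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    fold = 2**(-ddCt). Adding a constant to every Ct leaves the fold
    unchanged, and swapping case/control inverts it.
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
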