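"""Brain-age-gap stratification.

The brain-age gap (estimated brain age minus chronological age) is
z-transformed over the provided cohort and thresholded at +-threshold
standard deviations: subjects above the upper cut form the accelerated
maturation group, those below the lower cut the delayed group, and the
middle band is excluded from the two-group analysis.  At the conventional
threshold of 0.41 SD each extreme group captures roughly the top / bottom
third of a normal cohort (1 - Phi(0.41) ~ 0.341).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["zscore_gaps", "partition_by_gap", "assign_groups",
           "GROUP_CODES", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.41

#: numeric coding used by the association models
GROUP_CODES = {"accelerated": 3, "delayed": 2}


def zscore_gaps(gaps) -> np.ndarray:
    """Z-transform gaps with the population-SD convention (divide by n).

    Raises ``ValueError`` on fewer than two values or zero variance.
    """
    g = np.asarray(gaps, dtype=float).ravel()
    if g.size < 2:
        raise ValueError("need at least two gap values to z-transform")
    sd = g.std()  # population convention (ddof=0)
    if sd == 0.0:
        raise ValueError("gap vector has zero variance; z-transform undefined")
    return (g - g.mean()) / sd


def partition_by_gap(z, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Label z-scored gaps: accelerated (z > t), delayed (z < -t), else excluded.

    Inequalities are strict, so boundary values fall in the excluded band.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(z, dtype=float).ravel()
    return np.where(z > threshold, "accelerated",
                    np.where(z < -threshold, "delayed", "excluded"))


def assign_groups(metadata: pd.DataFrame, gap_column: str = "gap",
                  threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Return a copy of ``metadata`` with the group column (re)computed
    from the z-transformed gap column."""
    out = metadata.copy()
    z = zscore_gaps(out[gap_column].to_numpy())
    out["group"] = partition_by_gap(z, threshold)
    return out
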