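"""Library coverage and evenness diagnostics.

Coverage is the fraction of designed guides seen at least once. Evenness is
the ratio of the 90th to the 10th percentile of counts among *detected*
guides, using the nearest-rank percentile convention, so it is >= 1 and
scale-invariant.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = ["coverage", "evenness", "nearest_rank_percentile", "qc_table"]

MIN_DETECTED_FOR_EVENNESS = 10


def coverage(raw: np.ndarray, n_designed: int) -> float:
    """Fraction of designed guides with raw count > 0."""
    if n_designed <= 0:
        raise ValueError("n_designed must be positive")
    raw = np.asarray(raw)
    return float((raw > 0).sum()) / n_designed


def nearest_rank_percentile(sorted_values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile of an ascending-sorted array (1-based rank ceil(p/100*n))."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty array")
    rank = max(1, math.ceil(pct / 100.0 * n))
    return float(sorted_values[rank - 1])


def evenness(raw: np.ndarray) -> float:
    """90th / 10th nearest-rank percentile of detected (non-zero) guide counts.

    Returns NaN with a warning when fewer than 10 guides are detected.
    """
    raw = np.asarray(raw)
    detected = np.sort(raw[raw > 0])
    if len(detected) < MIN_DETECTED_FOR_EVENNESS:
        warnings.warn(
            f"evenness undefined: only {len(detected)} guides detected", stacklevel=2
        )
        return float("nan")
    p90 = nearest_rank_percentile(detected, 90)
    p10 = nearest_rank_percentile(detected, 10)
    return p90 / p10


def qc_table(counts: pd.DataFrame, n_designed: int) -> pd.DataFrame:
    """Per-library QC report (coverage, evenness, detection counts)."""
    rows = []
    for lib in counts.columns:
        col = counts[lib].to_numpy()
        cov = coverage(col, n_designed)
        rows.append(
            {
                "library_id": lib,
                "n_designed": n_designed,
                "n_detected": int((col > 0).sum()),
                "coverage": cov,
                "lost_fraction": 1.0 - cov,
                "evenness": evenness(col),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["library_id", "n_designed", "n_detected", "coverage", "lost_fraction", "evenness"],
    )
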