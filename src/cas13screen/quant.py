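"""Exact-match spacer counting from amplicon reads and abundance transforms.

A read counts toward a guide when it contains the 28-mer spacer or its
reverse complement as an exact substring, at most once per guide per read.
Counts are normalized per library after converting zeros to 1, then taken
to log2 space; all downstream contrasts are differences of log2 values, so
the counts-per-million scale factor cancels.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from cas13screen._seq import reverse_complement
from cas13screen.errors import LibraryFailedError
from cas13screen.io import read_fastq

logger = logging.getLogger(__name__)

__all__ = [
    "build_spacer_index",
    "count_exact",
    "count_reads",
    "normalize",
    "log2_abundance",
    "count_table",
    "normalize_table",
    "log2_table",
]


def build_spacer_index(spacers: Sequence[str]) -> dict[str, frozenset[int]]:
    """Map every spacer and its reverse complement to the guide indices it hits.

    Distinct guides normally never share a k-mer (the manifest forbids
    duplicate spacers) but corrupted input may; such k-mers map to several
    guides and each gets incremented, with a warning at count time.
    """
    index: dict[str, set[int]] = {}
    for i, spacer in enumerate(spacers):
        for key in (spacer, reverse_complement(spacer)):
            index.setdefault(key, set()).add(i)
    return {k: frozenset(v) for k, v in index.items()}


def count_reads(
    reads: Iterable[str],
    spacers: Sequence[str],
    *,
    index: dict[str, frozenset[int]] | None = None,
) -> np.ndarray:
    """Count reads containing each spacer (either orientation) exactly.

    Each read contributes at most once per guide, even if the spacer occurs
    multiple times in the read.
    """
    if index is None:
        index = build_spacer_index(spacers)
    k = len(spacers[0]) if spacers else 0
    counts = np.zeros(len(spacers), dtype=np.int64)
    for read in reads:
        seq = read.upper()
        hits: set[int] = set()
        for j in range(len(seq) - k + 1):
            guides = index.get(seq[j : j + k])
            if guides:
                hits.update(guides)
        if len(hits) > 1:
            logger.warning("read matches %d distinct guides", len(hits))
        for g in hits:
            counts[g] += 1
    return counts


def count_exact(fastq_path, manifest: pd.DataFrame) -> pd.Series:
    """One count-table column from a FASTQ file, indexed by guide_id."""
    spacers = manifest["spacer"].tolist()
    reads: Iterator[str] = (seq for _rid, seq, _q in read_fastq(fastq_path))
    counts = count_reads(reads, spacers)
    if counts.sum() == 0:
        logger.warning("no spacer matches in %s (empty or foreign FASTQ)", fastq_path)
    return pd.Series(counts, index=manifest["guide_id"].to_numpy(), name=str(fastq_path))


def normalize(raw: np.ndarray, scale: float = 1e6) -> np.ndarray:
    """Zero-replaced, total-normalized abundances.

    Zeros become 1 *before* the total is taken; each value is then divided by
    the post-replacement total and multiplied by ``scale`` (CPM by default;
    ``scale=1`` gives fractions summing to 1).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("normalize expects a single library column")
    if (raw < 0).any():
        raise ValueError("negative counts")
    if not (raw > 0).any():
        raise LibraryFailedError("all-zero count column: library failed")
    replaced = np.where(raw == 0, 1.0, raw)
    return replaced / replaced.sum() * scale


def log2_abundance(values: np.ndarray) -> np.ndarray:
    """Elementwise log2; inputs must be strictly positive (zeros were replaced upstream)."""
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("non-positive abundance: zero handling was skipped upstream")
    return np.log2(values)


def count_table(metadata: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Raw guides x libraries count table from per-library FASTQ paths."""
    cols = {}
    for _, row in metadata.iterrows():
        cols[row["library_id"]] = count_exact(row["fastq"], manifest).to_numpy()
    return pd.DataFrame(cols, index=manifest["guide_id"].to_numpy())


def normalize_table(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    return counts.apply(lambda col: normalize(col.to_numpy(), scale), axis=0)


def log2_table(normalized: pd.DataFrame) -> pd.DataFrame:
    return normalized.apply(lambda col: log2_abundance(col.to_numpy()), axis=0)
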