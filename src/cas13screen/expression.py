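"""Drug-induced expression fold changes and target-selection tiers.

FC = log2((NRC_drug + 1) / (NRC_DMSO + 1)) per gene, drug and timepoint.
Strong tier: FC > 0.58 at both timepoints for at least one drug. Weak
tier: FC > 0 at both timepoints for at least one drug, excluding strong.
Thresholds are strict (>). Also reported: the subset strong in >= 2 drugs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fold_change",
    "fc_table",
    "select_targets",
    "compare_fc_groups",
    "GroupComparison",
]

STRONG_FC = 0.58
WEAK_FC = 0.0
TIMEPOINTS = ("3h", "6h")


def fold_change(nrc_drug, nrc_dmso):
    """log2((nrc_drug + 1) / (nrc_dmso + 1)); inputs must be non-negative."""
    a = np.asarray(nrc_drug, dtype=float)
    b = np.asarray(nrc_dmso, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("normalized read counts must be non-negative")
    out = np.log2((a + 1.0) / (b + 1.0))
    return float(out) if out.ndim == 0 else out


def fc_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per gene x drug x timepoint fold changes from a long NRC table.

    ``records`` columns: gene_id, condition, timepoint, nrc; every
    (gene, drug, timepoint) needs a matched DMSO row.
    """
    required = {"gene_id", "condition", "timepoint", "nrc"}
    if not required.issubset(records.columns):
        raise ValueError(f"missing columns: {sorted(required - set(records.columns))}")
    dmso = records[records["condition"] == "DMSO"].set_index(["gene_id", "timepoint"])["nrc"]
    drugs = records[records["condition"] != "DMSO"]
    rows = []
    for (gene, drug, tp), grp in drugs.groupby(["gene_id", "condition", "timepoint"]):
        if (gene, tp) not in dmso.index:
            raise ValueError(f"no DMSO baseline for {gene} at {tp}")
        rows.append(
            {
                "gene_id": gene,
                "drug": drug,
                "timepoint": tp,
                "fc": fold_change(grp["nrc"].mean(), dmso.loc[(gene, tp)]),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "drug", "timepoint", "fc"])


def select_targets(
    fc: pd.DataFrame,
    strong: float = STRONG_FC,
    weak: float = WEAK_FC,
    timepoints: tuple[str, str] = TIMEPOINTS,
) -> pd.DataFrame:
    """Tier each gene: strong / weak / none, plus a multi-drug flag.

    strong: FC > ``strong`` at both timepoints for >= 1 drug;
    weak: FC > ``weak`` at both timepoints for >= 1 drug, not strong;
    multi_drug: strong condition met for >= 2 drugs.
    Genes missing a timepoint for every drug are skipped with a warning.
    """
    rows = []
    for gene, gene_grp in fc.groupby("gene_id"):
        n_strong = 0
        n_weak = 0
        n_complete = 0
        for _drug, drug_grp in gene_grp.groupby("drug"):
            by_tp = drug_grp.set_index("timepoint")["fc"]
            if not all(tp in by_tp.index for tp in timepoints):
                continue
            n_complete += 1
            both = [float(by_tp.loc[tp]) for tp in timepoints]
            if all(v > strong for v in both):
                n_strong += 1
            if all(v > weak for v in both):
                n_weak += 1
        if n_complete == 0:
            warnings.warn(f"{gene}: no drug with both timepoints, skipped", stacklevel=2)
            continue
        tier = "strong" if n_strong >= 1 else ("weak" if n_weak >= 1 else "none")
        rows.append(
            {
                "gene_id": gene,
                "tier": tier,
                "n_drugs_strong": n_strong,
                "multi_drug": n_strong >= 2,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "tier", "n_drugs_strong", "multi_drug"])


@dataclass(frozen=True)
class GroupComparison:
    median_a: float
    median_b: float
    t_stat: float
    p: float
    n_a: int
    n_b: int
    degenerate: bool = False


def compare_fc_groups(fc_a, fc_b) -> GroupComparison:
    """Two-sided pooled-variance two-sample t-test between fold-change sets."""
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return GroupComparison(
            float(np.median(a)), float(np.median(b)), np.nan, np.nan, a.size, b.size, True
        )
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        float(np.median(a)), float(np.median(b)), float(t_stat), float(p), a.size, b.size
    )
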