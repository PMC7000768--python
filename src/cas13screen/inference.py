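"""Three-level screen inference.

Level 1: per guide, D - ND — the difference of log2 normalized abundance
between a +Dox library and its matched -Dox library (matched on drug,
batch, split).
Level 2: per guide pair, T - MT — the targeting guide's D - ND minus its
mismatch control's, which cancels sequence-independent Dox effects.
Level 3: per transcript and drug, the median T - MT over all pairs and
replicates, a paired t-test of targeting vs mismatch D - ND values, and
Benjamini-Hochberg adjustment across the transcripts tested for that drug.

Significance calls use a permissive (raw p < alpha) and a strict
(BH-adjusted p < alpha) threshold; adjusted p in [alpha, 2*alpha) is
annotated as marginal.

A note on sidedness: the test direction is not known a priori (both
depletion and enrichment are of interest), so the natural procedure —
one-sided paired t in the direction of the observed mean — has size
2*alpha, not alpha. The default ``alternative="auto"`` therefore reports
the observed-direction one-tail probability doubled (capped at 1), which
restores size alpha and is numerically the two-sided p; the direction is
reported alongside. Pure one-sided tests are available via
``alternative="less"``/``"greater"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cas13screen.errors import PairingError

__all__ = [
    "TestResult",
    "ScreenResult",
    "pair_libraries",
    "dox_contrast",
    "pair_contrast",
    "transcript_summary",
    "transcript_test",
    "adjust_bh",
    "call_transcripts",
    "run_screen",
]


@dataclass(frozen=True)
class TestResult:
    n: int
    t_stat: float
    df: int
    p: float
    direction: str  # depleted | enriched | ns
    tested: bool
    note: str = ""


@dataclass
class ScreenResult:
    guide_contrasts: pd.DataFrame
    pair_contrasts: pd.DataFrame
    calls: pd.DataFrame
    bh_family_sizes: dict


def pair_libraries(metadata: pd.DataFrame) -> pd.DataFrame:
    """Match each +Dox library to the -Dox library with the same (drug, batch, split).

    Only ``post_challenge`` libraries participate when a ``stage`` column is
    present. Unmatched libraries raise PairingError listing the orphans.
    """
    meta = metadata
    if "stage" in meta.columns:
        meta = meta[meta["stage"] == "post_challenge"]
    key = ["drug", "batch", "split"]
    plus = meta[meta["dox"] == "plus"].set_index(key)["library_id"]
    minus = meta[meta["dox"] == "minus"].set_index(key)["library_id"]
    orphans = sorted(
        list(plus[~plus.index.isin(minus.index)])
        + list(minus[~minus.index.isin(plus.index)])
    )
    if orphans:
        raise PairingError(f"unpaired libraries: {orphans}")
    if plus.index.duplicated().any() or minus.index.duplicated().any():
        raise PairingError("duplicate (drug, batch, split) within an arm")
    pairs = pd.DataFrame(
        {
            "plus_library": plus,
            "minus_library": minus.reindex(plus.index),
        }
    ).reset_index()
    return pairs.sort_values(key).reset_index(drop=True)


def dox_contrast(d: np.ndarray, nd: np.ndarray) -> np.ndarray:
    """Elementwise D - ND for a matched (+Dox, -Dox) library pair in log2 space."""
    d = np.asarray(d, dtype=float)
    nd = np.asarray(nd, dtype=float)
    if d.shape != nd.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {nd.shape}")
    return d - nd


def pair_contrast(targeting: np.ndarray, mismatch: np.ndarray) -> np.ndarray:
    """T - MT: targeting D - ND minus mismatch D - ND, same replicate key."""
    targeting = np.asarray(targeting, dtype=float)
    mismatch = np.asarray(mismatch, dtype=float)
    if targeting.shape != mismatch.shape:
        raise ValueError(f"shape mismatch: {targeting.shape} vs {mismatch.shape}")
    return targeting - mismatch


def transcript_summary(values: np.ndarray) -> float:
    """Median T - MT over all pairs x replicates for one transcript and drug."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no T - MT values")
    return float(np.median(values))


def transcript_test(
    t_values: np.ndarray,
    mt_values: np.ndarray,
    alternative: str = "auto",
) -> TestResult:
    """Paired t-test of targeting vs mismatch D - ND values.

    Vectors must be elementwise paired by (pair, replicate). See the module
    docstring for the ``alternative`` semantics; ``"auto"`` is size-alpha.
    """
    t_values = np.asarray(t_values, dtype=float)
    mt_values = np.asarray(mt_values, dtype=float)
    if t_values.shape != mt_values.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = t_values - mt_values
    n = diffs.size
    if n < 2:
        return TestResult(n, np.nan, 0, np.nan, "ns", False, "n < 2")
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        return TestResult(n, np.nan, n - 1, np.nan, "ns", False, "zero variance")
    t_stat = mean / (sd / np.sqrt(n))
    df = n - 1
    if alternative == "auto":
        p = min(1.0, 2.0 * stats.t.sf(abs(t_stat), df))
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * stats.t.sf(abs(t_stat), df))
    elif alternative == "less":
        p = stats.t.cdf(t_stat, df)
    elif alternative == "greater":
        p = stats.t.sf(t_stat, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    direction = "depleted" if mean < 0 else ("enriched" if mean > 0 else "ns")
    return TestResult(n, float(t_stat), df, float(p), direction, True)


def adjust_bh(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement.

    NaN entries (untested transcripts) are ignored and returned as NaN; the
    family size is the number of finite p-values.
    """
    p = np.asarray(p_raw, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values outside [0,1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    unsorted = np.empty(m)
    unsorted[order] = adjusted
    out[mask] = unsorted
    return out


def call_transcripts(
    median_t_mt: float,
    p_raw: float,
    p_adj: float,
    alpha: float = 0.05,
    marginal_upper: float = 0.1,
) -> tuple[str, str, bool]:
    """(permissive call, strict call, marginal flag) for one transcript/drug.

    Permissive uses raw p, strict uses adjusted p; the sign of the median
    T - MT sets depleted vs enriched. The marginal flag marks adjusted p in
    [alpha, marginal_upper).
    """
    if np.isnan(p_raw):
        return "untested", "untested", False

    def _call(p: float) -> str:
        if p < alpha and median_t_mt != 0:
            return "depleted" if median_t_mt < 0 else "enriched"
        return "ns"

    marginal = bool(alpha <= p_adj < marginal_upper) if not np.isnan(p_adj) else False
    return _call(p_raw), _call(p_adj), marginal


def run_screen(
    log2_abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = 0.05,
    alternative: str = "auto",
) -> ScreenResult:
    """Full three-level inference from a guides x libraries log2 table.

    Returns per-guide D - ND contrasts, per-pair T - MT contrasts and the
    per-transcript call table; BH families are formed per drug.
    """
    pairs_meta = pair_libraries(metadata)
    man = manifest.set_index("guide_id")
    targeting = manifest[manifest["role"] == "targeting"].set_index("pair_id")
    mismatch = manifest[manifest["role"] == "mismatch"].set_index("pair_id")
    pair_ids = targeting.index.to_numpy()
    guide_ids = log2_abundance.index.to_numpy()
    gpos = {g: i for i, g in enumerate(guide_ids)}

    guide_rows = []
    pair_rows = []
    per_drug_calls: list[dict] = []

    for drug, grp in pairs_meta.groupby("drug", sort=True):
        rep_keys = list(zip(grp["batch"], grp["split"]))
        d_cols = log2_abundance[grp["plus_library"].tolist()].to_numpy()
        nd_cols = log2_abundance[grp["minus_library"].tolist()].to_numpy()
        dnd = dox_contrast(d_cols, nd_cols)  # guides x reps

        for gi, guide in enumerate(guide_ids):
            for ri, (batch, split) in enumerate(rep_keys):
                guide_rows.append(
                    {
                        "guide_id": guide,
                        "drug": drug,
                        "batch": batch,
                        "split": split,
                        "d_nd": dnd[gi, ri],
                    }
                )

        t_idx = np.array([gpos[targeting.loc[p, "guide_id"]] for p in pair_ids])
        mt_idx = np.array([gpos[mismatch.loc[p, "guide_id"]] for p in pair_ids])
        t_mat = dnd[t_idx, :]  # pairs x reps
        mt_mat = dnd[mt_idx, :]
        tmt = pair_contrast(t_mat, mt_mat)

        for pi, pid in enumerate(pair_ids):
            tx = targeting.loc[pid, "transcript_id"]
            for ri, (batch, split) in enumerate(rep_keys):
                pair_rows.append(
                    {
                        "pair_id": pid,
                        "transcript_id": tx,
                        "drug": drug,
                        "batch": batch,
                        "split": split,
                        "t_mt": tmt[pi, ri],
                    }
                )

        tx_of_pair = targeting["transcript_id"].reindex(pair_ids).to_numpy()
        for tx in pd.unique(tx_of_pair):
            sel = tx_of_pair == tx
            t_vec = t_mat[sel, :].ravel()
            mt_vec = mt_mat[sel, :].ravel()
            res = transcript_test(t_vec, mt_vec, alternative=alternative)
            per_drug_calls.append(
                {
                    "transcript_id": tx,
                    "drug": drug,
                    "n_pairs": int(sel.sum()),
                    "n_values": res.n,
                    "median_t_mt": transcript_summary(tmt[sel, :].ravel()),
                    "t_stat": res.t_stat,
                    "direction": res.direction,
                    "p_raw": res.p,
                    "tested": res.tested,
                    "note": res.note,
                }
            )

    calls = pd.DataFrame(per_drug_calls)
    bh_family_sizes: dict = {}
    calls["p_adj"] = np.nan
    for drug, grp in calls.groupby("drug"):
        adj = adjust_bh(grp["p_raw"].to_numpy())
        calls.loc[grp.index, "p_adj"] = adj
        bh_family_sizes[drug] = int(np.sum(~np.isnan(grp["p_raw"].to_numpy())))

    permissive, strict, marginal = [], [], []
    for _, row in calls.iterrows():
        cp, cs, mg = call_transcripts(
            row["median_t_mt"], row["p_raw"], row["p_adj"], alpha=alpha
        )
        permissive.append(cp)
        strict.append(cs)
        marginal.append(mg)
    calls["call_permissive"] = permissive
    calls["call_strict"] = strict
    calls["marginal"] = marginal
    calls = calls[
        [
            "transcript_id",
            "drug",
            "n_pairs",
            "n_values",
            "median_t_mt",
            "t_stat",
            "direction",
            "p_raw",
            "p_adj",
            "call_permissive",
            "call_strict",
            "marginal",
            "tested",
            "note",
        ]
    ]
    return ScreenResult(
        guide_contrasts=pd.DataFrame(
            guide_rows, columns=["guide_id", "drug", "batch", "split", "d_nd"]
        ),
        pair_contrasts=pd.DataFrame(
            pair_rows,
            columns=["pair_id", "transcript_id", "drug", "batch", "split", "t_mt"],
        ),
        calls=calls,
        bh_family_sizes=bh_family_sizes,
    )
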