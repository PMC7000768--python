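"""Synthetic-data generators with recorded ground truth.

Emulates the measured structure of a pooled Cas13 survival screen: a
paired targeting/mismatch guide library, recursive drug-treatment rounds
acting multiplicatively on per-cell survival, a Dox-dependent knockdown
effect applied to targeting guides only (scaled by a per-guide efficacy)
and optionally to mismatch guides via a residual-activity factor, the
3-batch x 2-split replicate layout, and multinomial sequencing with
negative-binomial overdispersion. Everything is deterministic under a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from cas13screen import design as _design
from cas13screen.errors import PopulationExtinctError

__all__ = [
    "DrugModel",
    "SimulationDesign",
    "SimulatedScreen",
    "DEFAULT_DRUGS",
    "bottleneck_percent",
    "percent",
    "random_transcript",
    "simulate_manifest",
    "simulate_screen_counts",
    "simulate_reads",
    "simulate_expression",
    "FLANK5",
    "FLANK3",
]

# Survival fractions are the minimum-population fractions observed for each
# drug (49.8%, 90.0%, 9.4%); rounds are the treatment/recovery cycles used.
@dataclass(frozen=True)
class DrugModel:
    survival: float
    rounds: int

    def __post_init__(self) -> None:
        if not (0 < self.survival <= 1):
            raise ValueError("survival must be in (0,1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


DEFAULT_DRUGS: dict[str, DrugModel] = {
    "imatinib": DrugModel(0.498, 5),
    "mirin": DrugModel(0.900, 4),
    "etoposide": DrugModel(0.094, 1),
}


def bottleneck_percent(min_cells: float, start_cells: float) -> float:
    """Minimum surviving-cell percentage, rounded to one decimal."""
    if start_cells <= 0:
        raise ValueError("start_cells must be positive")
    return round(100.0 * min_cells / start_cells, 1)


def percent(numerator: float, denominator: float) -> int:
    """Percentage rounded to the nearest integer."""
    return round(100.0 * numerator / denominator)


@dataclass
class SimulationDesign:
    """Everything needed to generate one synthetic screen.

    ``effects`` maps (transcript_id, drug) to a Dox-dependent log2 survival
    effect applied to targeting guides (negative = transcript needed for
    survival). Per-guide efficacies are Beta(``efficacy_beta``) multipliers;
    mismatch guides carry ``mismatch_activity`` (rho, default 0 = inert).
    """

    n_vlinc: int = 25
    pairs_per_vlinc: int = 10
    coding_pairs: tuple[int, ...] = (5, 5, 5, 5, 5, 5, 5, 3, 3, 3)
    vlinc_length: int = 1200
    coding_length: int = 800
    drugs: Mapping[str, DrugModel] = field(default_factory=lambda: dict(DEFAULT_DRUGS))
    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    efficacy_beta: tuple[float, float] | None = (8.0, 2.0)  # None -> efficacy 1
    mismatch_activity: float = 0.0
    log2_abundance_sigma: float = 0.5
    nb_dispersion: float = 0.05
    population: int = 200_000
    depth: int = 500_000
    batches: int = 3
    splits: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name, drug in self.drugs.items():
            if not isinstance(drug, DrugModel):
                self.drugs[name] = DrugModel(*drug)  # type: ignore[index]

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=seed)

    @property
    def n_pairs(self) -> int:
        return self.n_vlinc * self.pairs_per_vlinc + sum(self.coding_pairs)

    def transcript_ids(self) -> list[str]:
        vlinc = [f"vlinc{i:02d}" for i in range(1, self.n_vlinc + 1)]
        coding = [f"gene{i:02d}" for i in range(1, len(self.coding_pairs) + 1)]
        return vlinc + coding


@dataclass
class SimulatedScreen:
    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame  # transcript x drug ground truth
    guide_efficacy: pd.Series


_BASES = np.array(list("ACGT"))


def random_transcript(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_manifest(
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random designable transcripts run through the real design pipeline.

    Returns (manifest, transcript-level ground truth). Uniform uniqueness
    and no repeat mask, so only the sequence-level filters act.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    targets = []
    for tid in design.transcript_ids():
        if tid.startswith("vlinc"):
            length, pairs, cls = design.vlinc_length, design.pairs_per_vlinc, "vlinc"
        else:
            idx = int(tid.removeprefix("gene")) - 1
            length, pairs, cls = design.coding_length, design.coding_pairs[idx], "coding"
        targets.append(
            _design.TranscriptTarget(
                transcript_id=tid,
                transcript_class=cls,
                sequence=random_transcript(rng, length),
                requested_pairs=pairs,
            )
        )
    result = _design.build_design_manifest(targets)
    if not result.shortfalls.empty:
        raise RuntimeError(
            f"random transcripts not designable: {result.shortfalls.to_dict('records')}"
        )
    truth_rows = [
        {
            "transcript_id": tid,
            "drug": drug,
            "effect": design.effects.get((tid, drug), 0.0),
            "direction": _direction(design.effects.get((tid, drug), 0.0)),
        }
        for tid in design.transcript_ids()
        for drug in design.drugs
    ]
    return result.manifest, pd.DataFrame(truth_rows)


def _direction(effect: float) -> str:
    if effect < 0:
        return "depleted"
    if effect > 0:
        return "enriched"
    return "null"


def _sequencing_draw(
    rng: np.random.Generator, cell_counts: np.ndarray, depth: int, dispersion: float
) -> np.ndarray:
    probs = cell_counts / cell_counts.sum()
    reads = rng.multinomial(depth, probs).astype(float)
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=reads * dispersion)
        reads = rng.poisson(lam).astype(float)
    return reads.astype(np.int64)


def simulate_screen_counts(
    design: SimulationDesign,
    manifest: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> SimulatedScreen:
    """Generate the guides x libraries count table plus metadata and truth.

    Per arm and batch the population starts as a multinomial sample of the
    shared lognormal library composition. Each round, guide g survives with
    probability ``drug.survival * 2**(dox * effect * activity_g)`` (clipped
    to 1) where activity is the Beta-drawn efficacy for targeting guides
    and rho for mismatch guides, then the survivors regrow to the fixed
    population size. Each batch is sequenced as ``splits`` multinomial
    draws at ``depth`` with negative-binomial overdispersion on top.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    guide_ids = manifest["guide_id"].to_numpy()
    tx = manifest["transcript_id"].to_numpy()
    is_targeting = (manifest["role"] == "targeting").to_numpy()
    n_guides = len(guide_ids)

    if design.efficacy_beta is None:
        drawn = np.ones(n_guides)
    else:
        a, b = design.efficacy_beta
        drawn = rng.beta(a, b, size=n_guides)
    efficacy = np.where(is_targeting, drawn, design.mismatch_activity)
    weights = np.exp2(rng.normal(0.0, design.log2_abundance_sigma, size=n_guides))
    p0 = weights / weights.sum()

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for drug_name, drug in design.drugs.items():
        effect = np.array(
            [design.effects.get((t, drug_name), 0.0) for t in tx], dtype=float
        )
        for dox, dox_label in ((1, "plus"), (0, "minus")):
            surv_p = np.clip(
                drug.survival * np.exp2(dox * effect * efficacy), 0.0, 1.0
            )
            for batch in range(1, design.batches + 1):
                cells = rng.multinomial(design.population, p0)
                for _ in range(drug.rounds):
                    survivors = rng.binomial(cells, surv_p)
                    total = survivors.sum()
                    if total == 0:
                        raise PopulationExtinctError(
                            "population extinct during simulated treatment; "
                            "increase design.population"
                        )
                    cells = rng.multinomial(design.population, survivors / total)
                for split in range(1, design.splits + 1):
                    lib = f"{drug_name}_{'D' if dox else 'ND'}_b{batch}s{split}"
                    columns[lib] = _sequencing_draw(
                        rng, cells, design.depth, design.nb_dispersion
                    )
                    meta_rows.append(
                        {
                            "library_id": lib,
                            "drug": drug_name,
                            "dox": dox_label,
                            "batch": batch,
                            "split": split,
                            "stage": "post_challenge",
                        }
                    )

    counts = pd.DataFrame(columns, index=guide_ids)
    metadata = pd.DataFrame(
        meta_rows, columns=["library_id", "drug", "dox", "batch", "split", "stage"]
    )
    truth_rows = [
        {
            "transcript_id": t,
            "drug": d,
            "effect": design.effects.get((t, d), 0.0),
            "direction": _direction(design.effects.get((t, d), 0.0)),
        }
        for t in pd.unique(tx)
        for d in design.drugs
    ]
    return SimulatedScreen(
        counts=counts,
        metadata=metadata,
        truth=pd.DataFrame(truth_rows),
        guide_efficacy=pd.Series(efficacy, index=guide_ids, name="efficacy"),
    )


# Cassette-style context so each spacer sits strictly inside its read.
FLANK5 = "ACCTGAGGTCATCGTACGCAAC"
FLANK3 = (
    "GTCCAAGTGGTACGATCAGGTTCAGCATCCTAGGTACTGACGTACCTTGCAAGGTCATGC"
    "ATCGGATCCTTGACCAGTTCGAACTGGTCAAGGATCCGATGCATGACCTTGCAAGGTACG"
)


def simulate_reads(
    counts_column: pd.Series,
    manifest: pd.DataFrame,
    rng: np.random.Generator | None = None,
    depth: int | None = None,
    read_length: int = 150,
    flank5: str = FLANK5,
    flank3: str = FLANK3,
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Amplicon reads for one library with exact per-guide bookkeeping.

    Multiplicities are the counts themselves, or a multinomial draw of
    ``depth`` proportional to them. Each read is flank5 + spacer + flank3
    padded/truncated to ``read_length``; read order is shuffled under the
    rng. Returns (records, guide_id -> multiplicity).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    spacer_of = manifest.set_index("guide_id")["spacer"]
    guide_ids = counts_column.index.to_numpy()
    raw = counts_column.to_numpy()
    if depth is None:
        mult = raw.astype(np.int64)
    else:
        total = raw.sum()
        if total == 0:
            raise ValueError("cannot sample reads from an all-zero column")
        mult = rng.multinomial(depth, raw / total)
    spacer_len = len(spacer_of.iloc[0])
    if len(flank5) + spacer_len > read_length:
        raise ValueError("flank5 + spacer exceed the read length")

    records: list[tuple[str, str, str]] = []
    bookkeeping: dict[str, int] = {}
    for gid, m in zip(guide_ids, mult):
        bookkeeping[gid] = int(m)
        if m == 0:
            continue
        core = flank5 + spacer_of.loc[gid] + flank3
        while len(core) < read_length:
            core += flank3
        seq = core[:read_length]
        records.extend((gid, seq, "I" * read_length) for _ in range(int(m)))
    order = rng.permutation(len(records))
    records = [
        (f"read{i:07d}_{records[j][0]}", records[j][1], records[j][2])
        for i, j in enumerate(order)
    ]
    return records, bookkeeping


def simulate_expression(
    effects: Mapping[str, Mapping[str, tuple[float, float]]],
    rng: np.random.Generator | None = None,
    baseline_log2_mean: float = 7.0,
    baseline_log2_sd: float = 1.0,
    noise_sd: float = 0.0,
    drugs: tuple[str, ...] = ("imatinib", "mirin", "etoposide"),
    timepoints: tuple[str, str] = ("3h", "6h"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format NRC table with matched DMSO baselines and true tiers.

    ``effects[gene][drug] = (fc_3h, fc_6h)`` in log2 units; missing drugs
    mean no induction. At ``noise_sd=0`` the realized fold change equals
    the specified effect exactly, so the emitted tier labels are exact.
    """
    from cas13screen.expression import STRONG_FC, WEAK_FC

    rng = rng if rng is not None else np.random.default_rng(0)
    records = []
    truth_rows = []
    for gene, per_drug in effects.items():
        baseline = float(np.exp2(rng.normal(baseline_log2_mean, baseline_log2_sd)))
        n_strong = 0
        n_weak = 0
        for tp in timepoints:
            records.append(
                {"gene_id": gene, "condition": "DMSO", "timepoint": tp, "nrc": baseline}
            )
        for drug in drugs:
            fc_by_tp = per_drug.get(drug, (0.0, 0.0))
            for tp, fc_true in zip(timepoints, fc_by_tp):
                fc = fc_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                nrc = (baseline + 1.0) * np.exp2(fc) - 1.0
                records.append(
                    {
                        "gene_id": gene,
                        "condition": drug,
                        "timepoint": tp,
                        "nrc": max(0.0, float(nrc)),
                    }
                )
            if all(v > STRONG_FC for v in fc_by_tp):
                n_strong += 1
            if all(v > WEAK_FC for v in fc_by_tp):
                n_weak += 1
        tier = "strong" if n_strong >= 1 else ("weak" if n_weak >= 1 else "none")
        truth_rows.append({"gene_id": gene, "tier": tier, "multi_drug": n_strong >= 2})
    return (
        pd.DataFrame(records, columns=["gene_id", "condition", "timepoint", "nrc"]),
        pd.DataFrame(truth_rows, columns=["gene_id", "tier", "multi_drug"]),
    )
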