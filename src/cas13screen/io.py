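"""Readers/writers for the pipeline's plain-text formats and the
end-to-end driver.

All tables are TSV with headers and a stable column order; FASTQ may be
gzipped (detected by suffix). BED intervals are 0-based half-open;
manifest coordinates are 1-based inclusive.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from cas13screen.errors import ParseError

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "guide_id",
    "pair_id",
    "transcript_id",
    "transcript_class",
    "role",
    "target_start",
    "spacer",
    "sense_oligo",
    "antisense_oligo",
]
METADATA_COLUMNS = ["library_id", "drug", "dox", "batch", "split", "stage"]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) records; gzip transparent.

    Malformed records raise ParseError carrying the index of the offending
    record.
    """
    n = 0
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                n += 1
                yield (
                    rec.id,
                    str(rec.seq),
                    "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
                )
    except ValueError as exc:
        raise ParseError(f"malformed FASTQ record at index {n} in {path}: {exc}") from exc


def write_fastq(path, records) -> None:
    """Write (id, sequence, quality) triples; gzip transparent."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """0-based half-open intervals per sequence name."""
    out: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            out.setdefault(parts[0], []).append((start, end))
    return out


def read_uniqueness(path) -> dict[str, dict[int, float]]:
    """3-column TSV transcript_id / 1-based position / score."""
    out: dict[str, dict[int, float]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                pos, score = int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position/score") from exc
            out.setdefault(parts[0], {})[pos] = score
    return out


def _read_tsv(path, required: list[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
    return df


def read_manifest(path) -> pd.DataFrame:
    df = _read_tsv(path, required=MANIFEST_COLUMNS)
    df["target_start"] = df["target_start"].astype(int)
    return df


def read_metadata(path) -> pd.DataFrame:
    df = _read_tsv(path, required=METADATA_COLUMNS)
    df["batch"] = df["batch"].astype(int)
    df["split"] = df["split"].astype(int)
    return df


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end count -> qc -> screen run."""

    manifest: str
    metadata: str
    out_dir: str
    counts: str | None = None  # pre-computed counts bypass FASTQ counting
    expression: str | None = None
    alpha: float = 0.05
    strong_fc: float = 0.58
    weak_fc: float = 0.0
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute count -> qc -> screen (and optionally expression) in order.

    Writes every stage output under ``config.out_dir`` plus a JSON run log
    with package version, seed, row counts and the BH family size per drug.
    A stage failure raises with the failing stage named.
    """
    from cas13screen import __version__, expression, inference, qc, quant

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    stage = "count"
    try:
        manifest = read_manifest(config.manifest)
        metadata = read_metadata(config.metadata)
        if config.counts is not None:
            counts = read_counts(config.counts)
        else:
            counts = quant.count_table(metadata, manifest)
        write_table(counts, out / "counts.tsv", index=True)
        log["stages"][stage] = {"libraries": counts.shape[1], "guides": counts.shape[0]}

        stage = "qc"
        qc_report = qc.qc_table(counts, n_designed=len(manifest))
        write_table(qc_report, out / "qc.tsv")
        log["stages"][stage] = {"rows": len(qc_report)}

        stage = "screen"
        normalized = quant.normalize_table(counts)
        log2 = quant.log2_table(normalized)
        write_table(log2, out / "log2.tsv", index=True)
        result = inference.run_screen(log2, metadata, manifest, alpha=config.alpha)
        write_table(result.guide_contrasts, out / "guide_contrasts.tsv")
        write_table(result.pair_contrasts, out / "pair_contrasts.tsv")
        write_table(result.calls, out / "calls.tsv")
        log["stages"][stage] = {
            "pairs": len(result.pair_contrasts),
            "calls": len(result.calls),
            "bh_family_sizes": result.bh_family_sizes,
        }

        if config.expression is not None:
            stage = "expression"
            nrc = _read_tsv(config.expression, required=["gene_id", "condition", "timepoint", "nrc"])
            nrc["nrc"] = nrc["nrc"].astype(float)
            fc = expression.fc_table(nrc)
            tiers = expression.select_targets(fc, strong=config.strong_fc, weak=config.weak_fc)
            write_table(fc, out / "fc.tsv")
            write_table(tiers, out / "tiers.tsv")
            log["stages"][stage] = {"genes": tiers["gene_id"].nunique()}
    except Exception as exc:
        from cas13screen.errors import Cas13ScreenError

        raise Cas13ScreenError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return log
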