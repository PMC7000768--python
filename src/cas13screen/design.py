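"""Cas13 guide design: candidate enumeration, filtering, selection,
mismatch controls and cloning oligos.

Spacers are 28-mers reverse-complementary to the sense-strand transcript
window. Each targeting spacer gets a cognate control spacer whose bases
12-14 (1-based on the spacer) are complemented, guaranteeing exactly three
mismatches against the target while preserving the remaining context.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cas13screen._seq import complement, reverse_complement, validate_dna
from cas13screen.errors import ManifestError, MissingDataError

SPACER_LENGTH = 28

__all__ = [
    "SPACER_LENGTH",
    "DesignConstraints",
    "TranscriptTarget",
    "UniquenessTrack",
    "RepeatMask",
    "Candidate",
    "GuidePair",
    "SelectionResult",
    "DesignResult",
    "gc_fraction",
    "max_homopolymer_run",
    "max_dinucleotide_repeats",
    "mean_uniqueness",
    "enumerate_candidates",
    "select_guides",
    "make_mismatch",
    "to_cloning_oligos",
    "build_design_manifest",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Filter thresholds applied to every candidate spacer.

    GC bounds are inclusive; the uniqueness threshold is strict (>).
    ``mismatch_window`` is a 1-based closed interval on the spacer.
    """

    gc_min: float = 0.40
    gc_max: float = 0.60
    max_homopolymer: int = 3
    max_dinucleotide_repeats: int = 2
    uniqueness_min: float = 0.7
    mismatch_window: tuple[int, int] = (12, 14)
    spacer_length: int = SPACER_LENGTH

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min <= self.gc_max <= 1):
            raise ValueError("require 0 <= gc_min <= gc_max <= 1")
        lo, hi = self.mismatch_window
        if not (1 <= lo <= hi <= self.spacer_length):
            raise ValueError("mismatch_window must lie within the spacer")


@dataclass
class TranscriptTarget:
    """A transcript to design guides against.

    ``sequence`` is the sense strand (concatenated exons for coding genes).
    ``exon_intervals`` are optional 1-based closed intervals in transcript
    coordinates; for coding targets, candidate windows must fall entirely
    within a single interval. When absent the whole sequence is exonic.
    """

    transcript_id: str
    transcript_class: str  # "vlinc" | "coding"
    sequence: str
    requested_pairs: int
    exon_intervals: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.transcript_class not in ("vlinc", "coding"):
            raise ValueError(f"unknown transcript class {self.transcript_class!r}")
        if self.requested_pairs < 1:
            raise ValueError("requested_pairs must be >= 1")
        self.sequence = validate_dna(self.sequence, context=self.transcript_id)


@dataclass
class UniquenessTrack:
    """Per-base uniqueness scores in [0,1], keyed by 1-based position."""

    scores: Mapping[int, float]

    def __post_init__(self) -> None:
        for pos, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"uniqueness score {s} at {pos} outside [0,1]")

    @classmethod
    def constant(cls, length: int, value: float = 1.0) -> "UniquenessTrack":
        return cls({i: value for i in range(1, length + 1)})


@dataclass
class RepeatMask:
    """Repetitive intervals on the transcript, 0-based half-open."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def overlaps(self, start0: int, end0: int) -> bool:
        return any(s < end0 and start0 < e for s, e in self.intervals)


@dataclass(frozen=True)
class Candidate:
    """A passing 28-nt design window. ``start`` is 1-based on the transcript."""

    start: int
    window: str  # sense-strand sequence of the window
    spacer: str  # reverse complement of the window
    gc: float


@dataclass(frozen=True)
class GuidePair:
    pair_id: str
    transcript_id: str
    transcript_class: str
    target_start: int
    targeting_spacer: str
    mismatch_spacer: str

    def oligos(self, role: str) -> tuple[str, str]:
        spacer = self.targeting_spacer if role == "targeting" else self.mismatch_spacer
        return to_cloning_oligos(spacer)


@dataclass
class SelectionResult:
    selected: list[Candidate]
    requested: int

    @property
    def shortfall(self) -> int:
        return max(0, self.requested - len(self.selected))


@dataclass
class DesignResult:
    manifest: pd.DataFrame
    pairs: list[GuidePair]
    shortfalls: pd.DataFrame


def gc_fraction(spacer: str) -> float:
    """Fraction of G/C bases in the spacer."""
    spacer = validate_dna(spacer, context="spacer")
    return (spacer.count("G") + spacer.count("C")) / len(spacer)


def max_homopolymer_run(spacer: str) -> int:
    """Length of the longest run of a single repeated base."""
    spacer = validate_dna(spacer, context="spacer")
    best = run = 1
    for a, b in zip(spacer, spacer[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def max_dinucleotide_repeats(spacer: str) -> int:
    """Maximum tandem repeat count of any 2-mer unit with unequal bases.

    ``ACACAC`` scores 3 (AC repeated three times). Homopolymer stretches are
    deliberately not scored here; they are judged by max_homopolymer_run.
    """
    spacer = validate_dna(spacer, context="spacer")
    best = 0
    n = len(spacer)
    for i in range(n - 1):
        if spacer[i] == spacer[i + 1]:
            continue
        unit = spacer[i : i + 2]
        reps = 1
        j = i + 2
        while j + 2 <= n and spacer[j : j + 2] == unit:
            reps += 1
            j += 2
        best = max(best, reps)
    return best


def mean_uniqueness(track: UniquenessTrack, window: tuple[int, int]) -> float:
    """Arithmetic mean of per-base uniqueness over a 1-based closed window."""
    start, end = window
    total = 0.0
    for pos in range(start, end + 1):
        try:
            total += track.scores[pos]
        except KeyError:
            raise MissingDataError(
                f"uniqueness score missing at position {pos}"
            ) from None
    return total / (end - start + 1)


def passes_filters(spacer: str, constraints: DesignConstraints) -> bool:
    """Sequence-level filters only (GC, homopolymer, dinucleotide runs)."""
    return (
        constraints.gc_min <= gc_fraction(spacer) <= constraints.gc_max
        and max_homopolymer_run(spacer) <= constraints.max_homopolymer
        and max_dinucleotide_repeats(spacer) <= constraints.max_dinucleotide_repeats
    )


def _exonic_ok(target: TranscriptTarget, start1: int, end1: int) -> bool:
    if target.transcript_class != "coding" or target.exon_intervals is None:
        return True
    return any(lo <= start1 and end1 <= hi for lo, hi in target.exon_intervals)


def enumerate_candidates(
    target: TranscriptTarget,
    mask: RepeatMask | None = None,
    track: UniquenessTrack | None = None,
    constraints: DesignConstraints | None = None,
) -> list[Candidate]:
    """All 28-nt windows (step 1) passing every design filter.

    A window passes when its spacer satisfies the sequence filters, its mean
    uniqueness exceeds the threshold strictly, it overlaps no masked base,
    and (coding class) it lies inside a single exon interval. Windows with
    missing uniqueness positions are rejected.
    """
    constraints = constraints or DesignConstraints()
    seq = target.sequence
    k = constraints.spacer_length
    if len(seq) < k:
        warnings.warn(
            f"{target.transcript_id}: sequence shorter than {k} nt, no candidates",
            stacklevel=2,
        )
        return []
    out: list[Candidate] = []
    for i0 in range(len(seq) - k + 1):
        start1 = i0 + 1
        end1 = i0 + k
        if mask is not None and mask.overlaps(i0, i0 + k):
            continue
        if not _exonic_ok(target, start1, end1):
            continue
        window = seq[i0 : i0 + k]
        spacer = reverse_complement(window)
        if not passes_filters(spacer, constraints):
            continue
        if track is not None:
            try:
                u = mean_uniqueness(track, (start1, end1))
            except MissingDataError:
                continue
            if not u > constraints.uniqueness_min:
                continue
        out.append(Candidate(start=start1, window=window, spacer=spacer, gc=gc_fraction(spacer)))
    return out


def _greedy_fit(positions: Sequence[int], gap: int) -> int:
    """Max number of positions selectable from a sorted list with pairwise gap >= gap."""
    count = 0
    last = None
    for p in positions:
        if last is None or p - last >= gap:
            count += 1
            last = p
    return count


def select_guides(candidates: Sequence[Candidate], n: int) -> SelectionResult:
    """Deterministically pick ``n`` candidates maximizing the minimum spacing.

    The largest achievable minimum pairwise gap d* is found by binary search
    with a greedy feasibility check; the returned set realizes d*. Among
    positions compatible with completing a d*-spaced selection, each slot is
    filled by the candidate with smallest |GC - 0.5|, ties to the 5'-most.
    Returns fewer than ``n`` (with a recorded shortfall) when candidates run out.
    """
    cands = sorted(candidates, key=lambda c: c.start)
    if len(cands) <= n:
        return SelectionResult(selected=cands, requested=n)
    positions = [c.start for c in cands]
    if n == 1:
        best = min(cands, key=lambda c: (abs(c.gc - 0.5), c.start))
        return SelectionResult(selected=[best], requested=n)

    lo, hi = 1, (positions[-1] - positions[0]) // (n - 1) + 1
    while lo < hi:  # largest gap with _greedy_fit >= n
        mid = (lo + hi + 1) // 2
        if _greedy_fit(positions, mid) >= n:
            lo = mid
        else:
            hi = mid - 1
    dstar = lo

    # suffix[i]: how many d*-spaced picks fit starting at candidate i
    m = len(cands)
    suffix = [0] * m
    for i in range(m - 1, -1, -1):
        j = bisect_left(positions, positions[i] + dstar, i + 1)
        suffix[i] = 1 + (suffix[j] if j < m else 0)

    selected: list[Candidate] = []
    first_idx = 0
    remaining = n
    while remaining:
        feasible = [
            i
            for i in range(first_idx, m)
            if suffix[i] >= remaining
        ]
        pick = min(feasible, key=lambda i: (abs(cands[i].gc - 0.5), positions[i]))
        selected.append(cands[pick])
        first_idx = bisect_left(positions, positions[pick] + dstar, pick + 1)
        remaining -= 1
    return SelectionResult(selected=selected, requested=n)


def make_mismatch(spacer: str, window: tuple[int, int] = (12, 14)) -> str:
    """Control spacer: complement each base of the 1-based closed window.

    Complementation guarantees a mismatch at every altered position and makes
    the operation an involution.
    """
    spacer = validate_dna(spacer, context="spacer")
    lo, hi = window
    mutated = "".join(complement(b) for b in spacer[lo - 1 : hi])
    return spacer[: lo - 1] + mutated + spacer[hi:]


def to_cloning_oligos(spacer: str) -> tuple[str, str]:
    """Annealing oligos: AAAC + spacer (sense), AAAA + revcomp (antisense)."""
    spacer = validate_dna(spacer, context="spacer")
    return "AAAC" + spacer, "AAAA" + reverse_complement(spacer)


def build_design_manifest(
    targets: Iterable[TranscriptTarget],
    masks: Mapping[str, RepeatMask] | None = None,
    tracks: Mapping[str, UniquenessTrack] | None = None,
    constraints: DesignConstraints | None = None,
) -> DesignResult:
    """Design guide pairs for every target and assemble the manifest table.

    The manifest has one row per oligo sequence (two per pair) and is the
    guide universe for all downstream stages. Duplicate spacer sequences
    across the manifest are a hard error: spacers double as cell barcodes.
    """
    constraints = constraints or DesignConstraints()
    masks = masks or {}
    tracks = tracks or {}
    pairs: list[GuidePair] = []
    shortfalls: list[dict] = []
    for target in targets:
        cands = enumerate_candidates(
            target,
            masks.get(target.transcript_id),
            tracks.get(target.transcript_id),
            constraints,
        )
        sel = select_guides(cands, target.requested_pairs)
        if sel.shortfall:
            shortfalls.append(
                {
                    "transcript_id": target.transcript_id,
                    "requested": target.requested_pairs,
                    "selected": len(sel.selected),
                }
            )
        for k, cand in enumerate(sel.selected, start=1):
            pairs.append(
                GuidePair(
                    pair_id=f"{target.transcript_id}_p{k:02d}",
                    transcript_id=target.transcript_id,
                    transcript_class=target.transcript_class,
                    target_start=cand.start,
                    targeting_spacer=cand.spacer,
                    mismatch_spacer=make_mismatch(cand.spacer, constraints.mismatch_window),
                )
            )

    rows = []
    for pair in pairs:
        for role, spacer in (
            ("targeting", pair.targeting_spacer),
            ("mismatch", pair.mismatch_spacer),
        ):
            sense, antisense = to_cloning_oligos(spacer)
            rows.append(
                {
                    "guide_id": f"{pair.pair_id}_{'T' if role == 'targeting' else 'MT'}",
                    "pair_id": pair.pair_id,
                    "transcript_id": pair.transcript_id,
                    "transcript_class": pair.transcript_class,
                    "role": role,
                    "target_start": pair.target_start,
                    "spacer": spacer,
                    "sense_oligo": sense,
                    "antisense_oligo": antisense,
                }
            )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "guide_id",
            "pair_id",
            "transcript_id",
            "transcript_class",
            "role",
            "target_start",
            "spacer",
            "sense_oligo",
            "antisense_oligo",
        ],
    )
    if not manifest.empty and manifest["spacer"].duplicated().any():
        dup = manifest.loc[manifest["spacer"].duplicated(), "spacer"].iloc[0]
        raise ManifestError(f"duplicate spacer in manifest: {dup}")
    return DesignResult(
        manifest=manifest,
        pairs=pairs,
        shortfalls=pd.DataFrame(
            shortfalls, columns=["transcript_id", "requested", "selected"]
        ),
    )
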