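from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cas13screen import design
from cas13screen.design import (
    Candidate,
    DesignConstraints,
    RepeatMask,
    TranscriptTarget,
    UniquenessTrack,
    build_design_manifest,
    enumerate_candidates,
    gc_fraction,
    make_mismatch,
    max_dinucleotide_repeats,
    max_homopolymer_run,
    mean_uniqueness,
    select_guides,
    to_cloning_oligos,
)
from cas13screen.errors import InvalidSequenceError, ManifestError, MissingDataError

spacers = st.text(alphabet="ACGT", min_size=28, max_size=28)

REVCOMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq):
    return "".join(REVCOMP[b] for b in reversed(seq))


class TestSequenceFilters:
    def test_gc_zero(self):
        assert gc_fraction("A" * 28) == 0.0

    def test_gc_midpoint(self):
        spacer = "G" * 7 + "C" * 7 + "A" * 7 + "T" * 7
        assert gc_fraction(spacer) == 0.5

    def test_gc_eleven_of_28(self):
        spacer = "G" * 11 + "A" * 17
        assert gc_fraction(spacer) == pytest.approx(11 / 28)
        c = DesignConstraints()
        assert not (c.gc_min <= gc_fraction(spacer) <= c.gc_max)

    def test_gc_bounds_12_to_16_of_28(self):
        # inclusive 40-60% on a 28-mer admits 12..16 G/C bases
        c = DesignConstraints()
        for n_gc, ok in [(11, False), (12, True), (16, True), (17, False)]:
            frac = n_gc / 28
            assert (c.gc_min <= frac <= c.gc_max) is ok

    def test_gc_invalid_alphabet(self):
        with pytest.raises(InvalidSequenceError):
            gc_fraction("N" * 28)

    def test_homopolymer_none(self):
        assert max_homopolymer_run("ACGT" * 7) == 1

    def test_homopolymer_four_fails(self):
        spacer = "ACGTACGTAAAACGTACGTACGTACGTA"
        assert len(spacer) == 28
        assert max_homopolymer_run(spacer) == 4
        assert max_homopolymer_run(spacer) > DesignConstraints().max_homopolymer

    def test_homopolymer_three_passes(self):
        spacer = "GGGTTTACCACGTACGTACGTACGTACG"
        assert len(spacer) == 28
        assert max_homopolymer_run(spacer) == 3

    @given(spacers)
    def test_homopolymer_matches_scan_oracle(self, spacer):
        best = max(
            (len(run) for run in _runs(spacer)),
        )
        assert max_homopolymer_run(spacer) == best

    def test_dinucleotide_boundary(self):
        spacer = "ACACGTACGTACGTACGTACGTACGTAC"
        assert len(spacer) == 28
        assert max_dinucleotide_repeats(spacer) == 2

    def test_dinucleotide_three_fails(self):
        spacer = "AGAGAGTTCCAATTCCAATTCCAATTCC"
        assert len(spacer) == 28
        assert max_dinucleotide_repeats(spacer) == 3

    def test_dinucleotide_period_four(self):
        assert max_dinucleotide_repeats("ACGTACGTACGTACGTACGTACGTACGT") == 1

    @given(spacers)
    def test_dinucleotide_matches_bruteforce(self, spacer):
        assert max_dinucleotide_repeats(spacer) == _dinuc_oracle(spacer)

    def test_homopolymer_not_scored_as_dinucleotide(self):
        # AAAA is judged by the homopolymer rule only
        spacer = "AAAACGTCGTACGTACGTACGTACGTAC"
        assert max_dinucleotide_repeats(spacer) < 2


def _runs(s):
    run = s[0]
    for ch in s[1:]:
        if ch == run[-1]:
            run += ch
        else:
            yield run
            run = ch
    yield run


def _dinuc_oracle(s):
    """Brute force: try every start phase and unequal 2-mer unit."""
    best = 0
    for i in range(len(s) - 1):
        if s[i] == s[i + 1]:
            continue
        reps = 0
        j = i
        while j + 2 <= len(s) and s[j : j + 2] == s[i : i + 2]:
            reps += 1
            j += 2
        best = max(best, reps)
    return best


class TestUniqueness:
    def test_all_ones(self):
        track = UniquenessTrack.constant(28, 1.0)
        assert mean_uniqueness(track, (1, 28)) == 1.0

    def test_boundary_strict(self):
        track = UniquenessTrack.constant(28, 0.7)
        val = mean_uniqueness(track, (1, 28))
        assert val == pytest.approx(0.7)
        assert not val > DesignConstraints().uniqueness_min

    def test_half_half(self):
        scores = {i: 1.0 for i in range(1, 15)}
        scores.update({i: 0.5 for i in range(15, 29)})
        assert mean_uniqueness(UniquenessTrack(scores), (1, 28)) == pytest.approx(0.75)

    def test_missing_position(self):
        track = UniquenessTrack({1: 1.0})
        with pytest.raises(MissingDataError):
            mean_uniqueness(track, (1, 28))

    def test_score_bounds_validated(self):
        with pytest.raises(ValueError):
            UniquenessTrack({1: 1.5})


def _naive_enumerate(target, mask, track, constraints):
    """Independent brute-force filter over every window."""
    out = []
    seq = target.sequence
    k = constraints.spacer_length
    for i0 in range(len(seq) - k + 1):
        window = seq[i0 : i0 + k]
        spacer = revcomp(window)
        gc = (spacer.count("G") + spacer.count("C")) / k
        if not (constraints.gc_min <= gc <= constraints.gc_max):
            continue
        if max(len(r) for r in _runs(spacer)) > constraints.max_homopolymer:
            continue
        if _dinuc_oracle(spacer) > constraints.max_dinucleotide_repeats:
            continue
        if mask is not None and any(s < i0 + k and i0 < e for s, e in mask.intervals):
            continue
        if track is not None:
            try:
                u = sum(track.scores[p] for p in range(i0 + 1, i0 + k + 1)) / k
            except KeyError:
                continue
            if not u > constraints.uniqueness_min:
                continue
        if target.transcript_class == "coding" and target.exon_intervals is not None:
            if not any(lo <= i0 + 1 and i0 + k <= hi for lo, hi in target.exon_intervals):
                continue
        out.append((i0 + 1, spacer))
    return out


class TestEnumerate:
    def test_fully_masked(self):
        target = TranscriptTarget("t", "vlinc", "ACGT" * 30, 1)
        mask = RepeatMask([(0, 120)])
        assert enumerate_candidates(target, mask) == []

    def test_single_window(self):
        seq = "GCATGCATACGTACGTACGTGCATGCAT"  # 28 nt, 50% GC, no bad runs
        target = TranscriptTarget("t", "vlinc", seq, 1)
        cands = enumerate_candidates(target)
        assert len(cands) == 1
        assert cands[0].start == 1
        assert cands[0].spacer == revcomp(seq)

    def test_too_short_warns_empty(self):
        target = TranscriptTarget("t", "vlinc", "ACGTACGTACGTACGTACGTACGTACGT", 1)
        target.sequence = target.sequence[:27]
        with pytest.warns(UserWarning):
            assert enumerate_candidates(target) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_fixture(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        target = TranscriptTarget("t", "vlinc", seq, 5)
        mask = RepeatMask([(50, 80), (200, 210)])
        scores = {i: float(s) for i, s in enumerate(rng.uniform(0.5, 1.0, 300), start=1)}
        track = UniquenessTrack(scores)
        c = DesignConstraints()
        got = [(cand.start, cand.spacer) for cand in enumerate_candidates(target, mask, track, c)]
        assert got == _naive_enumerate(target, mask, track, c)

    def test_coding_exons_only(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        target = TranscriptTarget("t", "coding", seq, 3, exon_intervals=[(1, 60), (100, 200)])
        c = DesignConstraints()
        got = [(x.start, x.spacer) for x in enumerate_candidates(target, None, None, c)]
        assert got == _naive_enumerate(target, None, None, c)
        assert all(s <= 33 or s >= 100 for s, _ in got)


def _mk_cand(pos, gc=0.5):
    return Candidate(start=pos, window="A" * 28, spacer="T" * 28, gc=gc)


class TestSelect:
    def test_single_candidate(self):
        c = _mk_cand(5)
        res = select_guides([c], 1)
        assert res.selected == [c] and res.shortfall == 0

    def test_all_when_exact(self):
        cands = [_mk_cand(1 + 30 * i) for i in range(10)]
        res = select_guides(cands, 10)
        assert res.selected == cands

    def test_shortfall_recorded(self):
        cands = [_mk_cand(1), _mk_cand(50)]
        res = select_guides(cands, 5)
        assert len(res.selected) == 2 and res.shortfall == 3

    def test_spacing_optimal_vs_exhaustive(self):
        rng = np.random.default_rng(9)
        positions = sorted(rng.choice(np.arange(1, 500), size=20, replace=False))
        cands = [_mk_cand(int(p), gc=float(g)) for p, g in zip(positions, rng.uniform(0.4, 0.6, 20))]
        res = select_guides(cands, 5)
        got_gap = min(
            b.start - a.start for a, b in zip(res.selected, res.selected[1:])
        )
        best_gap = max(
            min(q - p for p, q in zip(combo, combo[1:]))
            for combo in combinations(positions, 5)
        )
        assert got_gap == best_gap

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        positions = sorted(rng.choice(np.arange(1, 400), size=15, replace=False))
        cands = [_mk_cand(int(p), gc=float(g)) for p, g in zip(positions, rng.uniform(0.4, 0.6, 15))]
        first = select_guides(cands, 4).selected
        again = select_guides(list(reversed(cands)), 4).selected
        assert first == again


class TestMismatch:
    def test_forced_by_complement_rule(self):
        assert make_mismatch("A" * 28) == "A" * 11 + "TTT" + "A" * 14

    @given(spacers)
    def test_involution(self, spacer):
        assert make_mismatch(make_mismatch(spacer)) == spacer

    @given(spacers)
    def test_hamming_exactly_three_at_12_14(self, spacer):
        mm = make_mismatch(spacer)
        diff = [i + 1 for i, (a, b) in enumerate(zip(spacer, mm)) if a != b]
        assert diff == [12, 13, 14]

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidSequenceError):
            make_mismatch("X" * 28)


class TestOligos:
    @given(spacers)
    def test_structure(self, spacer):
        sense, antisense = to_cloning_oligos(spacer)
        assert sense == "AAAC" + spacer
        assert antisense == "AAAA" + revcomp(spacer)
        assert len(sense) == len(antisense) == 32
        assert revcomp(antisense[4:]) == sense[4:]


class TestManifest:
    def test_one_target_one_pair(self):
        seq = "GCATGCATACGTACGTACGTGCATGCAT"
        res = build_design_manifest([TranscriptTarget("t", "vlinc", seq, 1)])
        assert len(res.manifest) == 2
        assert set(res.manifest["role"]) == {"targeting", "mismatch"}

    def test_rows_twice_pairs(self, paper_scale_manifest):
        assert len(paper_scale_manifest) == 2 * paper_scale_manifest["pair_id"].nunique()

    def test_duplicate_spacer_rejected(self):
        seq = "GCATGCATACGTACGTACGTGCATGCAT"
        targets = [
            TranscriptTarget("t1", "vlinc", seq, 1),
            TranscriptTarget("t2", "vlinc", seq, 1),
        ]
        with pytest.raises(ManifestError):
            build_design_manifest(targets)

    def test_filter_idempotence(self, paper_scale_manifest):
        # every emitted targeting spacer re-passes the individual filters
        c = DesignConstraints()
        targeting = paper_scale_manifest[paper_scale_manifest["role"] == "targeting"]
        for spacer in targeting["spacer"]:
            assert design.passes_filters(spacer, c)

    def test_mismatch_rows_consistent(self, paper_scale_manifest):
        by_pair = paper_scale_manifest.pivot(index="pair_id", columns="role", values="spacer")
        for t, mt in zip(by_pair["targeting"], by_pair["mismatch"]):
            assert make_mismatch(t) == mt
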