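"""Small DNA-string helpers used across modules."""

from cas13screen.errors import InvalidSequenceError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


def validate_dna(seq: str, *, context: str = "sequence") -> str:
    """Return ``seq`` uppercased, raising if it contains non-ACGT characters."""
    seq = seq.upper()
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise InvalidSequenceError(f"{context} contains non-ACGT characters: {bad}")
    return seq


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
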