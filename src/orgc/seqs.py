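"""Small nucleotide-sequence helpers shared across modules.

The accepted alphabet is A, C, G, T, N (uppercase after normalization);
anything else is rejected so that GC content and reverse complements are
deterministic.
"""

from __future__ import annotations

from Bio.Seq import reverse_complement as _bio_revcomp

ALPHABET = frozenset("ACGTN")


def normalize(seq: str, *, context: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it uses only A/C/G/T/N."""
    s = seq.upper()
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(
            f"{context} contains non-IUPAC characters {sorted(bad)!r}; "
            "only A, C, G, T, N are accepted"
        )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return str(_bio_revcomp(seq))


def rotate(seq: str, k: int) -> str:
    """Rotation of a circular sequence so that position ``k`` comes first."""
    k %= len(seq)
    return seq[k:] + seq[:k]
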