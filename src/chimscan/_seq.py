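"""Small nucleotide-string helpers shared across the package."""

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Used as the strand-insensitive key for k-mer counting, so that mates
    sequenced from opposite strands of the same fragment co-count.
    """
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def is_acgt(seq: str) -> bool:
    return not set(seq) - ALPHABET
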