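"""Exact k-mer index of the reference plus per-read location/support profiles.

The junction caller works from two per-read profiles:

* a :class:`LocationProfile` lists, for every k-mer of the read, all genomic
  loci (chromosome, 1-based start, strand) where that k-mer occurs — the
  "genomic locations" signal;
* a :class:`SupportProfile` lists, for every k-mer of the read, how many
  times that k-mer occurs across the whole read collection (canonical-form
  counting, so mates on opposite strands co-count) — the "local coverage"
  signal that separates one-off sequencing errors from real junctions.

The index is a plain in-memory hash of canonical k-mers; it targets
desk-scale genomes (tens to hundreds of kilobases), not whole mammalian
references.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import canonical, is_acgt, revcomp

#: A genomic locus of a k-mer: (chromosome, 1-based start on the forward
#: strand, strand). strand +1 means the queried k-mer equals the forward
#: genome at [start, start+k-1]; strand -1 means it equals the reverse
#: complement of that window.
Location = tuple[str, int, int]


class KmerIndex:
    """Exact k-mer -> genomic locations map, canonical-key storage."""

    def __init__(self, k: int):
        if k < 12:
            raise ValueError(f"k must be >= 12 for collision control, got {k}")
        self.k = k
        self._entries: dict[str, list[Location]] = {}

    def __len__(self):
        return len(self._entries)

    @property
    def n_locations(self) -> int:
        return sum(len(v) for v in self._entries.values())

    def add(self, kmer: str, chrom: str, start: int):
        c = canonical(kmer)
        strand = 1 if kmer == c else -1
        self._entries.setdefault(c, []).append((chrom, start, strand))

    def locate(self, kmer: str) -> list[Location]:
        """All genomic loci of ``kmer``, strand-explicit.

        Returns an empty list for absent or non-ACGT k-mers.  A locus with
        strand -1 means ``kmer`` matches the reverse complement of the
        forward genome at that window.
        """
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        if not is_acgt(kmer):
            return []
        c = canonical(kmer)
        hits = self._entries.get(c)
        if hits is None:
            return []
        if kmer == c:
            return list(hits)
        return [(chrom, pos, -strand) for chrom, pos, strand in hits]


def build_index(genome, k: int = 22) -> KmerIndex:
    """Index every k-mer of every chromosome (both strands queryable).

    ``genome`` is anything exposing ``chromosomes: dict[name, sequence]``
    (e.g. :class:`~chimscan.simulate.SyntheticGenome`).  k-mers containing
    non-ACGT characters are skipped.
    """
    min_len = min(len(s) for s in genome.chromosomes.values())
    if k >= min_len:
        raise ValueError(f"k={k} is not smaller than the shortest chromosome ({min_len})")
    index = KmerIndex(k)
    for chrom, seq in genome.chromosomes.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if not is_acgt(kmer):
                continue
            index.add(kmer, chrom, i + 1)
    return index


@dataclass
class LocationProfile:
    """Per-offset genomic locations for every k-mer of one read."""

    read_id: str
    read: str
    k: int
    locations: list[list[Location]]

    def __post_init__(self):
        expected = len(self.read) - self.k + 1
        if len(self.locations) != expected:
            raise ValueError(
                f"profile has {len(self.locations)} offsets, expected {expected}")


@dataclass
class SupportProfile:
    """Per-offset occurrence count of every k-mer across the read collection."""

    read_id: str
    k: int
    counts: list[int]


def locate_profile(read: str, index: KmerIndex, read_id: str = "") -> LocationProfile:
    """Genomic locations of every k-mer of ``read`` (strand-aware)."""
    read = read.upper()
    k = index.k
    if len(read) < k:
        raise ValueError(f"read length {len(read)} < k={k}")
    locs = [index.locate(read[i:i + k]) if is_acgt(read[i:i + k]) else []
            for i in range(len(read) - k + 1)]
    return LocationProfile(read_id=read_id, read=read, k=k, locations=locs)


def count_read_kmers(reads, k: int) -> dict[str, int]:
    """Canonical k-mer multiplicities over a whole read collection.

    ``reads`` is an iterable of sequences. Windows containing non-ACGT
    characters contribute nothing.  Counts are read-order independent.
    """
    counts: dict[str, int] = {}
    for seq in reads:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if not is_acgt(kmer):
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    return counts


def support_profile(read: str, kmer_counts: dict[str, int], k: int,
                    read_id: str = "") -> SupportProfile:
    """Per-offset multiplicity of each k-mer of ``read`` in the collection.

    ``kmer_counts`` must have been built over a collection containing the
    read itself, so ACGT windows always count at least 1.
    """
    read = read.upper()
    if len(read) < k:
        raise ValueError(f"read length {len(read)} < k={k}")
    counts = []
    for i in range(len(read) - k + 1):
        kmer = read[i:i + k]
        counts.append(kmer_counts.get(canonical(kmer), 0) if is_acgt(kmer) else 0)
    return SupportProfile(read_id=read_id, k=k, counts=counts)
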