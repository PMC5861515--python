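"""Exact junction-tag counting in raw FASTQ for recurrence screening.

A junction tag is a 30-nt sequence centered on a chimeric junction (15
transcript bases from the 5' partner, 15 from the 3' partner).  Because the
tag crosses the junction, an exact occurrence in a read is evidence for the
chimera itself, independent of any mapping — which makes tag counting usable
for screening large FASTQ cohorts for recurrence of a known event.

Counting is a streaming scan: every length-30 window of every read is
compared against the tag set and the reverse complements of the tags; per
file, raw counts are reported next to the file's total window count ("total
k-mers") and a count normalized per 5 billion k-mers.  A window equal to
both a tag and that same tag's reverse complement (a palindrome) counts
once.  Windows containing N can never match but still count toward the
denominator.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import is_acgt, revcomp

NORMALIZATION_KMERS = 5_000_000_000


@dataclass(frozen=True)
class TagRecord:
    """A junction tag: id (typically the chimera id) and its sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence or len(self.sequence) % 2 != 0:
            raise ValueError(
                f"tag {self.id}: length must be even and positive, "
                f"got {len(self.sequence)}")
        if not is_acgt(self.sequence):
            raise ValueError(f"tag {self.id}: alphabet must be A/C/G/T")


def extract_tag(junction_sequence: str, junction_offset: int,
                tag_len: int = 30, tag_id: str = "tag") -> TagRecord:
    """Cut the tag window centered on a junction from a reconstructed fusion
    sequence.

    ``junction_offset`` is the 1-based index of the last base of the 5' part;
    the tag takes exactly ``tag_len/2`` bases from each side.  Raises when a
    flank is too short (no silent shifting) or ``tag_len`` is odd.
    """
    if tag_len % 2 != 0:
        raise ValueError(f"tag_len must be even, got {tag_len}")
    half = tag_len // 2
    if junction_offset < half:
        raise ValueError(
            f"only {junction_offset} bases 5' of the junction, need {half}")
    if len(junction_sequence) - junction_offset < half:
        raise ValueError(
            f"only {len(junction_sequence) - junction_offset} bases 3' of the "
            f"junction, need {half}")
    seq = junction_sequence[junction_offset - half:junction_offset + half].upper()
    return TagRecord(id=tag_id, sequence=seq)


def read_tags_fasta(path) -> list[TagRecord]:
    return [TagRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_tags_fasta(tags, path) -> None:
    with open(path, "w") as fh:
        for tag in tags:
            fh.write(f">{tag.id}\n{tag.sequence}\n")


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path):
    try:
        with _open_maybe_gzip(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq).upper()
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


@dataclass
class TagCountTable:
    """Per-(tag, file) raw and normalized counts."""

    frame: pd.DataFrame

    def raw(self, tag_id: str, file: str) -> int:
        sel = self.frame[(self.frame.tag_id == tag_id) & (self.frame.file == file)]
        return int(sel.raw_count.iloc[0])

    def normalized(self, tag_id: str, file: str) -> float:
        sel = self.frame[(self.frame.tag_id == tag_id) & (self.frame.file == file)]
        return float(sel.normalized_count.iloc[0])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def count_in_sequences(tags, sequences) -> tuple[dict[str, int], int]:
    """Core scan over an iterable of read sequences.

    Returns ``(per-tag raw counts, total window count)``.  All tags must
    share one length; every window of that length in every read is compared
    against the tags and their reverse complements.
    """
    tags = list(tags)
    if not tags:
        raise ValueError("no tags given")
    lengths = {len(t.sequence) for t in tags}
    if len(lengths) != 1:
        raise ValueError(f"tags must share one length, got {sorted(lengths)}")
    (tlen,) = lengths
    lookup: dict[str, set[str]] = {}
    for tag in tags:
        lookup.setdefault(tag.sequence, set()).add(tag.id)
        lookup.setdefault(revcomp(tag.sequence), set()).add(tag.id)
    counts = {t.id: 0 for t in tags}
    total_kmers = 0
    for seq in sequences:
        n_windows = len(seq) - tlen + 1
        if n_windows <= 0:
            continue
        total_kmers += n_windows
        for i in range(n_windows):
            ids = lookup.get(seq[i:i + tlen])
            if ids:
                for tag_id in ids:
                    counts[tag_id] += 1
    return counts, total_kmers


def normalize_tag_counts(raw: int, total_kmers: int) -> float:
    """Tag count per 5 billion k-mers: ``raw * 5e9 / total_kmers``."""
    if total_kmers <= 0:
        raise ValueError("total_kmers must be positive")
    return raw * NORMALIZATION_KMERS / total_kmers


def count_tags(tags, fastqs) -> TagCountTable:
    """Stream each FASTQ once, counting exact tag and reverse-complement hits.

    ``tags`` is a list of :class:`TagRecord` or a path to a tag FASTA;
    ``fastqs`` a list of FASTQ paths (plain or gzip).  Deterministic and
    file-order independent: each file is counted against its own denominator.
    """
    if isinstance(tags, (str, Path)):
        tags = read_tags_fasta(tags)
    rows = []
    for path in fastqs:
        counts, total_kmers = count_in_sequences(tags, _iter_fastq(path))
        for tag in tags:
            raw = counts[tag.id]
            rows.append({
                "tag_id": tag.id,
                "file": str(path),
                "raw_count": raw,
                "total_kmers": total_kmers,
                "normalized_count":
                    normalize_tag_counts(raw, total_kmers) if total_kmers else 0.0,
            })
    return TagCountTable(frame=pd.DataFrame(rows))
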