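"""Chimeric-junction classification, aggregation and scoring.

A chimeric RNA (chRNA) joins two genomic loci that are not collinear within
one annotated gene.  Each junction is described by two :class:`GenomicSide`
objects: the *left* side is the genomic position of the last transcribed base
of the 5' fragment (Pos1), the *right* side the first transcribed base of the
3' fragment (Pos2).  Junctions fall into four classes by geometry:

* class 1 -- the two sides lie on different chromosomes (translocation-type);
* class 2 -- same chromosome and strand, in transcriptional (collinear)
  order: read-through / cis-splicing candidates, to be resolved through the
  annotation;
* class 3 -- same chromosome and strand but *not* in transcriptional order
  (intra-exonic inversions, tandem duplications such as FLT3-ITD);
* class 4 -- same chromosome, opposite strands (inversion-type, e.g.
  CBFB-MYH11).

This module also aggregates per-read junction candidates into chimera
records with raw and per-billion-read normalized support counts, and scores
each record with a 0-100 confidence value (``chim_value``) combining mapping
ambiguity and read-support consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import canonical, revcomp


@dataclass(frozen=True, order=True)
class GenomicSide:
    """One side of a junction: chromosome, 1-based position, strand (+1/-1)."""

    chrom: str
    pos: int
    strand: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")


def classify(left: GenomicSide, right: GenomicSide) -> int:
    """Assign the 4-way chimera class from junction geometry alone.

    Total and deterministic: every (left, right) pair maps to exactly one
    class.  Collinearity on the minus strand means descending genomic
    coordinates (transcription runs right-to-left), so ``left.pos >
    right.pos`` is the collinear case there.  Position ties on the same
    chromosome and strand fall into class 3: a zero-length gap is the
    degenerate non-collinear case, matching the overlapping-fragment
    (tandem-duplication) subtype.
    """
    if left.chrom != right.chrom:
        return 1
    if left.strand != right.strand:
        return 4
    if left.strand == 1 and left.pos < right.pos:
        return 2
    if left.strand == -1 and left.pos > right.pos:
        return 2
    return 3


@dataclass
class ChimeraRecord:
    """Aggregated, annotated, scored chimera.

    ``spanning_junction_raw`` counts distinct reads whose sequence crosses
    the junction; ``spanning_pe_raw`` counts distinct read pairs whose mates
    flank the junction with the junction itself in the unsequenced insert.
    Normalized values are per billion input reads (both mates counted).
    """

    id: str
    sample: str
    left: GenomicSide
    right: GenomicSide
    cls: int
    spanning_junction_raw: int
    spanning_pe_raw: int
    spanning_junction_norm: float
    spanning_pe_norm: float
    chim_value: float | None = None
    chim_value_flag: str | None = None
    gene_left: str | None = None
    gene_right: str | None = None
    left_fragment: tuple[str, int, int] | None = None
    right_fragment: tuple[str, int, int] | None = None
    read_ids: tuple[str, ...] = field(default_factory=tuple)
    pair_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def key(self) -> tuple[GenomicSide, GenomicSide]:
        return (self.left, self.right)

    @property
    def gap(self) -> int | None:
        """Bases between the two junction endpoints on one chromosome."""
        if self.left.chrom != self.right.chrom:
            return None
        return abs(self.right.pos - self.left.pos) - 1

    @property
    def fusion_name(self) -> str:
        a = self.gene_left or "NONE"
        b = self.gene_right or "NONE"
        return f"{a}-{b}"


def _merge_fragment(a, b):
    if a is None:
        return b
    if b is None:
        return a
    if a[0] != b[0]:
        return a
    return (a[0], min(a[1], b[1]), max(a[2], b[2]))


def aggregate(candidates, pe_support=None, sample: str = "sample",
              total_reads: int = 0) -> list[ChimeraRecord]:
    """Group junction candidates by exact (left, right) key into records.

    Parameters
    ----------
    candidates
        Iterable of :class:`~chimscan.junction_caller.JunctionCandidate`,
        already canonicalized (micro-homology left-shifted) upstream, so
        exact-coordinate grouping suffices.
    pe_support
        Optional mapping ``(left, right) -> set of pair ids`` from
        :func:`~chimscan.junction_caller.find_spanning_pairs`.
    total_reads
        Total number of input reads (both mates counted); the denominator
        of the per-billion normalization.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be a positive read count")
    pe_support = pe_support or {}
    order: list[tuple[GenomicSide, GenomicSide]] = []
    merged: dict[tuple, dict] = {}
    for cand in candidates:
        key = (cand.left, cand.right)
        if key not in merged:
            order.append(key)
            merged[key] = {
                "reads": set(),
                "left_frag": None,
                "right_frag": None,
            }
        slot = merged[key]
        slot["reads"].update(cand.read_ids)
        slot["left_frag"] = _merge_fragment(slot["left_frag"], cand.left_fragment)
        slot["right_frag"] = _merge_fragment(slot["right_frag"], cand.right_fragment)

    records = []
    for i, key in enumerate(order, start=1):
        left, right = key
        slot = merged[key]
        sj = len(slot["reads"])
        pairs = set(pe_support.get(key, ()))
        pe = len(pairs)
        records.append(ChimeraRecord(
            id=f"{sample}:{i}",
            sample=sample,
            left=left,
            right=right,
            cls=classify(left, right),
            spanning_junction_raw=sj,
            spanning_pe_raw=pe,
            spanning_junction_norm=sj * 1e9 / total_reads,
            spanning_pe_norm=pe * 1e9 / total_reads,
            left_fragment=slot["left_frag"],
            right_fragment=slot["right_frag"],
            read_ids=tuple(sorted(slot["reads"])),
            pair_ids=tuple(sorted(pairs)),
        ))
    return records


def _anchor_kmers(record: ChimeraRecord, genome, k: int) -> tuple[str, str]:
    """Transcript-sense k-mers immediately flanking the junction.

    Left anchor: the k bases whose last transcribed base is Pos1.
    Right anchor: the k bases whose first transcribed base is Pos2.
    """
    ls = record.left
    rs = record.right
    if ls.strand == 1:
        kl = genome.fetch(ls.chrom, ls.pos - k + 1, ls.pos)
    else:
        kl = revcomp(genome.fetch(ls.chrom, ls.pos, ls.pos + k - 1))
    if rs.strand == 1:
        kr = genome.fetch(rs.chrom, rs.pos, rs.pos + k - 1)
    else:
        kr = revcomp(genome.fetch(rs.chrom, rs.pos - k + 1, rs.pos))
    return kl, kr


def chim_value(record: ChimeraRecord, genome, index, kmer_counts=None) -> float:
    """Confidence score in [0, 100] for one chimera record.

    ``score = 100 * P_loc * P_support`` where

    * ``P_loc = 1 / (nL * nR)`` penalizes mapping ambiguity; nL and nR are
      the genomic hit counts of the two junction-flanking anchor k-mers
      (pseudogene-like multi-mapping anchors drive the score toward 0);
    * ``P_support = min(1, 2s / (cL + cR))`` compares the spanning-read
      count ``s`` with the read coverage of the two anchors: a real junction
      is crossed by a representative share of the local reads, whereas an
      artefact carried by a few reads against deep local coverage scores low.

    When coverage information is unavailable (``kmer_counts is None`` or the
    anchors are absent from the count table) the score is computed with
    ``P_support = 1`` and the record's ``chim_value_flag`` is set.

    The score is stored on ``record.chim_value`` and also returned.
    """
    k = index.k
    kl, kr = _anchor_kmers(record, genome, k)
    n_left = max(1, len(index.locate(kl)))
    n_right = max(1, len(index.locate(kr)))
    p_loc = 1.0 / (n_left * n_right)

    flag = None
    if kmer_counts is None:
        p_support = 1.0
        flag = "no_coverage"
    else:
        c_left = kmer_counts.get(canonical(kl), 0)
        c_right = kmer_counts.get(canonical(kr), 0)
        if c_left + c_right == 0:
            p_support = 1.0
            flag = "no_coverage"
        else:
            p_support = min(1.0, 2.0 * record.spanning_junction_raw / (c_left + c_right))

    score = 100.0 * p_loc * p_support
    record.chim_value = score
    record.chim_value_flag = flag
    return score


#: Column order of the tabular chimera report (first 12 columns).
RECORD_COLUMNS = [
    "ID", "Fusion_genes", "Chr_left", "Pos1", "Strand1",
    "Chr_right", "Pos2", "Strand2", "ChimValue",
    "Spanning_junction_normalized", "Spanning_PE_normalized", "Class",
]


def record_row(record: ChimeraRecord) -> dict:
    """The 12-field representation of one record, report column order."""
    return {
        "ID": record.id,
        "Fusion_genes": record.fusion_name,
        "Chr_left": record.left.chrom,
        "Pos1": record.left.pos,
        "Strand1": record.left.strand,
        "Chr_right": record.right.chrom,
        "Pos2": record.right.pos,
        "Strand2": record.right.strand,
        "ChimValue": round(record.chim_value, 4) if record.chim_value is not None else "",
        "Spanning_junction_normalized": record.spanning_junction_norm,
        "Spanning_PE_normalized": record.spanning_pe_norm,
        "Class": record.cls,
    }
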