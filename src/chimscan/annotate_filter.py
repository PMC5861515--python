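"""GFF3 gene models, exon-priority endpoint annotation, and the filter cascade.

Junction endpoints are annotated against an ENSEMBL-dialect GFF3 hierarchy
(gene -> mRNA -> exon) with exon hits outranking intronic gene hits, strand
matching on the gene's coding strand (antisense overlaps annotate as NONE
with a note), and "NONE" for positions in unannotated transcribed regions.

The filter cascade keeps a chimera record when it has at least one
junction-spanning read, paired-end support, at least one gene-annotated side,
a confidence score above threshold, and is not a same-gene collinear event
(a splice) nor a collinear fusion of adjacent genes closer than the adjacency
cutoff. Two subtype callers flag read-through (class 2, short fusion
distance, junctions at exon boundaries) and tandem-repeat / ITD-type events
(class 3, overlapping genomic fragments within a single exon).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import gffutils
import yaml
from intervaltree import IntervalTree

from .chimera_core import ChimeraRecord, GenomicSide

NONE_LABEL = "NONE"


@dataclass(frozen=True)
class Exon:
    id: str
    gene_id: str
    transcript_id: str
    chrom: str
    strand: int
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exon {self.id}: start > end")


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: int
    start: int
    end: int
    exons: list[Exon] = field(default_factory=list)


@dataclass
class Gene:
    id: str
    name: str
    chrom: str
    strand: int
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def exons(self) -> list[Exon]:
        return [e for t in self.transcripts for e in t.exons]


def _strand_char(strand: int) -> str:
    return "+" if strand == 1 else "-"


def _strand_int(char: str) -> int:
    if char == "+":
        return 1
    if char == "-":
        return -1
    raise ValueError(f"unstranded feature (strand {char!r}) not supported")


class GeneModels:
    """Genes/transcripts/exons with strand-aware interval lookup."""

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.id in self.genes:
                raise ValueError(f"duplicate gene id {gene.id}")
            self.genes[gene.id] = gene
            self._gene_trees.setdefault(gene.chrom, IntervalTree()).addi(
                gene.start, gene.end + 1, gene)
            for exon in gene.exons:
                if not (gene.start <= exon.start and exon.end <= gene.end):
                    raise ValueError(f"exon {exon.id} outside gene {gene.id} span")
                self._exon_trees.setdefault(gene.chrom, IntervalTree()).addi(
                    exon.start, exon.end + 1, exon)

    def __len__(self):
        return len(self.genes)

    def genes_at(self, chrom: str, pos: int, strand: int | None = None) -> list[Gene]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.start, g.id))

    def exons_at(self, chrom: str, pos: int, strand: int | None = None) -> list[Exon]:
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        if strand is not None:
            hits = [e for e in hits if e.strand == strand]
        return sorted(hits, key=lambda e: (e.start, e.id))

    def exons_containing(self, chrom: str, start: int, end: int,
                         strand: int | None = None) -> list[Exon]:
        """Exons that fully contain [start, end]."""
        return [e for e in self.exons_at(chrom, start, strand)
                if e.start <= start and end <= e.end]

    # ------------------------------------------------------------------ GFF3

    def to_gff3(self, path=None) -> str:
        """Serialize as ENSEMBL-dialect GFF3 (gene -> mRNA -> exon)."""
        lines = ["##gff-version 3"]
        for gene in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start)):
            s = _strand_char(gene.strand)
            lines.append("\t".join([
                gene.chrom, "chimscan", "gene", str(gene.start), str(gene.end),
                ".", s, ".", f"ID={gene.id};Name={gene.name}"]))
            for tx in gene.transcripts:
                lines.append("\t".join([
                    gene.chrom, "chimscan", "mRNA", str(tx.start), str(tx.end),
                    ".", s, ".", f"ID={tx.id};Parent={gene.id}"]))
                for exon in tx.exons:
                    lines.append("\t".join([
                        gene.chrom, "chimscan", "exon",
                        str(exon.start), str(exon.end), ".", s, ".",
                        f"ID={exon.id};Parent={tx.id}"]))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_gff3(cls, source) -> "GeneModels":
        """Parse GFF3 (path or literal text) via gffutils (in-memory db)."""
        source = str(source)
        from_string = "\n" in source or "\t" in source
        db = gffutils.create_db(source, dbfn=":memory:", from_string=from_string,
                                force=True, keep_order=True,
                                merge_strategy="create_unique")
        genes = []
        for g in db.features_of_type("gene"):
            gene = Gene(id=g.id, name=g.attributes.get("Name", [g.id])[0],
                        chrom=g.seqid, strand=_strand_int(g.strand),
                        start=g.start, end=g.end)
            for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
                tx = Transcript(id=t.id, gene_id=g.id, chrom=t.seqid,
                                strand=_strand_int(t.strand),
                                start=t.start, end=t.end)
                for i, e in enumerate(db.children(t, featuretype="exon",
                                                  order_by="start"), start=1):
                    tx.exons.append(Exon(
                        id=e.id or f"{t.id}.exon{i}", gene_id=g.id,
                        transcript_id=t.id, chrom=e.seqid,
                        strand=_strand_int(e.strand), start=e.start, end=e.end))
                gene.transcripts.append(tx)
            genes.append(gene)
        return cls(genes)


@dataclass
class EndpointAnnotation:
    """Annotation of one junction side.

    ``gene`` is None for the NONE case (no strand-matching gene overlaps the
    position). ``exon_end_distance`` is the distance from the junction
    position to the exon boundary facing the junction: the transcript 3' end
    of the exon for a left (5') side, the transcript 5' start for a right
    (3') side; None when no exon matched.  ``antisense`` marks positions
    overlapped only by a gene on the opposite strand.
    """

    gene: str | None
    exon: str | None
    exon_end_distance: int | None
    priority: str            # "exon" | "gene" | "none"
    antisense: bool = False

    @property
    def label(self) -> str:
        return self.gene if self.gene is not None else NONE_LABEL


def _facing_distance(exon: Exon, pos: int, role: str) -> int:
    """Distance from pos to the exon boundary facing the junction."""
    if role == "left":       # junction continues past the exon 3' end
        return exon.end - pos if exon.strand == 1 else pos - exon.start
    # right side: junction arrived at the exon 5' start
    return pos - exon.start if exon.strand == 1 else exon.end - pos


def annotate_endpoint(side: GenomicSide, models: GeneModels,
                      role: str = "left") -> EndpointAnnotation:
    """Exon-priority, strand-matched annotation of one junction side.

    ``role`` is "left" for the 5' side of the junction and "right" for the
    3' side; it selects which exon boundary the exon-end distance is
    measured to.  Unknown chromosomes yield NONE.
    """
    if role not in ("left", "right"):
        raise ValueError(f"role must be 'left' or 'right', got {role!r}")
    exons = models.exons_at(side.chrom, side.pos, side.strand)
    if exons:
        best = min(exons, key=lambda e: (_facing_distance(e, side.pos, role), e.id))
        gene = models.genes[best.gene_id]
        return EndpointAnnotation(gene=gene.name, exon=best.id,
                                  exon_end_distance=_facing_distance(best, side.pos, role),
                                  priority="exon")
    genes = models.genes_at(side.chrom, side.pos, side.strand)
    if genes:
        return EndpointAnnotation(gene=genes[0].name, exon=None,
                                  exon_end_distance=None, priority="gene")
    antisense = bool(models.genes_at(side.chrom, side.pos, -side.strand))
    return EndpointAnnotation(gene=None, exon=None, exon_end_distance=None,
                              priority="none", antisense=antisense)


@dataclass
class FilterThresholds:
    """All tunables of the filter cascade and the clustering gene selection.

    Defaults mirror the published procedure: >=1 spanning-junction read,
    paired-end support required, at least one annotated side, ChimValue >= 60,
    adjacent collinear genes closer than 3 kb discarded, read-through called
    at <= 300 kb fusion distance and <= 20 bp exon-end distance, clustering
    keeps events with ChimValue > 75 (strict) and >= 3 spanning reads, and
    genes taking part in >= 2 distinct events.
    """

    min_spanning_junction: int = 1
    require_pe: bool = True
    min_annotated_sides: int = 1
    min_chim_value: float = 60.0
    adjacent_gene_distance: int = 3000
    readthrough_max_distance: int = 300_000
    readthrough_max_exon_end: int = 20
    clustering_min_chim_value: float = 75.0
    clustering_min_spanning: int = 3
    clustering_min_events: int = 2

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not isinstance(value, bool) and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterThresholds":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "FilterThresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


#: Rule names in cascade order; the rejection log records the first failure.
FILTER_RULES = ("spanning_junction", "pe_support", "annotation",
                "chim_value", "splice", "adjacent_genes")


def _first_failing_rule(record: ChimeraRecord, anns, thresholds) -> str | None:
    ann_left, ann_right = anns
    if record.spanning_junction_raw < thresholds.min_spanning_junction:
        return "spanning_junction"
    if thresholds.require_pe and record.spanning_pe_raw < 1:
        return "pe_support"
    n_annotated = (ann_left.gene is not None) + (ann_right.gene is not None)
    if n_annotated < thresholds.min_annotated_sides:
        return "annotation"
    if record.chim_value is not None and record.chim_value < thresholds.min_chim_value:
        return "chim_value"
    if record.cls == 2 and ann_left.gene is not None and ann_left.gene == ann_right.gene:
        return "splice"
    if (record.cls == 2 and ann_left.gene and ann_right.gene
            and ann_left.gene != ann_right.gene
            and record.gap is not None
            and record.gap < thresholds.adjacent_gene_distance):
        return "adjacent_genes"
    return None


def apply_filters(records, annotations, thresholds: FilterThresholds | None = None):
    """Run the filter cascade.

    ``annotations`` maps record id -> (left EndpointAnnotation, right
    EndpointAnnotation).  Returns ``(kept, rejections)`` where rejections is
    a list of ``(record, rule)`` naming the first failing rule; every input
    record appears in exactly one of the two outputs.
    """
    thresholds = thresholds or FilterThresholds()
    kept, rejections = [], []
    for record in records:
        rule = _first_failing_rule(record, annotations[record.id], thresholds)
        if rule is None:
            kept.append(record)
        else:
            rejections.append((record, rule))
    return kept, rejections


def call_readthrough(record: ChimeraRecord, annotations,
                     thresholds: FilterThresholds | None = None) -> bool:
    """Read-through flag: class 2, short fusion distance, exon-boundary ends.

    True iff the record is class 2, the junction gap is at most
    ``readthrough_max_distance`` and both endpoints lie within
    ``readthrough_max_exon_end`` bases of the exon boundary facing the
    junction.  An unannotated (or intronic) side yields False.
    """
    thresholds = thresholds or FilterThresholds()
    if record.cls != 2:
        return False
    gap = record.gap
    if gap is None or gap > thresholds.readthrough_max_distance:
        return False
    ann_left, ann_right = annotations
    for ann in (ann_left, ann_right):
        if ann.exon_end_distance is None:
            return False
        if ann.exon_end_distance > thresholds.readthrough_max_exon_end:
            return False
    return True


def call_tandem_repeat(record: ChimeraRecord, models: GeneModels) -> bool:
    """Tandem-repeat (ITD-type) flag: class 3, overlapping fragments, one exon.

    True iff the record is class 3, its left and right genomic fragment
    intervals overlap, and a single exon of a single gene fully contains both
    fragments.  Missing fragment intervals yield False.
    """
    if record.cls != 3:
        return False
    lf, rf = record.left_fragment, record.right_fragment
    if lf is None or rf is None:
        return False
    if lf[0] != rf[0]:
        return False
    if lf[2] < rf[1] or rf[2] < lf[1]:
        return False                               # disjoint on the genome
    lo = min(lf[1], rf[1])
    hi = max(lf[2], rf[2])
    return bool(models.exons_containing(lf[0], lo, hi, record.left.strand))


def select_clustering_genes(entries, models: GeneModels,
                            thresholds: FilterThresholds | None = None) -> dict:
    """Candidate-gene selection for expression clustering.

    ``entries`` is an iterable of ``(record, (ann_left, ann_right))``, taken
    across one or more samples.  Events with ChimValue strictly greater than
    ``clustering_min_chim_value`` and at least ``clustering_min_spanning``
    spanning reads are partitioned into read-through and tandem-repeat types
    (mutually exclusive by class); a gene is selected for a type when it
    participates in at least ``clustering_min_events`` distinct events of
    that type, from the same or different samples.

    Returns ``{"read_through": [genes...], "tandem_repeat": [genes...]}``.
    """
    thresholds = thresholds or FilterThresholds()
    participation = {"read_through": {}, "tandem_repeat": {}}
    for record, anns in entries:
        if record.chim_value is None or record.chim_value <= thresholds.clustering_min_chim_value:
            continue
        if record.spanning_junction_raw < thresholds.clustering_min_spanning:
            continue
        if call_readthrough(record, anns, thresholds):
            kind = "read_through"
        elif call_tandem_repeat(record, models):
            kind = "tandem_repeat"
        else:
            continue
        for ann in anns:
            if ann.gene is None:
                continue
            participation[kind].setdefault(ann.gene, set()).add(record.id)
    return {
        kind: sorted(g for g, events in genes.items()
                     if len(events) >= thresholds.clustering_min_events)
        for kind, genes in participation.items()
    }
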