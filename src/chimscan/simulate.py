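"""Synthetic genome, gene models, planted chimeras and stranded PE reads.

Everything the pipeline consumes can be generated here at desk scale: a
random A/C/G/T genome of a few chromosomes, a non-overlapping gene annotation
(gene -> mRNA -> exon, both strands, with intergenic gaps), fusion
transcripts planting chimeric junctions of all four geometry classes, and
error-bearing stranded paired-end reads with a per-pair truth table.  All
outputs are pure functions of their inputs and a seed.

Planting details that matter downstream:

* class 2 is planted in two flavors -- adjacent genes (junction gap < 3 kb,
  the read-through geometry) and the most distant same-strand gene pair the
  chromosome allows (with the gap recorded; on a multi-hundred-kb chromosome
  this exceeds the 300 kb read-through cutoff);
* class 3 is planted in two flavors -- an intra-exonic inversion (disjoint
  fragments, exon 3' part before its 5' part) and a tandem duplication
  (overlapping genomic fragments within one exon, FLT3-ITD-like);
* junction micro-homology is removed by construction (the 3' fragment start
  is nudged until the base after Pos1 on the 5' locus differs from the base
  at Pos2), so truth coordinates coincide with the caller's left-shift
  canonicalization and junctions stay at exon boundaries.

The stranded protocol default is dUTP-style (``fr-firststrand``): mate 1 is
sequenced from the reverse complement of the fragment 3' end, mate 2 forward
from the fragment 5' end.  Errors are base substitutions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import complement, revcomp
from .annotate_filter import Exon, Gene, GeneModels, Transcript
from .chimera_core import GenomicSide, classify

PHRED33_Q30 = "?"          # fixed placeholder quality for every base


class CapacityError(ValueError):
    """The genome/annotation cannot host the requested structure."""


@dataclass
class SyntheticGenome:
    """A small in-memory reference: chromosome name -> ACGT sequence."""

    chromosomes: dict[str, str]
    seed: int | None = None

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name} is empty")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive substring of a chromosome."""
        seq = self.chromosomes[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"bad fetch {chrom}:{start}-{end}")
        return seq[start - 1:end]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "SyntheticGenome":
        from Bio import SeqIO
        chroms = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(path), "fasta")}
        return cls(chromosomes=chroms)


def make_genome(n_chrom: int, length: int, seed: int = 0) -> SyntheticGenome:
    """Uniform-random ACGT genome; deterministic per seed."""
    if n_chrom < 1:
        raise ValueError(f"n_chrom must be >= 1, got {n_chrom}")
    if length < 1000:
        raise ValueError(f"chromosome length must be >= 1000, got {length}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chroms = {f"chr{i + 1}": "".join(bases[rng.integers(0, 4, size=length)])
              for i in range(n_chrom)}
    return SyntheticGenome(chromosomes=chroms, seed=seed)


def make_annotation(genome: SyntheticGenome, n_genes: int,
                    exons_per_gene: tuple[int, int] = (2, 5),
                    seed: int = 0) -> GeneModels:
    """Place non-overlapping genes with exon/intron structure on both strands.

    The transcript-first and transcript-last exon of every gene are large
    (>=560 bp) so junction fragments fit inside single exons; interior exons
    are short.  Strands cycle ``+ + - -`` and intergenic gaps cycle through
    small (< 3 kb) and larger values, guaranteeing same-strand adjacent gene
    pairs inside and outside the adjacency-discard window.  Raises
    :class:`CapacityError` when the genome cannot host ``n_genes``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = exons_per_gene
    if lo < 1 or hi < lo:
        raise ValueError(f"bad exons_per_gene range {exons_per_gene}")
    rng = np.random.default_rng(seed)
    strand_cycle = [1, 1, -1, -1]
    gap_cycle = [900, 3400, 1200, 3800]
    margin = 300

    genes: list[Gene] = []
    chrom_names = list(genome.chromosomes)
    chrom_idx = 0
    cursor = margin + int(rng.integers(0, 100))
    for gi in range(n_genes):
        n_exons = int(rng.integers(lo, hi + 1))
        exon_lens = [int(rng.integers(560, 640))]
        if n_exons >= 2:
            exon_lens += [int(rng.integers(150, 260)) for _ in range(n_exons - 2)]
            exon_lens.append(int(rng.integers(560, 640)))
        intron_lens = [int(rng.integers(100, 180)) for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)

        placed = False
        while chrom_idx < len(chrom_names):
            chrom = chrom_names[chrom_idx]
            chrom_len = len(genome.chromosomes[chrom])
            if cursor + span + margin <= chrom_len:
                placed = True
                break
            chrom_idx += 1
            cursor = margin + int(rng.integers(0, 100))
        if not placed:
            raise CapacityError(
                f"genome too small: placed {gi} of {n_genes} requested genes")

        strand = strand_cycle[gi % 4]
        start = cursor
        gene_id = f"gene{gi + 1}"
        tx_id = f"{gene_id}.t1"
        exons = []
        pos = start
        for ei, elen in enumerate(exon_lens):
            exons.append(Exon(id=f"{tx_id}.exon{ei + 1}", gene_id=gene_id,
                              transcript_id=tx_id, chrom=chrom, strand=strand,
                              start=pos, end=pos + elen - 1))
            pos += elen
            if ei < len(intron_lens):
                pos += intron_lens[ei]
        end = exons[-1].end
        tx = Transcript(id=tx_id, gene_id=gene_id, chrom=chrom, strand=strand,
                        start=start, end=end, exons=exons)
        genes.append(Gene(id=gene_id, name=f"GENE{gi + 1}", chrom=chrom,
                          strand=strand, start=start, end=end, transcripts=[tx]))
        cursor = end + gap_cycle[gi % 4] + int(rng.integers(0, 100))
    return GeneModels(genes)


@dataclass
class TruthChimera:
    """A planted chimera with its fusion transcript and truth coordinates."""

    label: str
    cls: int
    flavor: str
    left: GenomicSide
    right: GenomicSide
    left_fragment: tuple[str, int, int]
    right_fragment: tuple[str, int, int]
    fusion_transcript: str
    junction_offset: int           # 1-based transcript index of the last 5' base
    gene_left: str | None = None
    gene_right: str | None = None
    gap: int | None = None

    @property
    def tag(self) -> str:
        """30-nt junction tag: 15 transcript bases each side of the junction."""
        j = self.junction_offset
        return self.fusion_transcript[j - 15:j + 15]


def _tx_exons(gene: Gene) -> list[Exon]:
    """Exons of the gene's first transcript in transcription order."""
    exons = sorted(gene.transcripts[0].exons, key=lambda e: e.start)
    return exons if gene.strand == 1 else exons[::-1]


def _txn_slice(exon: Exon, offset: int, length: int) -> tuple[int, int]:
    """Genomic interval of a transcript-order window inside an exon."""
    if offset + length > exon.end - exon.start + 1:
        raise CapacityError(f"window ({offset}+{length}) exceeds exon {exon.id}")
    if exon.strand == 1:
        return (exon.start + offset, exon.start + offset + length - 1)
    return (exon.end - offset - length + 1, exon.end - offset)


def _sense(genome: SyntheticGenome, chrom: str, start: int, end: int,
           strand: int) -> str:
    seq = genome.fetch(chrom, start, end)
    return seq if strand == 1 else revcomp(seq)


def _side5(chrom, start, end, strand) -> GenomicSide:
    """Side of the last transcribed base of a fragment."""
    return GenomicSide(chrom, end if strand == 1 else start, strand)


def _side3(chrom, start, end, strand) -> GenomicSide:
    """Side of the first transcribed base of a fragment."""
    return GenomicSide(chrom, start if strand == 1 else end, strand)


def _sense_base(genome, chrom, pos, strand) -> str | None:
    seq = genome.chromosomes[chrom]
    if pos < 1 or pos > len(seq):
        return None
    return seq[pos - 1] if strand == 1 else complement(seq[pos - 1])


def _build_fusion(genome, label, cls, flavor, left_frag, right_frag,
                  gene_left=None, gene_right=None) -> TruthChimera:
    """Assemble a fusion transcript from two (chrom, start, end, strand)
    fragments, nudging the 3' fragment start to remove junction
    micro-homology so truth coordinates are already canonical."""
    lc, ls, le, lstrand = left_frag
    for _ in range(20):
        rc, rs, re_, rstrand = right_frag
        left_side = _side5(lc, ls, le, lstrand)
        right_side = _side3(rc, rs, re_, rstrand)
        after_left = _sense_base(genome, lc, left_side.pos + lstrand, lstrand)
        at_right = _sense_base(genome, rc, right_side.pos, rstrand)
        if after_left != at_right:
            break
        # shift the 3' fragment one base forward in transcription order
        right_frag = (rc, rs + 1, re_ + 1, 1) if rstrand == 1 else \
                     (rc, rs - 1, re_ - 1, -1)
    else:
        raise CapacityError(f"{label}: could not remove junction micro-homology")

    rc, rs, re_, rstrand = right_frag
    left_seq = _sense(genome, lc, ls, le, lstrand)
    right_seq = _sense(genome, rc, rs, re_, rstrand)
    left_side = _side5(lc, ls, le, lstrand)
    right_side = _side3(rc, rs, re_, rstrand)
    got = classify(left_side, right_side)
    if got != cls:
        raise CapacityError(
            f"{label}: planted geometry classifies as {got}, wanted {cls}")
    gap = abs(right_side.pos - left_side.pos) - 1 if lc == rc else None
    return TruthChimera(
        label=label, cls=cls, flavor=flavor,
        left=left_side, right=right_side,
        left_fragment=(lc, ls, le), right_fragment=(rc, rs, re_),
        fusion_transcript=left_seq + right_seq,
        junction_offset=len(left_seq),
        gene_left=gene_left, gene_right=gene_right, gap=gap,
    )


def _adjacent_pairs(models: GeneModels):
    """Consecutive same-chromosome, same-strand gene pairs in genomic order."""
    by_chrom: dict[str, list[Gene]] = {}
    for gene in models.genes.values():
        by_chrom.setdefault(gene.chrom, []).append(gene)
    pairs = []
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            if a.strand == b.strand:
                pairs.append((a, b))
    return pairs


def _exon_window_5p(gene: Gene, flank: int):
    """Window of the last ``flank`` transcript bases of the transcript-last
    big exon -- ends exactly at the gene's final exon boundary."""
    exon = _tx_exons(gene)[-1]
    elen = exon.end - exon.start + 1
    if elen < flank:
        raise CapacityError(f"exon {exon.id} shorter than flank {flank}")
    start, end = _txn_slice(exon, elen - flank, flank)
    return (exon.chrom, start, end, exon.strand)


def _exon_window_3p(gene: Gene, flank: int):
    """Window of the first ``flank`` transcript bases of the transcript-first
    big exon -- starts exactly at an exon boundary."""
    exon = _tx_exons(gene)[0]
    if exon.end - exon.start + 1 < flank:
        raise CapacityError(f"exon {exon.id} shorter than flank {flank}")
    start, end = _txn_slice(exon, 0, flank)
    return (exon.chrom, start, end, exon.strand)


def plant_chimeras(genome: SyntheticGenome, models: GeneModels,
                   spec: list[int], seed: int = 0,
                   flank: int = 250) -> list[TruthChimera]:
    """Plant one or more fusion transcripts per requested class label.

    Class 2 yields two chimeras (adjacent + distant flavors), class 3 two
    (intra-exonic inversion + tandem duplication); classes 1 and 4 one each.
    Raises :class:`CapacityError` when the annotation cannot satisfy a
    class's geometry.
    """
    if not set(spec) <= {1, 2, 3, 4}:
        raise ValueError(f"class labels must be in 1..4, got {spec}")
    rng = np.random.default_rng(seed)
    genes = sorted(models.genes.values(), key=lambda g: (g.chrom, g.start))
    used: set[str] = set()
    out: list[TruthChimera] = []

    def take(predicate, n=1, allow_used=False):
        pool = [g for g in genes if predicate(g) and (allow_used or g.id not in used)]
        if len(pool) < n:
            pool = [g for g in genes if predicate(g)]
        if len(pool) < n:
            raise CapacityError("not enough genes for the requested geometry")
        chosen = list(rng.choice(len(pool), size=n, replace=False))
        picked = [pool[i] for i in sorted(chosen)]
        used.update(g.id for g in picked)
        return picked

    for label_no, cls in enumerate(spec, start=1):
        if cls == 1:
            chroms = sorted({g.chrom for g in genes})
            if len(chroms) < 2:
                raise CapacityError("class 1 needs genes on >= 2 chromosomes")
            (ga,) = take(lambda g: g.chrom == chroms[0])
            (gb,) = take(lambda g: g.chrom == chroms[1])
            out.append(_build_fusion(
                genome, f"class1_{label_no}", 1, "interchromosomal",
                _exon_window_5p(ga, flank), _exon_window_3p(gb, flank),
                ga.name, gb.name))

        elif cls == 2:
            pairs = _adjacent_pairs(models)
            near = [(a, b) for a, b in pairs if b.start - a.end - 1 < 3000]
            if not near:
                raise CapacityError("no adjacent same-strand gene pair < 3 kb")
            fresh = [(a, b) for a, b in near
                     if a.id not in used and b.id not in used]
            a, b = (fresh or near)[0]
            up, down = (a, b) if a.strand == 1 else (b, a)
            used.update((up.id, down.id))
            out.append(_build_fusion(
                genome, f"class2_adjacent_{label_no}", 2, "adjacent",
                _exon_window_5p(up, flank), _exon_window_3p(down, flank),
                up.name, down.name))

            far_pairs = sorted(
                ((x, y) for x in genes for y in genes
                 if x.chrom == y.chrom and x.strand == y.strand
                 and x.end < y.start),
                key=lambda p: p[0].end - p[1].start)   # most distant first
            if not far_pairs:
                raise CapacityError("no distant same-strand gene pair")
            fresh = [(a, b) for a, b in far_pairs
                     if a.id not in used and b.id not in used]
            a, b = (fresh or far_pairs)[0]
            up, down = (a, b) if a.strand == 1 else (b, a)
            used.update((up.id, down.id))
            out.append(_build_fusion(
                genome, f"class2_distant_{label_no}", 2, "distant",
                _exon_window_5p(up, flank), _exon_window_3p(down, flank),
                up.name, down.name))

        elif cls == 3:
            def big_exon(gene):
                return max(gene.exons, key=lambda e: e.end - e.start)

            (g1,) = take(lambda g: big_exon(g).end - big_exon(g).start + 1 >= 530)
            exon = big_exon(g1)
            frag_late = _txn_slice(exon, 300, 220)
            frag_early = _txn_slice(exon, 10, 220)
            out.append(_build_fusion(
                genome, f"class3_inversion_{label_no}", 3, "intra_exonic_inversion",
                (exon.chrom, frag_late[0], frag_late[1], exon.strand),
                (exon.chrom, frag_early[0], frag_early[1], exon.strand),
                g1.name, g1.name))

            (g2,) = take(lambda g: big_exon(g).end - big_exon(g).start + 1 >= 560)
            exon = big_exon(g2)
            f1 = _txn_slice(exon, 0, 300)
            f2 = _txn_slice(exon, 240, 300)
            out.append(_build_fusion(
                genome, f"class3_tandem_{label_no}", 3, "tandem_duplication",
                (exon.chrom, f1[0], f1[1], exon.strand),
                (exon.chrom, f2[0], f2[1], exon.strand),
                g2.name, g2.name))

        elif cls == 4:
            by_chrom: dict[str, set[int]] = {}
            for g in genes:
                by_chrom.setdefault(g.chrom, set()).add(g.strand)
            chrom = next((c for c, s in sorted(by_chrom.items()) if s == {1, -1}), None)
            if chrom is None:
                raise CapacityError("class 4 needs both strands on one chromosome")
            (gp,) = take(lambda g: g.chrom == chrom and g.strand == 1)
            (gm,) = take(lambda g: g.chrom == chrom and g.strand == -1)
            out.append(_build_fusion(
                genome, f"class4_{label_no}", 4, "strand_switch",
                _exon_window_5p(gp, flank), _exon_window_3p(gm, flank),
                gp.name, gm.name))
    return out


@dataclass
class ReadSimConfig:
    """Stranded paired-end read simulation parameters."""

    read_length: int = 100
    fragment_mean: int = 250
    fragment_sd: int = 25
    depth: float = 30.0
    error_rate: float = 0.0
    protocol: str = "fr-firststrand"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.error_rate < 0.1):
            raise ValueError(f"error_rate must be in [0, 0.1), got {self.error_rate}")
        if self.protocol not in ("fr-firststrand", "fr-secondstrand"):
            raise ValueError(f"unknown protocol {self.protocol!r}")


@dataclass
class SimulatedPair:
    pair_id: str
    transcript: str
    frag_start: int          # 1-based within the transcript
    frag_end: int
    mate1: str
    mate2: str
    junction_cover: str      # mate1 | mate2 | both | insert | none | na


@dataclass
class ReadSimResult:
    pairs: list[SimulatedPair]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "pair_id": p.pair_id, "transcript": p.transcript,
            "frag_start": p.frag_start, "frag_end": p.frag_end,
            "junction_cover": p.junction_cover,
        } for p in self.pairs])

    def fastq_strings(self) -> tuple[str, str]:
        r1, r2 = [], []
        for p in self.pairs:
            q1 = PHRED33_Q30 * len(p.mate1)
            q2 = PHRED33_Q30 * len(p.mate2)
            r1.append(f"@{p.pair_id}\n{p.mate1}\n+\n{q1}\n")
            r2.append(f"@{p.pair_id}\n{p.mate2}\n+\n{q2}\n")
        return "".join(r1), "".join(r2)

    def write_fastq(self, path1, path2) -> None:
        s1, s2 = self.fastq_strings()
        Path(path1).write_text(s1)
        Path(path2).write_text(s2)

    def reads(self) -> list[tuple[str, str]]:
        """Flat (read_id, sequence) list, mate suffixes /1 and /2."""
        out = []
        for p in self.pairs:
            out.append((f"{p.pair_id}/1", p.mate1))
            out.append((f"{p.pair_id}/2", p.mate2))
        return out

    def read_pairs(self) -> list[tuple[str, str, str]]:
        return [(p.pair_id, p.mate1, p.mate2) for p in self.pairs]


_BASES = "ACGT"


def _mutate(seq: str, rng, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
    for i in hits:
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _cover(a: int, b: int, j: int) -> bool:
    return a <= j and j + 1 <= b


def simulate_reads(transcripts, config: ReadSimConfig,
                   junctions: dict[str, int] | None = None) -> ReadSimResult:
    """Simulate stranded paired-end reads from fusion (or plain) transcripts.

    ``transcripts`` maps name -> sequence (a dict or an iterable of
    ``(name, sequence)``).  ``junctions`` optionally maps a transcript name to
    the 1-based index of the last 5' base before its junction; the truth
    table then records, per pair, whether mate 1, mate 2, both, neither
    ("none"), or only the unsequenced insert ("insert") covers the junction
    -- the "insert" pairs are the expected spanning-PE support.
    """
    if isinstance(transcripts, dict):
        items = list(transcripts.items())
    else:
        items = list(transcripts)
    if not items:
        raise ValueError("transcript list is empty")
    junctions = junctions or {}
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    pairs: list[SimulatedPair] = []
    for name, seq in items:
        n = len(seq)
        if n < config.fragment_mean:
            raise ValueError(
                f"transcript {name} ({n} nt) shorter than fragment_mean "
                f"({config.fragment_mean})")
        n_pairs = max(1, round(config.depth * n / (2 * rl)))
        j = junctions.get(name)
        for i in range(n_pairs):
            frag_len = int(np.clip(round(rng.normal(config.fragment_mean,
                                                    config.fragment_sd)), rl, n))
            start = int(rng.integers(1, n - frag_len + 2))
            end = start + frag_len - 1
            frag = seq[start - 1:end]
            fwd = frag[:rl]                       # fragment 5' end, sense
            rev = revcomp(frag)[:rl]              # fragment 3' end, antisense
            if config.protocol == "fr-firststrand":
                mate1, mate2 = rev, fwd
                m1_iv = (end - rl + 1, end)
                m2_iv = (start, start + rl - 1)
            else:
                mate1, mate2 = fwd, rev
                m1_iv = (start, start + rl - 1)
                m2_iv = (end - rl + 1, end)
            mate1 = _mutate(mate1, rng, config.error_rate)
            mate2 = _mutate(mate2, rng, config.error_rate)
            if j is None:
                cover = "na"
            else:
                c1 = _cover(*m1_iv, j)
                c2 = _cover(*m2_iv, j)
                if c1 and c2:
                    cover = "both"
                elif c1:
                    cover = "mate1"
                elif c2:
                    cover = "mate2"
                elif _cover(start, end, j):
                    cover = "insert"
                else:
                    cover = "none"
            pairs.append(SimulatedPair(
                pair_id=f"{name}_p{i:05d}", transcript=name,
                frag_start=start, frag_end=end,
                mate1=mate1, mate2=mate2, junction_cover=cover))
    return ReadSimResult(pairs=pairs)


def truth_chimeras_table(chimeras: list[TruthChimera]) -> pd.DataFrame:
    """Truth TSV layout: 1-based inclusive coordinates, one row per event."""
    return pd.DataFrame([{
        "label": c.label, "class": c.cls, "flavor": c.flavor,
        "chr_left": c.left.chrom, "pos1": c.left.pos, "strand1": c.left.strand,
        "chr_right": c.right.chrom, "pos2": c.right.pos, "strand2": c.right.strand,
        "gene_left": c.gene_left or "NONE", "gene_right": c.gene_right or "NONE",
        "left_fragment": f"{c.left_fragment[0]}:{c.left_fragment[1]}-{c.left_fragment[2]}",
        "right_fragment": f"{c.right_fragment[0]}:{c.right_fragment[1]}-{c.right_fragment[2]}",
        "gap": "" if c.gap is None else c.gap,
        "junction_offset": c.junction_offset,
        "tag": c.tag,
    } for c in chimeras])
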