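"""End-to-end orchestration: index -> profiles -> breaks -> junctions ->
aggregate -> score -> annotate/filter -> subtype -> tag extraction.

The stages run serially; per-stage record counts are collected in
``PipelineResult.stats`` and logged, and record conservation holds at the
filter stage (records in = records kept + records rejected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotate_filter as af
from . import chimera_core as cc
from . import junction_caller as jc
from .genomeindex import build_index, count_read_kmers
from .simulate import SyntheticGenome
from .tagcount import TagRecord, extract_tag, write_tags_fasta
from ._seq import revcomp

logger = logging.getLogger("chimscan")


@dataclass
class PipelineConfig:
    """Run-wide settings.

    ``total_reads`` for normalization counts individual mates (2 per pair).
    ``protocol`` names the stranded library orientation used for spanning-PE
    orientation checks.
    """

    k: int = 22
    sample: str = "sample"
    thresholds: af.FilterThresholds = field(default_factory=af.FilterThresholds)
    error_support: int = 1
    anchor_min: int | None = None
    fragment_max: int = 1000
    protocol: str = "fr-firststrand"
    tag_len: int = 30
    seed: int = 0

    def caller_config(self) -> jc.CallerConfig:
        return jc.CallerConfig(error_support=self.error_support,
                               anchor_min=self.anchor_min,
                               fragment_max=self.fragment_max,
                               protocol=self.protocol)

    def to_yaml(self, path=None) -> str:
        data = asdict(self)
        text = yaml.safe_dump(data, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        thresholds = af.FilterThresholds(**data.pop("thresholds", {}))
        return cls(thresholds=thresholds, **data)


def load_fastq_pairs(path1, path2) -> list[tuple[str, str, str]]:
    """Read two mate FASTQ files into (pair_id, mate1, mate2) tuples."""
    from Bio import SeqIO
    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if not r1 or not r2:
        raise ValueError(f"empty FASTQ input ({path1!s}, {path2!s})")
    if len(r1) != len(r2):
        raise ValueError(f"mate files differ in length: {len(r1)} vs {len(r2)}")
    pairs = []
    for a, b in zip(r1, r2):
        ida = a.id.removesuffix("/1")
        idb = b.id.removesuffix("/2")
        if ida != idb:
            raise ValueError(f"mate id mismatch: {a.id} vs {b.id}")
        pairs.append((ida, str(a.seq).upper(), str(b.seq).upper()))
    return pairs


def reconstruct_junction_window(record: cc.ChimeraRecord, genome: SyntheticGenome,
                                flank: int = 30) -> tuple[str, int]:
    """Rebuild ``flank`` transcript-sense bases on each side of a junction
    from the genome; returns (sequence, junction offset)."""
    ls, rs = record.left, record.right
    if ls.strand == 1:
        left = genome.fetch(ls.chrom, max(1, ls.pos - flank + 1), ls.pos)
    else:
        end = min(len(genome.chromosomes[ls.chrom]), ls.pos + flank - 1)
        left = revcomp(genome.fetch(ls.chrom, ls.pos, end))
    if rs.strand == 1:
        end = min(len(genome.chromosomes[rs.chrom]), rs.pos + flank - 1)
        right = genome.fetch(rs.chrom, rs.pos, end)
    else:
        right = revcomp(genome.fetch(rs.chrom, max(1, rs.pos - flank + 1), rs.pos))
    return left + right, len(left)


@dataclass
class PipelineResult:
    records: list[cc.ChimeraRecord]
    kept: list[cc.ChimeraRecord]
    rejections: list[tuple[cc.ChimeraRecord, str]]
    annotations: dict[str, tuple[af.EndpointAnnotation, af.EndpointAnnotation]]
    subtypes: dict[str, dict[str, bool]]
    tags: list[TagRecord]
    stats: dict

    def to_frame(self) -> pd.DataFrame:
        """Extended tabular report: the 12 standard columns plus support
        counts, fragments, subtype flags and rejection reason."""
        rejected_rule = {rec.id: rule for rec, rule in self.rejections}
        rows = []
        for record in self.records:
            row = cc.record_row(record)
            ann_l, ann_r = self.annotations[record.id]
            sub = self.subtypes.get(record.id, {})
            row.update({
                "gene_left": ann_l.label, "gene_right": ann_r.label,
                "spanning_junction_raw": record.spanning_junction_raw,
                "spanning_pe_raw": record.spanning_pe_raw,
                "left_fragment": _fmt_frag(record.left_fragment),
                "right_fragment": _fmt_frag(record.right_fragment),
                "read_through": sub.get("read_through", False),
                "tandem_repeat": sub.get("tandem_repeat", False),
                "status": "kept" if record.id not in rejected_rule else "rejected",
                "rejection_reason": rejected_rule.get(record.id, ""),
            })
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        frame[frame.status == "kept"].to_csv(outdir / "chimeras.tsv",
                                             sep="\t", index=False)
        frame[frame.status == "rejected"].to_csv(outdir / "chimeras.rejected.tsv",
                                                 sep="\t", index=False)
        if self.tags:
            write_tags_fasta(self.tags, outdir / "junction_tags.fa")
        with open(outdir / "pipeline_stats.yaml", "w") as fh:
            yaml.safe_dump(self.stats, fh, sort_keys=False)


def _fmt_frag(frag):
    return "" if frag is None else f"{frag[0]}:{frag[1]}-{frag[2]}"


def run_pipeline(config: PipelineConfig, genome: SyntheticGenome,
                 models: af.GeneModels, pairs, outdir=None) -> PipelineResult:
    """Run every stage on paired reads.

    ``pairs`` is a list of ``(pair_id, mate1, mate2)`` (see
    :func:`load_fastq_pairs`) or a pair of FASTQ paths.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], (str, Path)):
        pairs = load_fastq_pairs(*pairs)
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no read pairs supplied")

    stats: dict = {"read_pairs": len(pairs), "total_reads": 2 * len(pairs)}
    cfg = config.caller_config()

    index = build_index(genome, config.k)
    stats["indexed_kmers"] = len(index)
    logger.info("indexed %d canonical %d-mers", len(index), config.k)

    reads = [(f"{pid}/1", m1) for pid, m1, _ in pairs]
    reads += [(f"{pid}/2", m2) for pid, _, m2 in pairs]
    kmer_counts = count_read_kmers((seq for _, seq in reads), config.k)

    # under the dUTP protocol mate 1 is antisense to the transcript; its
    # junction calls are flipped into sense orientation before merging
    anti_suffix = "/1" if config.protocol == "fr-firststrand" else "/2"
    antisense_ids = {rid for rid, _ in reads if rid.endswith(anti_suffix)}
    candidates, call_stats = jc.call_junctions(reads, index, genome,
                                               kmer_counts=kmer_counts, cfg=cfg,
                                               antisense_ids=antisense_ids)
    stats["caller"] = call_stats
    stats["junction_candidates"] = len(candidates)
    logger.info("caller: %s", call_stats)

    pe_support = jc.find_spanning_pairs(candidates, pairs, index, cfg)
    records = cc.aggregate(candidates, pe_support, sample=config.sample,
                           total_reads=2 * len(pairs))
    for record in records:
        cc.chim_value(record, genome, index, kmer_counts)
    stats["records"] = len(records)

    annotations = {}
    for record in records:
        ann_l = af.annotate_endpoint(record.left, models, role="left")
        ann_r = af.annotate_endpoint(record.right, models, role="right")
        record.gene_left = ann_l.gene
        record.gene_right = ann_r.gene
        annotations[record.id] = (ann_l, ann_r)

    kept, rejections = af.apply_filters(records, annotations, config.thresholds)
    stats["kept"] = len(kept)
    stats["rejected"] = {rule: sum(1 for _, r in rejections if r == rule)
                         for rule in af.FILTER_RULES}
    assert len(kept) + len(rejections) == len(records)
    logger.info("filters: %d kept, %d rejected", len(kept), len(rejections))

    subtypes = {}
    for record in records:
        subtypes[record.id] = {
            "read_through": af.call_readthrough(record, annotations[record.id],
                                                config.thresholds),
            "tandem_repeat": af.call_tandem_repeat(record, models),
        }

    tags = []
    half = config.tag_len // 2
    for record in kept:
        window, offset = reconstruct_junction_window(record, genome, flank=half)
        try:
            tags.append(extract_tag(window, offset, tag_len=config.tag_len,
                                    tag_id=record.id.replace(":", "_")))
        except ValueError:
            logger.warning("no tag for %s: junction too close to a contig end",
                           record.id)
    stats["tags"] = len(tags)

    result = PipelineResult(records=records, kept=kept, rejections=rejections,
                            annotations=annotations, subtypes=subtypes,
                            tags=tags, stats=stats)
    if outdir is not None:
        result.write(outdir)
    return result
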