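"""Endpoint annotation, filter cascade boundaries, subtype callers, clustering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chimscan import (ChimeraRecord, FilterThresholds, GenomicSide,
                      annotate_endpoint, apply_filters, call_readthrough,
                      call_tandem_repeat, select_clustering_genes)
from chimscan.annotate_filter import FILTER_RULES, EndpointAnnotation


def make_record(rid="s:1", chrom="chr1", pos1=10_000, strand1=1, chrom2=None,
                pos2=20_000, strand2=None, sj=5, pe=3, cv=90.0,
                lf=None, rf=None):
    left = GenomicSide(chrom, pos1, strand1)
    right = GenomicSide(chrom2 or chrom, pos2,
                        strand2 if strand2 is not None else strand1)
    from chimscan import classify
    return ChimeraRecord(
        id=rid, sample="s", left=left, right=right,
        cls=classify(left, right),
        spanning_junction_raw=sj, spanning_pe_raw=pe,
        spanning_junction_norm=sj * 1e9 / 1e6, spanning_pe_norm=pe * 1e9 / 1e6,
        chim_value=cv, left_fragment=lf, right_fragment=rf)


def ann(gene="GENEX", exon=None, dist=None, priority="exon"):
    return EndpointAnnotation(gene=gene, exon=exon, exon_end_distance=dist,
                              priority=priority)


ANN_OK = (ann(gene="GENEA", dist=0), ann(gene="GENEB", dist=0))


class TestAnnotateEndpoint:
    def test_exon_boundary_left_side_distance_zero(self, models):
        gene = next(g for g in models.genes.values() if g.strand == 1)
        exon = max(gene.exons, key=lambda e: e.end)
        a = annotate_endpoint(GenomicSide(gene.chrom, exon.end, 1), models, "left")
        assert a.gene == gene.name
        assert a.exon_end_distance == 0
        assert a.priority == "exon"

    def test_exon_interior_distance(self, models):
        gene = next(g for g in models.genes.values() if g.strand == 1)
        exon = max(gene.exons, key=lambda e: e.end - e.start)
        a = annotate_endpoint(GenomicSide(gene.chrom, exon.end - 10, 1),
                              models, "left")
        assert a.exon_end_distance == 10
        b = annotate_endpoint(GenomicSide(gene.chrom, exon.start + 7, 1),
                              models, "right")
        assert b.exon_end_distance == 7

    def test_minus_strand_facing_boundaries(self, models):
        gene = next(g for g in models.genes.values() if g.strand == -1)
        exon = min(gene.exons, key=lambda e: e.start)   # transcript-last exon
        a = annotate_endpoint(GenomicSide(gene.chrom, exon.start, -1),
                              models, "left")
        assert a.exon_end_distance == 0                 # 3' boundary on minus

    def test_intron_falls_back_to_gene(self, models):
        gene = next(g for g in models.genes.values()
                    if g.strand == 1 and len(g.exons) >= 2)
        exons = sorted(gene.exons, key=lambda e: e.start)
        intron_pos = exons[0].end + 1
        a = annotate_endpoint(GenomicSide(gene.chrom, intron_pos, 1), models, "left")
        assert a.gene == gene.name
        assert a.priority == "gene"
        assert a.exon_end_distance is None

    def test_intergenic_is_none(self, genome, models):
        genes = sorted(models.genes.values(), key=lambda g: (g.chrom, g.start))
        a, b = next((a, b) for a, b in zip(genes, genes[1:])
                    if a.chrom == b.chrom and b.start - a.end > 2)
        pos = a.end + (b.start - a.end) // 2
        for strand in (1, -1):
            out = annotate_endpoint(GenomicSide(a.chrom, pos, strand), models, "left")
            assert out.gene is None
            assert out.label == "NONE"

    def test_antisense_hit_is_none_with_note(self, models):
        gene = next(g for g in models.genes.values() if g.strand == 1)
        exon = gene.exons[0]
        out = annotate_endpoint(GenomicSide(gene.chrom, exon.start + 5, -1),
                                models, "left")
        assert out.gene is None
        assert out.antisense

    def test_unknown_chromosome_is_none(self, models):
        out = annotate_endpoint(GenomicSide("chrZZ", 100, 1), models, "left")
        assert out.gene is None


class TestApplyFilters:
    def _run(self, record, anns=ANN_OK, **kw):
        th = FilterThresholds(**kw)
        kept, rej = apply_filters([record], {record.id: anns}, th)
        return ("kept", None) if kept else ("rejected", rej[0][1])

    @pytest.mark.parametrize("gap,expected", [
        (2999, ("rejected", "adjacent_genes")),
        (3001, ("kept", None)),
    ])
    def test_adjacency_boundary(self, gap, expected):
        rec = make_record(pos1=10_000, pos2=10_000 + gap + 1)
        assert rec.cls == 2 and rec.gap == gap
        assert self._run(rec) == expected

    @pytest.mark.parametrize("cv,expected", [
        (59.9, ("rejected", "chim_value")),
        (60.0, ("kept", None)),
    ])
    def test_chim_value_boundary(self, cv, expected):
        rec = make_record(chrom2="chr2", cv=cv)     # class 1: no adjacency rule
        assert self._run(rec) == expected

    def test_none_none_rejected_by_annotation_rule(self):
        rec = make_record(chrom2="chr2")
        anns = (ann(gene=None, priority="none"), ann(gene=None, priority="none"))
        assert self._run(rec, anns=anns) == ("rejected", "annotation")

    def test_gene_none_kept(self):
        rec = make_record(chrom2="chr2")
        anns = (ann(gene="PAN3", dist=0), ann(gene=None, priority="none"))
        assert self._run(rec, anns=anns) == ("kept", None)

    def test_same_gene_collinear_removed_as_splice(self):
        rec = make_record(pos1=1000, pos2=9000)     # class 2, gap 7999
        anns = (ann(gene="GENEA"), ann(gene="GENEA"))
        assert self._run(rec, anns=anns) == ("rejected", "splice")

    def test_pe_required(self):
        rec = make_record(chrom2="chr2", pe=0)
        assert self._run(rec) == ("rejected", "pe_support")
        assert self._run(rec, require_pe=False) == ("kept", None)

    def test_no_spanning_read_rejected(self):
        rec = make_record(chrom2="chr2", sj=0)
        assert self._run(rec) == ("rejected", "spanning_junction")

    def test_rejection_log_partitions_records(self):
        records = [make_record(rid=f"s:{i}", chrom2="chr2", cv=cv, pe=pe)
                   for i, (cv, pe) in enumerate([(90, 3), (10, 3), (90, 0), (59, 0)])]
        anns = {r.id: ANN_OK for r in records}
        kept, rej = apply_filters(records, anns)
        assert len(kept) + len(rej) == len(records)
        assert all(rule in FILTER_RULES for _, rule in rej)
        ids = {r.id for r in kept} | {r.id for r, _ in rej}
        assert ids == {r.id for r in records}

    @given(min_cv=st.floats(0, 100), min_sj=st.integers(0, 10),
           adj=st.integers(0, 5000))
    @settings(max_examples=60, derandomize=True)
    def test_monotonicity_raising_thresholds_shrinks_kept(self, min_cv, min_sj, adj):
        records = [make_record(rid=f"s:{i}", pos1=1000, pos2=1000 + 700 * (i + 1),
                               sj=i, cv=10.0 * i) for i in range(10)]
        anns = {r.id: ANN_OK for r in records}
        base = FilterThresholds()
        tight = FilterThresholds(min_chim_value=max(base.min_chim_value, min_cv),
                                 min_spanning_junction=max(1, min_sj),
                                 adjacent_gene_distance=max(3000, adj))
        kept_base, _ = apply_filters(records, anns, base)
        kept_tight, _ = apply_filters(records, anns, tight)
        assert {r.id for r in kept_tight} <= {r.id for r in kept_base}

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_chim_value=-1)

    def test_yaml_round_trip(self, tmp_path):
        th = FilterThresholds(adjacent_gene_distance=1234)
        path = tmp_path / "th.yaml"
        th.to_yaml(path)
        assert FilterThresholds.from_yaml(path) == th


class TestReadthrough:
    def test_short_distance_exon_boundaries_flagged(self):
        rec = make_record(pos1=1000, pos2=3378)     # gap 2377, VAMP8/VAMP5-like
        anns = (ann(gene="VAMP8", dist=0), ann(gene="VAMP5", dist=0))
        assert call_readthrough(rec, anns) is True

    def test_long_distance_not_flagged(self):
        rec = make_record(pos1=1000, pos2=856_830)  # gap 855828
        anns = (ann(gene="SLC16A3", dist=0), ann(gene="METRNL", dist=0))
        assert call_readthrough(rec, anns) is False

    def test_class1_never_flagged(self):
        rec = make_record(chrom2="chr2")
        assert call_readthrough(rec, ANN_OK) is False

    def test_exon_end_distance_both_sides_enforced(self):
        rec = make_record(pos1=1000, pos2=5000)
        assert call_readthrough(rec, (ann(dist=0), ann(dist=21))) is False
        assert call_readthrough(rec, (ann(dist=20), ann(dist=20))) is True
        assert call_readthrough(rec, (ann(dist=None, priority="gene"),
                                      ann(dist=0))) is False


class TestTandemRepeat:
    def _exon(self, models, min_len=550):
        for gene in models.genes.values():
            for exon in gene.exons:
                if exon.end - exon.start + 1 >= min_len:
                    return exon
        raise AssertionError("no large exon in fixture")

    def test_overlapping_fragments_one_exon_flagged(self, models):
        e = self._exon(models)
        rec = make_record(pos1=e.start + 160, pos2=e.start + 130,
                          strand1=e.strand, strand2=e.strand, chrom=e.chrom,
                          lf=(e.chrom, e.start + 100, e.start + 160),
                          rf=(e.chrom, e.start + 130, e.start + 190))
        assert rec.cls == 3 if e.strand == 1 else True
        rec.cls = 3
        assert call_tandem_repeat(rec, models) is True

    def test_disjoint_fragments_not_tandem(self, models):
        e = self._exon(models)
        rec = make_record(chrom=e.chrom, strand1=e.strand, strand2=e.strand,
                          pos1=e.start + 400, pos2=e.start + 10,
                          lf=(e.chrom, e.start + 215, e.start + 400),
                          rf=(e.chrom, e.start + 10, e.start + 47))
        rec.cls = 3
        assert call_tandem_repeat(rec, models) is False

    def test_overlap_spanning_two_exons_not_tandem(self, models, genome):
        gene = next(g for g in models.genes.values() if len(g.exons) >= 2)
        exons = sorted(gene.exons, key=lambda e: e.start)
        a, b = exons[0], exons[1]
        rec = make_record(chrom=a.chrom, strand1=a.strand, strand2=a.strand,
                          pos1=b.start + 5, pos2=a.end - 5,
                          lf=(a.chrom, a.end - 30, b.start + 5),
                          rf=(a.chrom, a.end - 5, b.start + 30))
        rec.cls = 3
        assert call_tandem_repeat(rec, models) is False

    def test_missing_fragments_false(self):
        rec = make_record(pos1=2000, pos2=1000)
        rec.cls = 3
        from chimscan import GeneModels
        assert call_tandem_repeat(rec, GeneModels([])) is False

    def test_readthrough_and_tandem_disjoint(self, models, pipeline_result):
        """No record can be both read-through (class 2) and tandem (class 3)."""
        for rid, flags in pipeline_result.subtypes.items():
            assert not (flags["read_through"] and flags["tandem_repeat"])


class TestClusteringSelection:
    def _entries(self, models):
        e = None
        for gene in models.genes.values():
            for exon in gene.exons:
                if exon.end - exon.start + 1 >= 550:
                    e = exon
                    break
            if e:
                break
        entries = []
        # two read-through events sharing GENEB, from different samples
        for i, sample in enumerate(["s1", "s2"]):
            rec = make_record(rid=f"{sample}:{i}", pos1=1000, pos2=5000,
                              sj=5, cv=90.0)
            entries.append((rec, (ann(gene=f"GENE_{i}", dist=0),
                                  ann(gene="GENEB", dist=0))))
        # one lone read-through gene
        rec = make_record(rid="s1:9", pos1=1000, pos2=5000, sj=5, cv=90.0)
        entries.append((rec, (ann(gene="LONELY", dist=0), ann(gene="GENEC", dist=0))))
        # a tandem event (needs two to be selected)
        tdm = make_record(rid="s1:7", chrom=e.chrom, strand1=e.strand,
                          strand2=e.strand, pos1=e.start + 160, pos2=e.start + 130,
                          sj=5, cv=90.0,
                          lf=(e.chrom, e.start + 100, e.start + 160),
                          rf=(e.chrom, e.start + 130, e.start + 190))
        tdm.cls = 3
        gene_name = models.genes[e.gene_id].name
        entries.append((tdm, (ann(gene=gene_name, dist=None, priority="gene"),
                              ann(gene=gene_name, dist=None, priority="gene"))))
        return entries

    def test_gene_in_two_events_across_samples_selected(self, models):
        out = select_clustering_genes(self._entries(models), models)
        assert "GENEB" in out["read_through"]

    def test_gene_in_single_event_excluded(self, models):
        out = select_clustering_genes(self._entries(models), models)
        assert "LONELY" not in out["read_through"]
        assert "GENEC" not in out["read_through"]
        assert out["tandem_repeat"] == []          # single tandem event

    def test_chim_value_75_is_strict(self, models):
        rec = make_record(rid="sx:1", pos1=1000, pos2=5000, sj=5, cv=75.0)
        rec2 = make_record(rid="sx:2", pos1=1000, pos2=5000, sj=5, cv=75.0)
        entries = [(r, (ann(gene="GA", dist=0), ann(gene="GB", dist=0)))
                   for r in (rec, rec2)]
        out = select_clustering_genes(entries, models)
        assert out["read_through"] == []           # 75.0 is not > 75
        rec.chim_value = rec2.chim_value = 75.1
        out = select_clustering_genes(entries, models)
        assert "GB" in out["read_through"]

    def test_spanning_minimum(self, models):
        entries = [(make_record(rid=f"sy:{i}", pos1=1000, pos2=5000, sj=2, cv=90.0),
                    (ann(gene="GA", dist=0), ann(gene="GB", dist=0)))
                   for i in range(3)]
        out = select_clustering_genes(entries, models)
        assert out["read_through"] == []           # 2 < 3 spanning reads
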