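"""Call chimeric junctions from reads and classify them, end to end.

Runs the full pipeline on a simulated bundle and prints, per discovered
chimera: the class, exact breakpoints, spanning-read and spanning-pair
support, the 0-100 confidence score, and whether the filter cascade kept it.
"""

from chimscan import (PipelineConfig, ReadSimConfig, make_annotation,
                      make_genome, plant_chimeras, run_pipeline,
                      simulate_reads)

genome = make_genome(3, 50_000, seed=1)
models = make_annotation(genome, 24, seed=2)
chimeras = plant_chimeras(genome, models, [1, 2, 3, 4], seed=3)
sim = simulate_reads({c.label: c.fusion_transcript for c in chimeras},
                     ReadSimConfig(seed=4),
                     junctions={c.label: c.junction_offset for c in chimeras})

result = run_pipeline(PipelineConfig(k=22, sample="demo"), genome, models,
                      sim.read_pairs())

rejected = {rec.id: rule for rec, rule in result.rejections}
print(f"{'id':8} {'class':5} {'junction':32} {'sj':>3} {'pe':>3} "
      f"{'ChimValue':>9}  status")
for r in result.records:
    junction = (f"{r.left.chrom}:{r.left.pos}({r.left.strand:+d}) -> "
                f"{r.right.chrom}:{r.right.pos}({r.right.strand:+d})")
    status = rejected.get(r.id, "kept")
    print(f"{r.id:8} {r.cls:5} {junction:32} {r.spanning_junction_raw:3} "
          f"{r.spanning_pe_raw:3} {r.chim_value:9.1f}  {status}")

truth = {(c.left, c.right) for c in chimeras}
found = {(r.left, r.right) for r in result.records}
print(f"\nplanted junctions recovered exactly: {len(truth & found)}/{len(truth)}")
# 'sj' counts reads whose sequence crosses the junction, 'pe' read pairs
# bridging it in the unsequenced insert. The class-2 adjacent event is
# rejected by the 3 kb adjacency rule by design; every planted breakpoint is
# still recovered base-exactly before filtering.
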