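"""Generate a synthetic study bundle: genome, genes, planted chimeras, reads.

Builds a 3 x 50 kb genome with 24 annotated genes, plants fusion transcripts
of all four chimera classes (class 2 in adjacent and distant flavors, class 3
as intra-exonic inversion and tandem duplication), and simulates error-free
stranded 100-bp paired-end reads at 30x. Prints the planted truth table.
"""

from chimscan import (ReadSimConfig, make_annotation, make_genome,
                      plant_chimeras, simulate_reads)
from chimscan.simulate import truth_chimeras_table

genome = make_genome(n_chrom=3, length=50_000, seed=1)
models = make_annotation(genome, n_genes=24, seed=2)
chimeras = plant_chimeras(genome, models, [1, 2, 3, 4], seed=3)

sim = simulate_reads({c.label: c.fusion_transcript for c in chimeras},
                     ReadSimConfig(depth=30, error_rate=0.0, seed=4),
                     junctions={c.label: c.junction_offset for c in chimeras})

print(truth_chimeras_table(chimeras)[
    ["label", "class", "flavor", "chr_left", "pos1", "strand1",
     "chr_right", "pos2", "strand2", "gap"]].to_string(index=False))
print(f"\n{len(sim.pairs)} read pairs simulated "
      f"({2 * len(sim.pairs)} reads, 100 bp, stranded dUTP protocol)")
# Each row is one planted junction: pos1 is the genomic position of the last
# transcribed base of the 5' fragment, pos2 the first base of the 3' fragment;
# 'gap' is the distance between the two endpoints on a shared chromosome.
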