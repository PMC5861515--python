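"""Screen FASTQ collections for known junctions with 30-nt tags.

Junction tags (15 bases each side of the breakpoint) are matched exactly,
forward and reverse complement, against every read window; counts are
normalized per 5 billion k-mers so files of different depth are comparable.
"""

import tempfile
from pathlib import Path

from chimscan import (PipelineConfig, ReadSimConfig, count_tags,
                      make_annotation, make_genome, plant_chimeras,
                      run_pipeline, simulate_reads)
from chimscan.tagcount import write_tags_fasta

genome = make_genome(3, 50_000, seed=1)
models = make_annotation(genome, 24, seed=2)
chimeras = plant_chimeras(genome, models, [1, 4], seed=3)
sim = simulate_reads({c.label: c.fusion_transcript for c in chimeras},
                     ReadSimConfig(seed=4),
                     junctions={c.label: c.junction_offset for c in chimeras})
result = run_pipeline(PipelineConfig(sample="demo"), genome, models,
                      sim.read_pairs())

workdir = Path(tempfile.mkdtemp())
sim.write_fastq(workdir / "reads_1.fastq", workdir / "reads_2.fastq")
write_tags_fasta(result.tags, workdir / "tags.fa")

table = count_tags(workdir / "tags.fa",
                   [workdir / "reads_1.fastq", workdir / "reads_2.fastq"])
print(table.frame.to_string(index=False))
# raw_count: exact occurrences of the tag or its reverse complement;
# total_kmers: number of 30-nt windows scanned in the file;
# normalized_count = raw * 5e9 / total_kmers. A tag that recurs in a sample
# it was not discovered in is evidence for recurrence of that chimera.
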