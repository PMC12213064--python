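"""Genome statistics: GC content, circular GC skew, codon usage and
feature tallies from an annotation."""

import tempfile
from pathlib import Path

from tinygenome import SimConfig, generate_marker_families, generate_target_genome
from tinygenome.stats import codon_usage, feature_tally, gc3, gc_content, gc_skew

config = SimConfig(seed=9, n_families=10, n_ref_taxa=30, family_length=200,
                   gc_target=0.33)
families, truth_cols = generate_marker_families(config)
genome, truth = generate_target_genome(families, config, truth_cols)

print(f"genome: {len(genome):,} nt")
print(f"GC content: {100 * gc_content(genome):.2f}%")

profile = gc_skew(genome, window=2000, step=500)
values = [v for v in profile.values if v is not None]
print(f"GC skew over {len(profile.values)} circular windows: "
      f"min {min(values):+.3f}, max {max(values):+.3f}")

genes = [truth.extract_cds(genome, g) for g in truth.genes]
usage = codon_usage(genes)
print(f"codon usage: {int(usage['count'].sum()):,} codons counted; "
      f"GC3 = {gc3(genes):.3f} (third positions track the genome-wide bias)")

with tempfile.TemporaryDirectory() as tmp:
    gff = Path(tmp) / "truth.gff3"
    truth.to_gff3(gff)
    tally = feature_tally(gff)
print(f"annotation tally: {tally['counts']}")
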