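"""Detect a UGA=Trp genetic-code change from conserved-position evidence.

Simulates reference marker families and a low-GC genome that encodes
tryptophan with TGA 70% of the time, then runs the full inference:
conserved-column scan -> six-frame translated search -> 64x20 codon
observation matrix -> per-codon code call -> translation-table choice.
"""

from tinygenome import SimConfig, generate_marker_families, generate_target_genome
from tinygenome.pipeline import run_code_inference

config = SimConfig(seed=42, n_families=12, n_ref_taxa=50, family_length=200,
                   genetic_code="uga_trp", gc_target=0.32)
families, conserved_truth = generate_marker_families(config)
genome, truth = generate_target_genome(families, config, conserved_truth)

print(f"simulated genome: {len(genome):,} nt, {len(truth.genes)} genes, "
      f"{len(truth.tga_sites)} TGA-Trp codons")

matrix, call, hits = run_code_inference(genome, families)

print(f"conserved sites observed: {matrix.total_sites:,}")
tga = matrix.counts.loc["TGA"]
print(f"TGA row: {int(tga.sum())} observations, "
      f"p(W|TGA) = {call.probabilities.loc['TGA', 'W']:.3f}")
print(f"selected translation table: {call.selected_table}")
for r in call.reassignments:
    print(f"reassignment: {r.codon} {r.standard_meaning} -> {r.inferred_meaning}")

# The selected table 4 with the single reassignment TGA: stop -> W means the
# genome reads UGA as tryptophan, the Mycoplasma-like code of many low-GC
# reduced genomes; a standard-code genome would select table 11 instead.
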