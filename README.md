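# tinygenome

Analysis toolkit for **highly reduced endosymbiont genomes**: inference of a
genome's genetic code from conserved-position evidence (detecting stop-codon
reassignments such as UGA=Trp), rule-based reconstruction of the minimal
ancestral proteome from orthogroup presence/absence, and the descriptive
genome statistics that accompany such studies — together with a
synthetic-data generator that produces every input with known ground truth.

It is written for microbial comparative genomicists working on
endosymbionts and other reduced genomes, where two questions recur:

1. **Which genetic code does this genome use?**  Severely reduced, low-GC
   genomes (e.g. *Mycoplasma* and many arthropod endosymbionts) often
   reassign the stop codon UGA to tryptophan.  Annotating such a genome
   with the wrong translation table fragments its ORFs.
2. **How much of the ancestral gene repertoire survives, and when was the
   rest lost?**  Given orthogroup presence/absence across the target
   lineages, their sister clade and a basal outgroup pair, one can bound
   the ancestral proteome and partition losses into shared (pre-divergence)
   and lineage-specific events.

## The method

**Genetic-code inference.**  Let a set of marker-protein families be aligned
across many reference taxa.  An alignment column is a *highly conserved
amino acid* (HCAA) position when ≥ 90% of the sequences share one residue
*a*.  The target genome is searched with each family's protein by local
alignment against all six translation frames (Smith–Waterman, BLOSUM62,
affine gaps; stop codons render `*` and score a flat −4 so alignments read
through reassigned stops).  Each HCAA column aligned to a subject residue
contributes one observation pairing the genome codon *c* at that residue
with the conserved amino acid *a*.  Observations accumulate into a 64 × 20
count matrix *N(c, a)*; row-normalising gives *p(a | c)*.  Codon *c* is
assigned to amino acid *a* when

> N(c,·) ≥ min_count  and  p(a | c) ≥ dominance  (defaults 10 and 0.8),

and an assigned codon whose meaning differs from the standard bacterial
code (NCBI table 11) is a *reassignment*.  No reassignments → annotate with
table 11; exactly {UGA: stop → Trp} → table 4; anything else → "custom".

**Ancestral proteome.**  An orthogroup belongs to the minimal ancestral
proteome iff it is present in ≥ 1 basal-group taxon AND ≥ 1 sister-group
taxon (target presence is ignored).  Retention of a target *t* is
|ancestral ∩ present(t)|, reported as a percentage truncated (floored) at
one decimal.  Losses split exactly into shared (absent from all targets)
and lineage-specific (absent from *t*, present in another target) classes.

**Genome statistics.**  GC content, sliding-window GC skew (G−C)/(G+C) on a
circular chromosome, codon usage with within-family frequencies, GFF3
feature tallies, and tRNA anticodon-stem length (consecutive Watson–Crick
or G·U pairs walking outward from the 7-nt anticodon loop) — a 4-bp stem
on tRNA-Trp(CCA) being the structural correlate of UGA readthrough.

## Worked example

`examples/01_infer_genetic_code.py` simulates twelve marker families and a
low-GC genome that encodes tryptophan with TGA 70% of the time, then runs
the full inference:

```
simulated genome: 8,499 nt, 12 genes, 75 TGA-Trp codons
conserved sites observed: 718
TGA row: 16 observations, p(W|TGA) = 1.000
selected translation table: 4
reassignment: TGA stop -> W
```

Of 718 codon observations at conserved positions, 16 fall on TGA codons,
and every one of them sits at a conserved-tryptophan column — decisive
evidence that this genome reads UGA as Trp, so it should be annotated with
translation table 4.  `examples/02_ancestral_proteome.py` shows the
gene-content side; its first block reproduces a published retention table
exactly:

```
ancestral proteome: 2151 orthogroups
  T1: retained 477 (22.1%)
  T2: retained 402 (18.6%)
```

The other examples cover genome statistics and the tRNA stem measurement.
The same flow is available as a pipeline with a manifest
(`tinygenome run-all --config config.yaml`) or stage by stage
(`tinygenome simulate | hcaa | search | infer-code | gene-content | stats`).

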