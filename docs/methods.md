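# Methods

This note documents the models and procedures implemented in
`tinygenome`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical and design choices
made where the design was genuinely open.

## Genetic-code inference from conserved positions

### Rationale

A codon's meaning can be read off a genome without any expression data by
exploiting deep conservation: if an alignment column of a marker-protein
family carries the same amino acid in ≥ 90% of diverse reference taxa, a
diverged genome almost certainly uses that amino acid at the homologous
position, whatever codon it writes there.  Pooling thousands of such
(codon, conserved residue) pairs yields a per-codon evidence profile; a
stop codon whose profile is dominated by tryptophan has been reassigned
(UGA=Trp, the *Mycoplasma*-like code of many low-GC reduced genomes).

### HCAA scan

A column qualifies as a highly conserved amino acid (HCAA) position when
`count(modal residue) / n_sequences ≥ threshold` (default 0.90,
inclusive).  The denominator counts **all** sequences, gaps included —
the conservative reading of "fraction of sequences sharing a residue";
gap-heavy columns therefore rarely qualify.  `X` (any non-standard or
ambiguous letter) and `-` never count toward the modal residue.  For
thresholds ≤ 0.5 two residues can tie at the threshold; a tied column is
rejected, since an ambiguous column has no consensus.  The comparison
uses a 1e−12 absolute tolerance so that exact boundary cases such as 9/10
against 0.90 are included regardless of float representation.

### Translated search

Marker proteins (the family consensus, by default) are located by
Smith–Waterman local alignment against all six translation frames of the
genome — an in-process, deterministic equivalent of a tBLASTn search,
with `Bio.Align.PairwiseAligner` as the DP engine.  Scoring: BLOSUM62,
affine gaps (open 11, extend 1), and stop codons rendered `*` scoring a
flat −4 against every residue rather than terminating the alignment.
The stop handling is essential: in a UGA=Trp genome the conserved ORFs
are "interrupted" by what table 11 calls stops, and the alignment must
read through them to expose the evidence.  Codons containing `N`
translate to `X`; trailing partial codons are dropped.

Hits below a raw-score threshold (default 60, well above the empirical
null for the genome sizes involved; CLI-overridable) are discarded.
Because the markers are single-copy, hits for the same query sharing more
than 50% of a genome span collapse to the best-scoring one (ties:
leftmost start).  All internal coordinates are 0-based half-open on the
forward strand; GFF3 output is 1-based inclusive.

### Codon observation matrix and code call

Each HCAA column whose query residue aligns to a subject residue (never
a gap; `*` positions do emit) contributes the coding-strand codon at
that residue paired with the column's consensus amino acid.  Duplicate
observations of the same (family, column, genome position) — possible
when overlapping hits are retained — count once.  Codons containing `N`
are dropped with a logged count.  The result is the 64 × 20 count matrix
whose grand total equals the number of observation sites.

Each codon is called independently (codons of one amino acid are never
pooled): assign codon *c* to amino acid *a* iff `total(c) ≥ min_count`
(default 10) and `p(a|c) ≥ dominance` (default 0.8); otherwise
*unassigned*.  The thresholds formalise a judgement that is often made
by eye from probability logos; they are explicit and overridable.
Unassigned stop codons are presumed to retain termination.  Reassignments
are assigned codons whose meaning differs from table 11; table selection
is rule-based: none → 11, exactly {TGA: stop → W} → 4, else "custom".
The default `dominance = 0.8` tolerates the main noise source — target
residues that diverged away from (or into) the conserved amino acid —
at divergence levels around 10–20%, while `min_count = 10` keeps
single-digit codon rows unassigned rather than over-called.

The probability table exported for logo rendering is the row-normalised
matrix itself ("units: probability, no composition adjustment"); rows
with zero observations are all-zero.  The optional stacked-letter plot is
drawn with plain matplotlib.

## Ancestral proteome and loss accounting

The minimal ancestral proteome is defined operationally, not by
parsimony or likelihood reconstruction: an orthogroup is ancestral iff
present in ≥ 1 basal-group taxon AND ≥ 1 sister-group taxon.  Target
presence is deliberately ignored so that target retention is a
measurement, not a tautology; the set is "minimal" because an orthogroup
lost from the basal pair or the whole sister clade is invisible to the
criteria.  Presence is binary (copy number ignored), matching binarized
orthogroup count tables.

Retention percentages are **truncated** (floored) at one decimal, e.g.
477/2151 → 22.1% and 402/2151 → 18.6%; this is the only rounding
convention consistent with both of those printed values, and is applied
with integer arithmetic (`1000·count // total / 10`) to avoid float
boundary errors.  An empty ancestral set has no defined percentage
(count 0, percentage null).

Loss partition per target *t*: `retained(t) = ancestral ∩ present(t)`;
`shared_loss` = ancestral orthogroups absent from **all** targets (under
parsimony, losses on the common-ancestor branch); `specific_loss(t)` =
absent from *t* but present in another target.  The three classes
partition the ancestral set exactly, and the implementation asserts the
set algebra rather than approximating it.  Functional-category summaries
cross-tabulate these classes against a (possibly partial) orthogroup →
category map; unmapped orthogroups are "uncategorized".

## Genome statistics

* **GC content** excludes `N` from numerator and denominator; empty or
  all-`N` input returns null.
* **GC skew** is (G−C)/(G+C) in sliding windows (defaults: 10 kb window,
  1 kb step) over a circular sequence — windows wrap past the origin, so
  there are `ceil(L / step)` of them; a window with no G or C records
  null.  Defaults suit chromosome-scale plots of ~0.5 Mb genomes; tests
  use smaller windows.
* **Codon usage** counts per codon with frequencies normalised within
  each synonymous family under the chosen code; genes whose length is
  not a multiple of 3 are skipped with a warning.  `gc3` reports
  third-position GC, the most sensitive readout of compositional bias.
* **Feature tallies** count GFF3 records by type, skipping unparseable
  lines, and — when tRNA records carry `anticodon=` attributes — check
  whether the decoded anticodons cover all 20 amino acids.
* **Anticodon-stem length** assumes the standard 7-nt anticodon loop
  (2 nt + anticodon + 2 nt) and counts consecutive pairing positions
  walking outward from the loop boundary, stopping at the first
  non-pairing position, capped at 7.  G·U wobble counts as pairing by
  default (wobble pairs are canonical in tRNA stems; disable with
  `allow_gu=False`).

## The synthetic-data generator

The generator produces every pipeline input with known ground truth; its
defaults are the package's study conditions.

**Marker families.**  Each family derives from a random ancestral protein
(default 200 residues, 50 reference taxa).  A fixed fraction of columns
(default 0.3) is conserved: exactly `ceil(conservation_level · n_taxa)`
taxa (default level 0.95) carry the consensus, so realized identity never
falls below the configured level and every truth column passes a 90%
scan.  Variable columns keep the ancestral residue with probability 0.5,
far below any HCAA threshold in expectation.

**Target genome.**  Each family's consensus is mutated at the divergence
rate (default 0.1, the regime of a confamilial relative), then
reverse-translated with synonymous-codon weights ∝ exp(λ·#GC(codon)),
where λ is solved by root-finding so the expected coding GC equals
`gc_target`; a target outside the composition's achievable range raises
a parameter error (with uniform amino-acid usage the floor is ≈ 0.30, so
the low-GC study setting is 0.32).  Genes get a TAA stop, a random
strand, and Poisson-length intergenic spacers (mean 100 nt) at the
target GC.  Under the `uga_trp` code, tryptophan is written as TGA with
probability 0.7 (else TGG) and every TGA-Trp site is recorded, flagged
by whether it sits at a conserved-W column.  With `divergence = 0` and
the standard code, annotation-guided translation reproduces the source
proteins exactly.

**Orthogroup matrix.**  A fixed five-group cladogram
`((T1,T2),(S1,S2,S3),(B1,B2))` — two targets, a three-taxon sister
clade, a basal pair — with independent per-branch loss of orthogroups
present at the root.  Default rates put most loss on the target-ancestor
branch (0.55) and target tips (0.5), with light background loss
elsewhere (0.02–0.05), so targets retain ≈ 20% of the ancestral set and
shared losses dominate — the regime of severely reduced sibling
endosymbionts.  The truth records every loss event per branch.

**tRNAs.**  A 7-nt anticodon loop flanked by exactly `stem_bp` ∈ {4, 5}
pairs (Watson–Crick with occasional G·U) and a guaranteed non-pairing
position at `stem_bp + 1`, so the stem length is unambiguous by
construction.

**What the generator does not emulate**, hence what passing tests do not
show about real data: no substitution-model branch lengths or rate
heterogeneity (reference taxa are i.i.d. around a consensus), no indels
within families, no paralogy or horizontal transfer in the orthogroup
model (losses only, independence across branches), no multi-replicon
genomes, no sequencing or assembly error, and amino-acid composition is
uniform rather than proteome-like (which is why the achievable GC floor
is higher than in real low-GC genomes).  Results on real data depend on
alignment quality and taxon sampling in ways these simulations cannot
probe.

## Study sizes and runtime choices

The code-recovery experiments (`tinygenome.experiments`) run 20 seeded
simulations per genetic code at 24 families × 50 taxa × 200 residues,
about 1,400 conserved sites per genome.  This is a deliberate desk-scale
stand-in for a full marker survey (~10⁵-residue alignments, ~10,000
usable sites): large enough that the TGA row is decisively sampled
(dozens of observations against a handful of divergence-noise pairings),
small enough that the whole study runs in a couple of minutes on one
CPU.  Oracle-equivalence checks use 100 random alignments/matrices, and
planted-gene recovery plants 100 single genes at 20% divergence in 2 kb
of random flanking DNA.

## Known limitations

* The code call is per-codon and frequency-based; it does not model
  sampling error explicitly (no confidence intervals on p(a|c)), so very
  rare codons stay "unassigned" rather than receiving an uncertain call.
* The translated search is full dynamic programming without heuristic
  seeding — appropriate for sub-megabase genomes and a few hundred
  queries, not for large-scale database search.
* The ancestral-proteome rule is the operational two-criteria bound, not
  a probabilistic ancestral-state reconstruction; orthogroups lost
  before the basal/sister split are invisible to it.
* Stem measurement assumes the canonical cloverleaf anticodon-loop
  geometry; structurally aberrant tRNAs would need a folding model.
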