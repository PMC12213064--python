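"""Synthetic data with known ground truth for every pipeline stage.

Emulates the inputs of a reduced-endosymbiont genome study: reference
marker-protein families with controlled column conservation, a compact
single-contig coding genome written under a chosen genetic code (standard
bacterial, or the UGA=Trp variant seen in low-GC reduced genomes), an
orthogroup presence/absence matrix produced by independent gene losses on
a fixed five-group cladogram, and tRNA sequences with a prescribed
anticodon-stem length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import brentq

from ._codons import (
    AMINO_ACIDS,
    GENETIC_CODES,
    gc_count,
    revcomp,
    synonymous_codons,
    translate_cds,
)
from .errors import ParameterError
from .hcaa import MarkerAlignment, consensus_sequence

logger = logging.getLogger(__name__)

_AA = np.array(list(AMINO_ACIDS))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: tens of conserved marker
    families over dozens of reference taxa, ~10% target divergence, and a
    low-GC target genome.
    """

    seed: int = 0
    n_families: int = 10
    n_ref_taxa: int = 50
    family_length: int = 200  # residues
    conserved_fraction: float = 0.3
    conservation_level: float = 0.95  # per-conserved-column identity
    genetic_code: str = "standard"  # or "uga_trp"
    gc_target: float = 0.33
    divergence: float = 0.1  # expected aa substitution fraction, consensus -> target
    intergenic_mean: int = 100  # nucleotides
    tga_prob: float = 0.7  # P(Trp encoded by TGA) under uga_trp

    def validate(self) -> None:
        for name in ("n_families", "n_ref_taxa", "family_length"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        for name in (
            "conserved_fraction",
            "conservation_level",
            "gc_target",
            "divergence",
            "tga_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.genetic_code not in GENETIC_CODES:
            raise ParameterError(
                f"genetic_code must be one of {sorted(GENETIC_CODES)}"
            )
        if self.intergenic_mean < 0:
            raise ParameterError("intergenic_mean must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# marker families


def generate_marker_families(
    config: SimConfig,
) -> tuple[list[MarkerAlignment], pd.DataFrame]:
    """Simulate aligned marker families with known conserved columns.

    Each family starts from a random ancestral protein.  A fixed fraction
    of columns are flagged conserved: there, exactly
    ``ceil(conservation_level * n_ref_taxa)`` taxa carry the consensus
    residue (so realized identity never falls below the configured
    level).  Remaining columns are variable (consensus kept with
    probability 0.5, otherwise a uniform residue).

    Returns the families and a truth table with columns
    ``family``, ``column``, ``consensus``.
    """
    config.validate()
    logger.info("generate_marker_families: seed=%d", config.seed)
    rng = np.random.default_rng(config.seed)
    n, L = config.n_ref_taxa, config.family_length
    n_cons = int(round(config.conserved_fraction * L))
    n_match = math.ceil(config.conservation_level * n)

    families: list[MarkerAlignment] = []
    truth_rows: list[tuple[str, int, str]] = []
    for f in range(config.n_families):
        fid = f"fam{f:03d}"
        ancestral = rng.choice(_AA, size=L)
        conserved = np.sort(rng.choice(L, size=n_cons, replace=False))
        cons_set = set(int(c) for c in conserved)
        matrix = np.empty((n, L), dtype="<U1")
        for col in range(L):
            aa = ancestral[col]
            if col in cons_set:
                col_res = np.full(n, aa, dtype="<U1")
                mut_taxa = rng.choice(n, size=n - n_match, replace=False)
                for t in mut_taxa:
                    col_res[t] = _random_other_aa(rng, aa)
            else:
                keep = rng.random(n) < 0.5
                col_res = np.where(keep, aa, rng.choice(_AA, size=n))
            matrix[:, col] = col_res
        seqs = tuple("".join(row) for row in matrix)
        taxa = tuple(f"taxon{t:03d}" for t in range(n))
        families.append(MarkerAlignment(fid, taxa, seqs))
        truth_rows.extend((fid, int(c), str(ancestral[c])) for c in conserved)

    truth = pd.DataFrame(truth_rows, columns=["family", "column", "consensus"])
    return families, truth


def _random_other_aa(rng: np.random.Generator, aa: str) -> str:
    while True:
        cand = str(rng.choice(_AA))
        if cand != aa:
            return cand


# ---------------------------------------------------------------------------
# target genome


@dataclass(frozen=True)
class Gene:
    """A planted CDS.  Coordinates are 0-based half-open on the forward
    strand and include the terminal stop codon."""

    family_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'

    @property
    def frame(self) -> int:
        return self.start % 3 if self.strand == "+" else self.end % 3

    def __post_init__(self):
        if (self.end - self.start) % 3:
            raise ParameterError("gene length must be divisible by 3")


@dataclass(frozen=True)
class TgaSite:
    """A genomic TGA codon that encodes tryptophan (uga_trp genomes)."""

    family_id: str
    protein_index: int  # residue index within the gene's protein
    start: int  # forward-strand start of the codon (0-based)
    strand: str
    at_conserved_column: bool


@dataclass
class GenomeTruth:
    contig: str
    length: int
    genetic_code: str
    genes: list[Gene] = field(default_factory=list)
    tga_sites: list[TgaSite] = field(default_factory=list)

    def extract_cds(self, genome: str, gene: Gene) -> str:
        """Coding-strand nucleotide sequence of a gene (stop included)."""
        seg = genome[gene.start : gene.end]
        return seg if gene.strand == "+" else revcomp(seg)

    def translate_gene(self, genome: str, gene: Gene, code: str | None = None) -> str:
        """Protein of a truth gene (terminal stop stripped)."""
        aa = translate_cds(self.extract_cds(genome, gene), code or self.genetic_code)
        return aa[:-1] if aa.endswith("*") else aa

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.contig} 1 {self.length}\n")
            for i, g in enumerate(self.genes):
                attrs = (
                    f"ID=cds{i:04d};family={g.family_id};"
                    f"genetic_code={self.genetic_code}"
                )
                fh.write(
                    "\t".join(
                        [
                            self.contig,
                            "tinygenome_sim",
                            "CDS",
                            str(g.start + 1),  # GFF3 is 1-based inclusive
                            str(g.end),
                            ".",
                            g.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def _solve_gc_bias(proteins: list[str], gc_target: float, code: str) -> float:
    """Find lambda with codon weights ∝ exp(lambda * #GC) matching gc_target.

    Raises ParameterError when the target GC is unreachable for the given
    amino-acid composition under the code (e.g. gc_target 0.0: tryptophan
    TGG always contributes G).
    """
    fams = synonymous_codons(GENETIC_CODES[code])
    aa_counts: dict[str, int] = {}
    for p in proteins:
        for aa in p:
            aa_counts[aa] = aa_counts.get(aa, 0) + 1

    def mean_gc(lam: float) -> float:
        total, sites = 0.0, 0
        for aa, cnt in aa_counts.items():
            codons = fams[aa]
            w = np.exp(lam * np.array([gc_count(c) for c in codons]))
            exp_gc = float(np.sum(w * [gc_count(c) for c in codons]) / np.sum(w))
            total += cnt * exp_gc
            sites += cnt * 3
        return total / sites

    lo, hi = -30.0, 30.0
    if not (mean_gc(lo) <= gc_target <= mean_gc(hi)):
        raise ParameterError(
            f"gc_target={gc_target} unreachable under code {code!r} "
            f"(achievable range {mean_gc(lo):.3f}-{mean_gc(hi):.3f})"
        )
    return float(brentq(lambda l: mean_gc(l) - gc_target, lo, hi, xtol=1e-6))


def _sample_codon(
    rng: np.random.Generator, codons: list[str], lam: float
) -> str:
    if len(codons) == 1:
        return codons[0]
    w = np.exp(lam * np.array([gc_count(c) for c in codons]))
    return str(rng.choice(codons, p=w / w.sum()))


def _random_spacer(rng: np.random.Generator, mean: int, gc: float) -> str:
    length = int(rng.poisson(mean)) if mean > 0 else 0
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def generate_target_genome(
    families: list[MarkerAlignment],
    config: SimConfig,
    truth_columns: pd.DataFrame | None = None,
    contig: str = "contig_1",
) -> tuple[str, GenomeTruth]:
    """Write each family's diverged consensus into a synthetic genome.

    The consensus protein of each family is mutated at the configured
    divergence, reverse-translated with synonymous-codon weights biased
    toward ``gc_target``, terminated with TAA, and placed on a random
    strand with Poisson-length intergenic spacers.  Under the uga_trp
    code, tryptophan is encoded by TGA with probability ``tga_prob``
    (TGG otherwise) and every TGA-Trp site is recorded in the truth.
    """
    if not families:
        raise ParameterError("families must be non-empty")
    config.validate()
    logger.info("generate_target_genome: seed=%d code=%s", config.seed, config.genetic_code)
    rng = np.random.default_rng((config.seed, 1))
    code = config.genetic_code
    fams = synonymous_codons(GENETIC_CODES[code])

    conserved_w: dict[str, set[int]] = {}
    if truth_columns is not None:
        trp = truth_columns[truth_columns["consensus"] == "W"]
        for fid, grp in trp.groupby("family"):
            conserved_w[str(fid)] = set(int(c) for c in grp["column"])

    # diverge each consensus once, then solve the GC bias for the realized
    # amino-acid composition
    proteins: list[tuple[str, str]] = []
    for fam in families:
        cons = consensus_sequence(fam)
        residues = list(cons)
        for i in range(len(residues)):
            if rng.random() < config.divergence:
                residues[i] = _random_other_aa(rng, residues[i])
        proteins.append((fam.family_id, "".join(residues)))
    lam = _solve_gc_bias([p for _, p in proteins], config.gc_target, code)

    parts: list[str] = []
    truth = GenomeTruth(contig=contig, length=0, genetic_code=code)
    pos = 0
    spacer = _random_spacer(rng, config.intergenic_mean, config.gc_target)
    parts.append(spacer)
    pos += len(spacer)
    for fid, protein in proteins:
        codon_list: list[str] = []
        tga_idx: list[int] = []
        for i, aa in enumerate(protein):
            if code == "uga_trp" and aa == "W":
                use_tga = rng.random() < config.tga_prob
                codon = "TGA" if use_tga else "TGG"
                if use_tga:
                    tga_idx.append(i)
            else:
                codon = _sample_codon(rng, fams[aa], lam)
            codon_list.append(codon)
        codon_list.append("TAA")  # terminal stop shared by both codes
        cds = "".join(codon_list)
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + len(cds)
        parts.append(cds if strand == "+" else revcomp(cds))
        gene = Gene(fid, contig, start, end, strand)
        truth.genes.append(gene)
        cons_cols = conserved_w.get(fid, set())
        for i in tga_idx:
            fwd_start = start + 3 * i if strand == "+" else end - 3 * (i + 1)
            truth.tga_sites.append(
                TgaSite(fid, i, fwd_start, strand, i in cons_cols)
            )
        pos = end
        spacer = _random_spacer(rng, config.intergenic_mean, config.gc_target)
        parts.append(spacer)
        pos += len(spacer)

    genome = "".join(parts)
    truth.length = len(genome)
    return genome, truth


def write_genome_fasta(genome: str, path: str | Path, name: str = "contig_1") -> None:
    SeqIO.write([SeqRecord(Seq(genome), id=name, description="")], str(path), "fasta")


# ---------------------------------------------------------------------------
# orthogroup matrix under a loss model

#: Fixed cladogram: ((target1,target2),(sisterA,sisterB,sisterC),(basal1,basal2)),
#: with the target clade sister to the sister clade and the basal pair outside.
DEFAULT_TAXA_GROUPS = {
    "target": ["T1", "T2"],
    "sister": ["S1", "S2", "S3"],
    "basal": ["B1", "B2"],
}

#: Branch loss rates chosen so targets retain ~20% of the ancestral set
#: with most losses shared on the target-ancestor branch.
DEFAULT_LOSS_RATES = {
    "inner": 0.02,
    "basal_mrca": 0.02,
    "sister_mrca": 0.02,
    "target_mrca": 0.55,
    "tip": 0.05,  # default for any tip without an explicit rate
    "tip:T1": 0.5,
    "tip:T2": 0.5,
}


def _branch_path(role: str, taxon: str) -> list[str]:
    if role == "basal":
        return ["basal_mrca", f"tip:{taxon}"]
    if role == "sister":
        return ["inner", "sister_mrca", f"tip:{taxon}"]
    if role == "target":
        return ["inner", "target_mrca", f"tip:{taxon}"]
    raise ParameterError(f"unknown role {role!r}")


def generate_orthogroup_matrix(
    taxa_groups: dict[str, list[str]] | None = None,
    n_orthogroups: int = 2151,
    loss_rates: dict[str, float] | float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Simulate presence/absence by independent losses on the cladogram.

    Every orthogroup is present at the root and is lost independently on
    each branch with that branch's rate; a tip carries the orthogroup iff
    no branch on its root-to-tip path lost it.

    Returns ``(matrix, roles, truth)`` where *matrix* is an orthogroup x
    taxon 0/1 DataFrame, *roles* maps taxon -> role, and *truth* records
    the root set and the per-branch loss events.
    """
    groups = taxa_groups if taxa_groups is not None else DEFAULT_TAXA_GROUPS
    for role in ("basal", "sister", "target"):
        if not groups.get(role):
            raise ParameterError(f"taxa group {role!r} must be non-empty")
    if n_orthogroups < 1:
        raise ParameterError("n_orthogroups must be positive")

    if loss_rates is None:
        rates = dict(DEFAULT_LOSS_RATES)
    elif isinstance(loss_rates, (int, float)):
        rates = {"tip": float(loss_rates)}
        for b in ("inner", "basal_mrca", "sister_mrca", "target_mrca"):
            rates[b] = float(loss_rates)
    else:
        rates = dict(loss_rates)

    def rate(branch: str) -> float:
        r = rates.get(branch, rates.get("tip", 0.0) if branch.startswith("tip:") else 0.0)
        if not (0.0 <= r <= 1.0):
            raise ParameterError(f"loss rate for {branch!r} outside [0, 1]")
        return r

    logger.info("generate_orthogroup_matrix: seed=%d n=%d", seed, n_orthogroups)
    rng = np.random.default_rng((seed, 2))
    og_ids = [f"OG{i:07d}" for i in range(n_orthogroups)]
    taxa = [t for role in ("basal", "sister", "target") for t in groups[role]]
    roles = {t: role for role in ("basal", "sister", "target") for t in groups[role]}

    branches = ["inner", "basal_mrca", "sister_mrca", "target_mrca"] + [
        f"tip:{t}" for t in taxa
    ]
    lost: dict[str, np.ndarray] = {
        b: rng.random(n_orthogroups) < rate(b) for b in branches
    }

    data = {}
    for t in taxa:
        path = _branch_path(roles[t], t)
        absent = np.zeros(n_orthogroups, dtype=bool)
        for b in path:
            absent |= lost[b]
        data[t] = (~absent).astype(int)
    matrix = pd.DataFrame(data, index=og_ids)
    truth = {
        "root": list(og_ids),
        "losses": {b: [og_ids[i] for i in np.flatnonzero(lost[b])] for b in branches},
    }
    return matrix, roles, truth


# ---------------------------------------------------------------------------
# tRNA with a prescribed anticodon-stem length

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_MISMATCH = ("A", "G")  # neither Watson-Crick nor G-U


def generate_trna(
    stem_bp: int, seed: int = 0, anticodon: str = "CCA", flank: int = 8
) -> tuple[str, int]:
    """Build a tRNA-like sequence whose anticodon stem has *stem_bp* pairs.

    The 7-nt anticodon loop (2 nt + anticodon + 2 nt) is flanked by
    exactly *stem_bp* paired positions (Watson-Crick, with an occasional
    G·U wobble) and a guaranteed mismatch at position ``stem_bp + 1``.
    Returns the sequence and the 0-based index of the anticodon.
    """
    if stem_bp not in (4, 5):
        raise ParameterError(f"stem_bp must be 4 or 5, got {stem_bp}")
    rng = np.random.default_rng((seed, 3))
    bases = list("ACGT")

    stem5, stem3 = [], []
    for _ in range(stem_bp):
        b5 = str(rng.choice(bases))
        b3 = _WC[b5]
        if b5 in ("G", "T") and rng.random() < 0.25:
            b3 = "T" if b5 == "G" else "G"  # G-U wobble pair
        stem5.append(b5)
        stem3.append(b3)
    loop5 = "".join(rng.choice(bases, size=2))
    loop3 = "".join(rng.choice(bases, size=2))
    flank5 = "".join(rng.choice(bases, size=flank))
    flank3 = "".join(rng.choice(bases, size=flank))

    seq = (
        flank5
        + _MISMATCH[0]
        + "".join(stem5)
        + loop5
        + anticodon
        + loop3
        + "".join(reversed(stem3))
        + _MISMATCH[1]
        + flank3
    )
    anticodon_index = flank + 1 + stem_bp + 2
    return seq, anticodon_index
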