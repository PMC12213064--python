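"""Codon tables, alphabets and low-level sequence helpers.

The standard bacterial code is NCBI translation table 11; the UGA=Trp
variant (table 4, as used by *Mycoplasma*-like reduced genomes) differs
only in reading TGA as tryptophan instead of a termination signal.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"

#: The 20 standard amino acids, alphabetically.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: All 64 codons in alphabetical order (row order of the 64x20 matrix).
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def _table_to_dict(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


#: codon -> amino acid (or '*') under the standard bacterial code.
STANDARD_CODE: dict[str, str] = _table_to_dict(11)

#: codon -> amino acid with TGA reassigned to tryptophan.
UGA_TRP_CODE: dict[str, str] = _table_to_dict(4)

GENETIC_CODES = {"standard": STANDARD_CODE, "uga_trp": UGA_TRP_CODE}


def synonymous_codons(code: dict[str, str]) -> dict[str, list[str]]:
    """Map each amino acid (and '*') to its codons under *code*."""
    families: dict[str, list[str]] = {}
    for codon, aa in code.items():
        families.setdefault(aa, []).append(codon)
    for fam in families.values():
        fam.sort()
    return families


_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def gc_count(codon: str) -> int:
    return codon.count("G") + codon.count("C")


def translate_cds(seq: str, code: dict[str, str] | str = "standard") -> str:
    """Translate an in-frame nucleotide sequence codon by codon.

    Codons containing N (or any non-ACGT letter) translate to 'X';
    trailing partial codons are dropped.  Stop codons render '*'.
    """
    if isinstance(code, str):
        code = GENETIC_CODES[code]
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append(code.get(codon, "X"))
    return "".join(out)
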