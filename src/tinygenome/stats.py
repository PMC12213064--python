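"""Descriptive genome statistics: GC content, circular GC skew, codon
usage, annotation feature tallies, and tRNA anticodon-stem length.

The anticodon-stem measurement formalises the structural contrast behind
UGA readthrough: a tRNA-Trp(CCA) whose anticodon stem closes with four
base pairs (rather than the canonical five) is associated with efficient
decoding of UGA as tryptophan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import GENETIC_CODES, revcomp, synonymous_codons
from .errors import ParameterError

logger = logging.getLogger(__name__)


def gc_content(sequence: str) -> float | None:
    """(G+C) / (A+C+G+T); N and other letters excluded.  Empty -> None."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return None
    return (counts["G"] + counts["C"]) / denom


@dataclass
class SkewProfile:
    """Windowed (G-C)/(G+C) over a (by default circular) sequence."""

    window: int
    step: int
    starts: list[int]
    values: list[float | None]  # None where a window has no G or C

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"start": self.starts,
             "skew": [np.nan if v is None else v for v in self.values]}
        ).to_csv(path, sep="\t", index=False)


def gc_skew(
    sequence: str, window: int = 10_000, step: int = 1_000, circular: bool = True
) -> SkewProfile:
    """Sliding-window GC skew; windows wrap past the origin when circular."""
    seq = sequence.upper()
    n = len(seq)
    if not (1 <= step <= window):
        raise ParameterError("require window >= step >= 1")
    if window > n:
        raise ParameterError(f"window {window} exceeds sequence length {n}")
    starts, values = [], []
    for i in range(math.ceil(n / step)):
        start = i * step
        if start + window <= n:
            win = seq[start : start + window]
        elif circular:
            win = seq[start:] + seq[: (start + window) % n]
        else:
            win = seq[start:]
        g, c = win.count("G"), win.count("C")
        starts.append(start)
        values.append(None if g + c == 0 else (g - c) / (g + c))
    return SkewProfile(window, step, starts, values)


def codon_usage(
    genes: list[str], code: str = "standard"
) -> pd.DataFrame:
    """Codon counts and within-amino-acid-family relative frequencies.

    Genes whose length is not divisible by 3 are skipped with a warning.
    Returns a 64-row DataFrame (codon, amino_acid, count, frequency)
    where frequency normalises counts within each synonymous family
    under *code* (0 where the family was never used).
    """
    table = GENETIC_CODES[code]
    counts: dict[str, int] = {c: 0 for c in table}
    for i, gene in enumerate(genes):
        g = gene.upper()
        if len(g) % 3:
            logger.warning("gene %d length %d not divisible by 3; skipped", i, len(g))
            continue
        for j in range(0, len(g), 3):
            codon = g[j : j + 3]
            if codon in counts:
                counts[codon] += 1
    fams = synonymous_codons(table)
    rows = []
    for aa, codons in sorted(fams.items()):
        fam_total = sum(counts[c] for c in codons)
        for c in codons:
            freq = counts[c] / fam_total if fam_total else 0.0
            rows.append((c, aa, counts[c], freq))
    df = pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "frequency"])
    return df.sort_values("codon").reset_index(drop=True)


def gc3(genes: list[str]) -> float | None:
    """GC fraction at third codon positions across in-frame genes."""
    thirds = "".join(
        g.upper()[2::3] for g in genes if len(g) % 3 == 0
    )
    return gc_content(thirds)


_ANTICODON_ATTRS = ("anticodon",)


def feature_tally(gff3_path: str | Path) -> dict:
    """Count features by type in a GFF3 annotation.

    Returns ``{"counts": {...}, "n_features": int,
    "trna_covers_all_amino_acids": bool | None}`` — the coverage check
    translates each tRNA's ``anticodon=`` attribute (reverse-complement
    gives the codon) and asks whether all 20 amino acids are decoded;
    None when no anticodon attributes are present.  Unparseable lines
    are logged and skipped.
    """
    counts: dict[str, int] = {t: 0 for t in ("CDS", "rRNA", "tRNA", "tmRNA")}
    anticodon_aas: set[str] = set()
    saw_anticodon = False
    n_features = 0
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                logger.warning("%s:%d unparseable GFF3 line skipped", gff3_path, lineno)
                continue
            ftype = fields[2]
            counts[ftype] = counts.get(ftype, 0) + 1
            n_features += 1
            if ftype == "tRNA":
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                for key in _ANTICODON_ATTRS:
                    if key in attrs:
                        saw_anticodon = True
                        codon = revcomp(attrs[key].upper().replace("U", "T"))
                        aa = GENETIC_CODES["standard"].get(codon, "X")
                        if aa == "*" and codon == "TGA":
                            aa = "W"  # tRNA-Trp(CCA)-style readthrough isoacceptor
                        if aa not in ("*", "X"):
                            anticodon_aas.add(aa)
    coverage = len(anticodon_aas) >= 20 if saw_anticodon else None
    return {
        "counts": counts,
        "n_features": n_features,
        "trna_covers_all_amino_acids": coverage,
    }


_PAIRS_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_PAIRS_GU = {("G", "T"), ("T", "G")}


def _pairs(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _PAIRS_WC or (allow_gu and (a, b) in _PAIRS_GU)


def anticodon_stem_length(
    trna: str, anticodon_start: int, allow_gu: bool = True, max_bp: int = 7
) -> int:
    """Base pairs in the anticodon stem, walking outward from the loop.

    The 7-nt anticodon loop is assumed centred on the anticodon (2 nt on
    each side); stem position k pairs sequence indices
    ``anticodon_start - 2 - k`` and ``anticodon_start + 4 + k``.
    Counting stops at the first non-pairing position and is capped at
    *max_bp*.  G·U wobble counts as pairing unless disabled.
    """
    seq = trna.upper().replace("U", "T")
    if not (0 <= anticodon_start and anticodon_start + 3 <= len(seq)):
        raise ParameterError(
            f"anticodon index {anticodon_start} out of range for length {len(seq)}"
        )
    length = 0
    for k in range(1, max_bp + 1):
        i = anticodon_start - 2 - k
        j = anticodon_start + 4 + k
        if i < 0 or j >= len(seq):
            break
        if _pairs(seq[i], seq[j], allow_gu):
            length += 1
        else:
            break
    return length
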