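"""Highly conserved amino acid (HCAA) positions in marker-protein alignments.

A column of a reference multiple alignment is an HCAA position when at
least a threshold fraction (default 90%) of the sequences carry the same
amino acid.  Such columns anchor genetic-code inference: whatever codon a
diverged genome uses at an HCAA position almost certainly encodes the
conserved residue, so pairing observed codons with conserved residues
across thousands of positions reads the genome's code directly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import AMINO_ACIDS
from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

_STANDARD_AA = set(AMINO_ACIDS)


@dataclass(frozen=True)
class MarkerAlignment:
    """One aligned conserved protein family across reference taxa.

    Residues are uppercase; '-' marks gaps; 'X' stands for any
    non-standard or ambiguous letter.
    """

    family_id: str
    taxon_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if not self.sequences:
            raise FormatError(f"{self.family_id}: alignment has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(
                f"{self.family_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError(f"{self.family_id}: duplicate taxon ids")
        if len(self.taxon_ids) != len(self.sequences):
            raise FormatError(f"{self.family_id}: ids/sequences count mismatch")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.sequences)


@dataclass(frozen=True)
class HCAAPosition:
    family_id: str
    column: int  # 0-based alignment column
    consensus_aa: str
    conservation: float


def _sanitize(residues: str) -> str:
    out = []
    for ch in residues.upper():
        if ch in _STANDARD_AA or ch == "-":
            out.append(ch)
        else:
            out.append("X")  # U, O, B, Z, J, ambiguity codes ...
    return "".join(out)


def read_alignment_fasta(path: str | Path, family_id: str | None = None) -> MarkerAlignment:
    """Read an aligned protein FASTA into a :class:`MarkerAlignment`.

    Residues are uppercased; non-standard letters map to 'X'.  Ragged
    lengths or an empty file raise :class:`FormatError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    fid = family_id if family_id is not None else path.stem
    return MarkerAlignment(
        family_id=fid,
        taxon_ids=tuple(r.id for r in records),
        sequences=tuple(_sanitize(str(r.seq)) for r in records),
    )


def write_alignment_fasta(alignment: MarkerAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="")
        for tid, seq in zip(alignment.taxon_ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def identify_hcaa(
    alignment: MarkerAlignment, threshold: float = 0.90
) -> list[HCAAPosition]:
    """Return the columns where >= *threshold* of sequences share one residue.

    The denominator is the total number of sequences, gaps included; gaps
    and 'X' never count toward the modal residue.  The threshold is
    inclusive ("90% or more").  If two residues tie for modal at or above
    the threshold (possible only for threshold <= 0.5) the column is
    rejected: an ambiguous column has no consensus.
    """
    if not (0 < threshold <= 1):
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    n = alignment.n_sequences
    positions: list[HCAAPosition] = []
    for col in range(alignment.n_columns):
        counts = Counter(alignment.column(col))
        for non_aa in ("-", "X"):
            counts.pop(non_aa, None)
        if not counts:
            continue
        (aa, top), *rest = counts.most_common()
        if rest and rest[0][1] == top:
            continue  # tied modal residues: no consensus
        # integer comparison avoids float-boundary surprises at e.g. 9/10
        if top * 1.0 / n >= threshold - 1e-12:
            positions.append(
                HCAAPosition(alignment.family_id, col, aa, top / n)
            )
    return positions


def consensus_sequence(alignment: MarkerAlignment) -> str:
    """Ungapped modal-residue sequence (ties broken alphabetically).

    Columns with no standard residue at all are dropped.
    """
    out = []
    for col in range(alignment.n_columns):
        counts = Counter(
            ch for ch in alignment.column(col) if ch in _STANDARD_AA
        )
        if not counts:
            continue
        top = max(counts.values())
        out.append(min(aa for aa, c in counts.items() if c == top))
    return "".join(out)


def consensus_column_map(alignment: MarkerAlignment) -> dict[int, int]:
    """Map alignment column -> residue index in :func:`consensus_sequence`."""
    mapping: dict[int, int] = {}
    i = 0
    for col in range(alignment.n_columns):
        if any(ch in _STANDARD_AA for ch in alignment.column(col)):
            mapping[col] = i
            i += 1
    return mapping


def ungapped_column_map(alignment: MarkerAlignment, taxon_id: str) -> dict[int, int]:
    """Map alignment column -> residue index of one taxon's ungapped sequence."""
    try:
        idx = alignment.taxon_ids.index(taxon_id)
    except ValueError as exc:
        raise ParameterError(f"unknown taxon {taxon_id!r}") from exc
    mapping: dict[int, int] = {}
    i = 0
    for col, ch in enumerate(alignment.sequences[idx]):
        if ch != "-":
            mapping[col] = i
            i += 1
    return mapping


def hcaa_to_frame(positions: list[HCAAPosition]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.family_id, p.column, p.consensus_aa, p.conservation) for p in positions],
        columns=["family", "column", "consensus", "conservation"],
    )


def write_hcaa_tsv(positions: list[HCAAPosition], path: str | Path) -> None:
    hcaa_to_frame(positions).to_csv(path, sep="\t", index=False)


def read_hcaa_tsv(path: str | Path) -> list[HCAAPosition]:
    df = pd.read_csv(path, sep="\t")
    return [
        HCAAPosition(str(r.family), int(r.column), str(r.consensus), float(r.conservation))
        for r in df.itertuples()
    ]
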