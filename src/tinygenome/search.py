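"""Six-frame translated homology search and codon-observation counting.

Marker proteins are located in the target genome by Smith-Waterman local
alignment against all six translation frames (BLOSUM62, affine gaps),
the in-process equivalent of a tBLASTn search.  Stop codons in the
translated frames are rendered '*' and score a flat penalty instead of
terminating the alignment — essential, because a genome that reassigned
UGA to tryptophan has conserved ORFs "interrupted" by what table 11
calls a stop, and the alignment must read through them.

Hits are then projected onto HCAA alignment columns: each conserved
column aligned to a subject residue yields one (genome codon, conserved
amino acid) observation, and the observations accumulate into the
64 x 20 codon-observation matrix that the code-inference stage consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._codons import AMINO_ACIDS, CODONS, GENETIC_CODES, revcomp, translate_cds
from .errors import FormatError, ParameterError
from .hcaa import HCAAPosition

logger = logging.getLogger(__name__)

_STANDARD_AA = set(AMINO_ACIDS)

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_STOP_PENALTY = -4
DEFAULT_SCORE_THRESHOLD = 60.0
MAX_SPAN_OVERLAP = 0.5  # hits sharing more than this fraction collapse to one


# ---------------------------------------------------------------------------
# six-frame translation with coordinate maps


@dataclass(frozen=True)
class FrameTranslation:
    """One translated reading frame with its genome coordinate map."""

    contig: str
    strand: str  # '+' or '-'
    frame: int  # 0-2, offset on the translated strand
    protein: str
    contig_length: int

    def codon_span(self, residue_index: int) -> tuple[int, int]:
        """Forward-strand half-open span of the codon behind one residue."""
        if not (0 <= residue_index < len(self.protein)):
            raise ParameterError(f"residue index {residue_index} out of frame")
        off = self.frame + 3 * residue_index
        if self.strand == "+":
            return off, off + 3
        return self.contig_length - off - 3, self.contig_length - off


def six_frame_translate(
    sequence: str, contig: str = "contig_1", code: str = "standard"
) -> list[FrameTranslation]:
    """Translate all six frames; codons containing N become 'X'.

    Trailing partial codons are dropped.  An empty sequence yields six
    empty frames.
    """
    seq = sequence.upper()
    rc = revcomp(seq)
    frames = []
    for strand, s in (("+", seq), ("-", rc)):
        for f in range(3):
            frames.append(
                FrameTranslation(
                    contig, strand, f, translate_cds(s[f:], code), len(seq)
                )
            )
    return frames


# ---------------------------------------------------------------------------
# local alignment


@dataclass
class TranslatedHit:
    """A local alignment of a marker protein against one genome frame."""

    family_id: str
    query_id: str
    contig: str
    strand: str
    frame: int
    span: tuple[int, int]  # forward strand, 0-based half-open
    score: float
    aligned_query: str  # gapped
    aligned_subject: str  # gapped, stops as '*'
    query_start: int  # index of first aligned query residue
    subject_start: int  # index of first aligned residue in the frame translation
    _frame_translation: FrameTranslation = field(repr=False, default=None)

    def __post_init__(self):
        if (self.span[1] - self.span[0]) % 3:
            raise ParameterError("hit span must be a whole number of codons")

    @property
    def n_subject_residues(self) -> int:
        return sum(1 for ch in self.aligned_subject if ch != "-")

    def query_to_subject(self) -> dict[int, int]:
        """Map aligned query residue index -> frame-translation residue index."""
        mapping: dict[int, int] = {}
        qi, si = self.query_start, self.subject_start
        for qc, sc in zip(self.aligned_query, self.aligned_subject):
            if qc != "-" and sc != "-":
                mapping[qi] = si
            if qc != "-":
                qi += 1
            if sc != "-":
                si += 1
        return mapping


def scoring_matrix(stop_penalty: int = DEFAULT_STOP_PENALTY):
    """BLOSUM62 with the '*' row/column pinned to *stop_penalty*."""
    m = substitution_matrices.load("BLOSUM62")
    if stop_penalty == DEFAULT_STOP_PENALTY:
        return m  # BLOSUM62 already scores '*' at -4 against residues
    m = m.copy()
    for ch in m.alphabet:
        if ch != "*":
            m[ch, "*"] = stop_penalty
            m["*", ch] = stop_penalty
    return m


def _make_aligner(stop_penalty: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scoring_matrix(stop_penalty)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _gapped_strings(alignment) -> tuple[str, str, int, int]:
    """Rebuild gapped query/subject strings from an alignment's blocks."""
    q, s = alignment.sequences
    qb, sb = alignment.aligned
    out_q, out_s = [], []
    prev_q, prev_s = qb[0][0], sb[0][0]
    for (q0, q1), (s0, s1) in zip(qb, sb):
        if q0 > prev_q:  # subject gap opposite unaligned query residues
            out_q.append(q[prev_q:q0])
            out_s.append("-" * (q0 - prev_q))
        if s0 > prev_s:  # query gap opposite unaligned subject residues
            out_q.append("-" * (s0 - prev_s))
            out_s.append(s[prev_s:s0])
        out_q.append(q[q0:q1])
        out_s.append(s[s0:s1])
        prev_q, prev_s = q1, s1
    return "".join(out_q), "".join(out_s), int(qb[0][0]), int(sb[0][0])


def translated_search(
    genome: str,
    query: str,
    family_id: str = "query",
    query_id: str = "query",
    contig: str = "contig_1",
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    stop_penalty: int = DEFAULT_STOP_PENALTY,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    code_for_search: str = "standard",
) -> list[TranslatedHit]:
    """Smith-Waterman the query protein against all six genome frames.

    Returns hits scoring at or above the threshold, after collapsing
    hits that share more than half of a genome span for the same query
    (single-copy markers imply one locus each); the highest score wins,
    ties broken by leftmost start.
    """
    query = query.upper()
    if len(query) < 30:
        raise ParameterError("query must be at least 30 residues")
    bad = set(query) - _STANDARD_AA - {"X"}
    if bad:
        raise FormatError(f"query contains non-amino-acid letters: {sorted(bad)}")
    if code_for_search not in GENETIC_CODES:
        raise ParameterError(f"unknown code_for_search {code_for_search!r}")

    aligner = _make_aligner(stop_penalty, gap_open, gap_extend)
    hits: list[TranslatedHit] = []
    for ft in six_frame_translate(genome, contig, code_for_search):
        if not ft.protein:
            continue
        alignments = aligner.align(query, ft.protein)
        if alignments.score < score_threshold:
            continue
        aln = alignments[0]
        gq, gs, q0, s0 = _gapped_strings(aln)
        n_sub = sum(1 for ch in gs if ch != "-")
        first = ft.codon_span(s0)
        last = ft.codon_span(s0 + n_sub - 1)
        span = (min(first[0], last[0]), max(first[1], last[1]))
        hits.append(
            TranslatedHit(
                family_id=family_id,
                query_id=query_id,
                contig=contig,
                strand=ft.strand,
                frame=ft.frame,
                span=span,
                score=float(alignments.score),
                aligned_query=gq,
                aligned_subject=gs,
                query_start=q0,
                subject_start=s0,
                _frame_translation=ft,
            )
        )
    return filter_overlapping_hits(hits)


def filter_overlapping_hits(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Keep the best-scoring hit among hits sharing >50% of a genome span."""
    kept: list[TranslatedHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.span[0])):
        clash = False
        for other in kept:
            if hit.contig != other.contig:
                continue
            ov = min(hit.span[1], other.span[1]) - max(hit.span[0], other.span[0])
            shorter = min(hit.span[1] - hit.span[0], other.span[1] - other.span[0])
            if ov > MAX_SPAN_OVERLAP * shorter:
                clash = True
                break
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: h.span[0])
    return kept


def hits_to_frame(hits: list[TranslatedHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.family_id, h.contig, h.strand, h.frame, h.span[0], h.span[1], h.score)
            for h in hits
        ],
        columns=["family", "contig", "strand", "frame", "start", "end", "score"],
    )


# ---------------------------------------------------------------------------
# HCAA -> codon observations


@dataclass(frozen=True)
class CodonObservation:
    family_id: str
    column: int  # alignment column of the HCAA position
    consensus_aa: str
    codon: str  # coding-strand codon
    contig: str
    genome_start: int  # forward-strand start of the codon
    strand: str


def map_hcaa_to_codons(
    hit: TranslatedHit,
    hcaa: list[HCAAPosition],
    query_column_map: dict[int, int],
    genome: str,
) -> list[CodonObservation]:
    """Project HCAA columns through a hit onto genome codons.

    For each conserved column whose query residue falls inside the hit
    and aligns to a subject residue (not a gap), emit the coding-strand
    codon at that residue paired with the column's consensus amino acid.
    Subject '*' positions emit too — a reassigned stop codon at a
    conserved-tryptophan column is exactly the signal of interest.
    """
    q2s = hit.query_to_subject()
    ft = hit._frame_translation
    observations: list[CodonObservation] = []
    for pos in hcaa:
        if pos.family_id != hit.family_id:
            raise ParameterError(
                f"HCAA family {pos.family_id!r} does not match hit family "
                f"{hit.family_id!r}"
            )
        qi = query_column_map.get(pos.column)
        if qi is None or qi not in q2s:
            continue
        si = q2s[qi]
        start, end = ft.codon_span(si)
        codon = genome[start:end].upper()
        if hit.strand == "-":
            codon = revcomp(codon)
        observations.append(
            CodonObservation(
                hit.family_id, pos.column, pos.consensus_aa, codon,
                hit.contig, start, hit.strand,
            )
        )
    return observations


# ---------------------------------------------------------------------------
# the 64 x 20 matrix


class CodonObservationMatrix:
    """Counts of (codon, conserved amino acid) co-occurrences.

    Rows are the 64 codons (alphabetical), columns the 20 amino acids
    (alphabetical); ``total_sites`` equals the grand sum.
    """

    def __init__(self, counts: pd.DataFrame | None = None):
        if counts is None:
            counts = pd.DataFrame(
                0, index=list(CODONS), columns=list(AMINO_ACIDS), dtype=int
            )
        else:
            counts = counts.reindex(
                index=list(CODONS), columns=list(AMINO_ACIDS), fill_value=0
            ).astype(int)
            if (counts.values < 0).any():
                raise ParameterError("codon observation counts must be >= 0")
        self.counts = counts

    @property
    def total_sites(self) -> int:
        return int(self.counts.values.sum())

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="codon")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonObservationMatrix":
        df = pd.read_csv(path, sep="\t", index_col="codon")
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CodonObservationMatrix) and self.counts.equals(
            other.counts
        )


def accumulate(observations: list[CodonObservation]) -> CodonObservationMatrix:
    """Count observations into the 64 x 20 matrix.

    Duplicate observations of the same (family, column, genome codon
    position) — e.g. from overlapping retained hits — count once.
    Codons containing N are discarded with a logged count.
    """
    matrix = CodonObservationMatrix()
    seen: set[tuple[str, int, str, int]] = set()
    n_dropped = 0
    for obs in observations:
        key = (obs.family_id, obs.column, obs.contig, obs.genome_start)
        if key in seen:
            continue
        seen.add(key)
        if obs.codon not in STANDARD_CODON_SET:
            n_dropped += 1
            continue
        matrix.counts.loc[obs.codon, obs.consensus_aa] += 1
    if n_dropped:
        logger.info("accumulate: dropped %d observations with ambiguous codons", n_dropped)
    return matrix


STANDARD_CODON_SET = set(CODONS)
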