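"""Genetic-code inference from the codon-observation matrix.

Each of the 64 codons is called independently: normalise its row of the
64 x 20 matrix to a probability vector, and assign the codon to an amino
acid when the evidence is both sufficient (enough observed sites) and
decisive (one amino acid dominates).  Assigned codons whose meaning
differs from the standard bacterial code (table 11) are reassignments;
a genome whose only reassignment is UGA: stop -> Trp is using the
*Mycoplasma*-like code, NCBI translation table 4.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import AMINO_ACIDS, CODONS, STANDARD_CODE
from .errors import ParameterError
from .search import CodonObservationMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Reassignment:
    codon: str
    standard_meaning: str  # amino acid or 'stop'
    inferred_meaning: str


@dataclass
class GeneticCodeCall:
    """Per-codon probabilities, discrete assignments and the table choice."""

    probabilities: pd.DataFrame  # 64 x 20, rows sum to 1 or to 0
    totals: pd.Series  # observations per codon
    assignments: dict[str, str]  # codon -> amino acid or 'unassigned'
    reassignments: list[Reassignment] = field(default_factory=list)
    selected_table: int | str = 11
    min_count: int = 10
    dominance: float = 0.8

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_table": self.selected_table,
            "min_count": self.min_count,
            "dominance": self.dominance,
            "assignments": self.assignments,
            "reassignments": [
                [r.codon, r.standard_meaning, r.inferred_meaning]
                for r in self.reassignments
            ],
            "totals": {c: int(self.totals[c]) for c in CODONS},
            "probabilities": {
                c: {a: float(self.probabilities.loc[c, a]) for a in AMINO_ACIDS}
                for c in CODONS
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def standard_meaning(codon: str) -> str:
    aa = STANDARD_CODE[codon]
    return "stop" if aa == "*" else aa


def infer_code(
    matrix: CodonObservationMatrix,
    min_count: int = 10,
    dominance: float = 0.8,
) -> GeneticCodeCall:
    """Call each codon's meaning from conserved-position evidence.

    A codon is assigned to amino acid *a* iff it was observed at least
    ``min_count`` times and ``p(a | codon) >= dominance``; otherwise it
    is left unassigned.  Unassigned stop codons are presumed to retain
    termination; an assigned stop codon is always a reassignment.
    """
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    if not (0 < dominance <= 1):
        raise ParameterError("dominance must be in (0, 1]")

    counts = matrix.counts.astype(float)
    totals = counts.sum(axis=1)
    probs = counts.div(totals.where(totals > 0, 1.0), axis=0)
    probs[totals == 0] = 0.0

    assignments: dict[str, str] = {}
    reassignments: list[Reassignment] = []
    for codon in CODONS:
        total = totals[codon]
        if total < min_count:
            assignments[codon] = UNASSIGNED
            continue
        row = probs.loc[codon]
        aa = row.idxmax()
        if row[aa] >= dominance:
            assignments[codon] = aa
            std = standard_meaning(codon)
            if aa != std:
                reassignments.append(Reassignment(codon, std, aa))
        else:
            assignments[codon] = UNASSIGNED

    call = GeneticCodeCall(
        probabilities=probs,
        totals=totals.astype(int),
        assignments=assignments,
        reassignments=sorted(reassignments, key=lambda r: r.codon),
        min_count=min_count,
        dominance=dominance,
    )
    call.selected_table = select_translation_table(call)
    return call


def select_translation_table(call: GeneticCodeCall) -> int | str:
    """Choose the annotation table implied by the reassignment list.

    No reassignments -> standard bacterial table 11; exactly the single
    reassignment UGA(TGA): stop -> Trp -> table 4; anything else ->
    'custom' with a warning.
    """
    re = {(r.codon, r.standard_meaning, r.inferred_meaning) for r in call.reassignments}
    if not re:
        return 11
    if re == {("TGA", "stop", "W")}:
        return 4
    logger.warning(
        "reassignments %s match no standard table; selecting 'custom'", sorted(re)
    )
    return "custom"


def export_logo_matrix(
    call: GeneticCodeCall,
    tsv_path: str | Path | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-codon amino-acid probability table (rows with no data all-zero).

    Optionally writes the table as TSV and renders a stacked-letter
    probability logo (one column per observed codon).
    """
    table = call.probabilities.copy()
    if tsv_path is not None:
        table.to_csv(tsv_path, sep="\t", index_label="codon")
    if plot_path is not None:
        _plot_logo(call, plot_path)
    return table


def _plot_logo(call: GeneticCodeCall, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    observed = [c for c in CODONS if call.totals[c] > 0]
    fig, ax = plt.subplots(figsize=(max(6, 0.28 * len(observed)), 3.2))
    for x, codon in enumerate(observed):
        row = call.probabilities.loc[codon]
        y = 0.0
        for aa in row.sort_values().index:
            p = float(row[aa])
            if p <= 0.005:
                continue
            ax.text(
                x, y + p / 2, aa,
                ha="center", va="center",
                fontsize=4 + 14 * p, family="monospace",
            )
            y += p
    ax.set_xticks(range(len(observed)))
    ax.set_xticklabels(observed, rotation=90, fontsize=5, family="monospace")
    ax.set_ylim(0, 1.02)
    ax.set_xlim(-1, len(observed))
    ax.set_ylabel("probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
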