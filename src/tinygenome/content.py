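"""Ancestral gene content from orthogroup presence/absence.

The minimal ancestral proteome of a pair of reduced genomes is defined
operationally from the phylogeny: an orthogroup belongs to it iff it is
present in at least one taxon of the basal group of the family AND in at
least one taxon of the sister lineage of the targets.  Target-taxon
presence plays no part in the definition, which makes retention in the
targets a meaningful measurement rather than a tautology.  Losses from
the ancestral set are then partitioned into shared losses (absent from
every target: events on the common-ancestor branch) and lineage-specific
losses.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

ROLES = ("basal", "sister", "target", "other")


@dataclass
class OrthogroupMatrix:
    """Binary presence/absence of orthogroups across named taxa."""

    presence: pd.DataFrame  # orthogroups x taxa, 0/1
    roles: dict[str, str]  # taxon -> basal | sister | target | other

    def __post_init__(self):
        df = self.presence
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise FormatError("duplicate orthogroup or taxon ids")
        unknown = set(self.roles) - set(df.columns)
        if unknown:
            raise ConfigurationError(f"roles for unknown taxa: {sorted(unknown)}")
        bad_roles = set(self.roles.values()) - set(ROLES)
        if bad_roles:
            raise ConfigurationError(f"unknown roles: {sorted(bad_roles)}")
        for role in ("basal", "sister", "target"):
            if not self.taxa_with_role(role):
                raise ConfigurationError(f"no taxon has role {role!r}")
        self.presence = df.astype(bool)

    def taxa_with_role(self, role: str) -> list[str]:
        return [t for t in self.presence.columns if self.roles.get(t) == role]

    def present_in(self, taxon: str) -> set[str]:
        col = self.presence[taxon]
        return set(col.index[col])

    @classmethod
    def from_tsv(
        cls, matrix_path: str | Path, roles_path: str | Path
    ) -> "OrthogroupMatrix":
        """Read an orthogroup x taxon 0/1 TSV plus a taxon -> role YAML map.

        Any positive count binarizes to presence, so a binarized
        OrthoFinder gene-count table works directly.
        """
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        with open(roles_path) as fh:
            roles = yaml.safe_load(fh)
        if not isinstance(roles, dict):
            raise ConfigurationError(f"{roles_path}: expected a taxon->role mapping")
        return cls((df > 0).astype(int), {str(k): str(v) for k, v in roles.items()})

    def to_tsv(self, matrix_path: str | Path, roles_path: str | Path | None = None) -> None:
        self.presence.astype(int).to_csv(matrix_path, sep="\t", index_label="orthogroup")
        if roles_path is not None:
            with open(roles_path, "w") as fh:
                yaml.safe_dump(self.roles, fh, sort_keys=True)


@dataclass
class LossLedger:
    """The ancestral set partitioned per target into retained / shared-loss /
    lineage-specific-loss classes."""

    ancestral: set[str]
    targets: list[str]
    retained: dict[str, set[str]]
    shared_loss: set[str]
    specific_loss: dict[str, set[str]]
    retained_pct: dict[str, float | None] = field(default_factory=dict)

    @property
    def ancestral_size(self) -> int:
        return len(self.ancestral)

    def counts(self) -> dict:
        return {
            "ancestral": self.ancestral_size,
            "shared_loss": len(self.shared_loss),
            "retained": {t: len(self.retained[t]) for t in self.targets},
            "retained_pct": dict(self.retained_pct),
            "specific_loss": {t: len(self.specific_loss[t]) for t in self.targets},
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.counts(), fh, indent=1, sort_keys=True)


def infer_ancestral_proteome(matrix: OrthogroupMatrix) -> set[str]:
    """Two-criteria minimal ancestral set: present in >=1 basal taxon AND
    >=1 sister taxon.  Target presence is ignored."""
    basal = matrix.taxa_with_role("basal")
    sister = matrix.taxa_with_role("sister")
    df = matrix.presence
    mask = df[basal].any(axis=1) & df[sister].any(axis=1)
    return set(df.index[mask])


def truncate_pct(count: int, total: int) -> float:
    """Percentage floored at one decimal: 477/2151 -> 22.1, 402/2151 -> 18.6."""
    return math.floor(1000 * count / total) / 10


def compute_retention(
    ancestral: set[str], matrix: OrthogroupMatrix, target: str
) -> tuple[int, float | None]:
    """Count and truncated percentage of ancestral orthogroups a target kept.

    An empty ancestral set has no defined percentage: returns (0, None).
    """
    if matrix.roles.get(target) != "target":
        raise ConfigurationError(f"{target!r} is not a target taxon")
    if not ancestral:
        return 0, None
    count = len(ancestral & matrix.present_in(target))
    return count, truncate_pct(count, len(ancestral))


def partition_losses(
    ancestral: set[str], matrix: OrthogroupMatrix, targets: list[str] | None = None
) -> LossLedger:
    """Split ancestral losses into shared and lineage-specific classes.

    shared_loss: absent from every target (loss on the common-ancestor
    branch, under parsimony); specific_loss(t): absent from t but present
    in at least one other target; retained(t): present in t.  For every
    target the three classes partition the ancestral set exactly.
    """
    if targets is None:
        targets = matrix.taxa_with_role("target")
    if not targets:
        raise ConfigurationError("at least one target taxon required")
    present = {t: ancestral & matrix.present_in(t) for t in targets}
    any_present = set().union(*present.values())
    shared_loss = ancestral - any_present
    specific = {t: (ancestral - present[t]) - shared_loss for t in targets}
    ledger = LossLedger(
        ancestral=set(ancestral),
        targets=list(targets),
        retained=present,
        shared_loss=shared_loss,
        specific_loss=specific,
        retained_pct={
            t: (truncate_pct(len(present[t]), len(ancestral)) if ancestral else None)
            for t in targets
        },
    )
    for t in targets:  # exact set algebra, asserted not approximated
        assert present[t] | shared_loss | specific[t] == ancestral
        assert not (present[t] & shared_loss)
        assert not (present[t] & specific[t])
        assert not (shared_loss & specific[t])
    return ledger


UNCATEGORIZED = "uncategorized"


def read_category_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (orthogroup, category); malformed rows logged, skipped."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                logger.warning("category map line %d malformed, skipped", lineno)
                continue
            mapping[parts[0]] = parts[1]
    return mapping


def summarize_categories(
    ledger: LossLedger, category_map: dict[str, str]
) -> pd.DataFrame:
    """Contingency of functional category x loss class.

    Classes: retained_all (kept by every target), shared_loss, and one
    ``specific_loss(t)`` per target.  With two targets the classes
    partition each category exactly, so class counts sum to the
    per-category ancestral totals reported alongside; with more targets
    an orthogroup lost from several (but not all) appears in several
    specific-loss columns.
    """
    retained_all = set.intersection(*(ledger.retained[t] for t in ledger.targets))
    classes: dict[str, set[str]] = {"retained_all": retained_all,
                                    "shared_loss": ledger.shared_loss}
    for t in ledger.targets:
        classes[f"specific_loss({t})"] = ledger.specific_loss[t]

    def cat(og: str) -> str:
        return category_map.get(og, UNCATEGORIZED)

    categories = sorted({cat(og) for og in ledger.ancestral} | {UNCATEGORIZED})
    rows = []
    for c in categories:
        members = {og for og in ledger.ancestral if cat(og) == c}
        row = {name: len(members & ogs) for name, ogs in classes.items()}
        row["ancestral_total"] = len(members)
        rows.append(row)
    return pd.DataFrame(rows, index=categories)
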