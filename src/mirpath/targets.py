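"""Filtered miRNA->gene interaction maps and signature target sets.

Interactions come with a prediction-score percentile (TargetScan-style
context-score percentile: the predicted efficacy of a site relative to
all sites of that miRNA) and a CLIP support count (number of
cross-linking immunoprecipitation experiments confirming physical
binding).  "CLIP-confirmed" is operationalized as a support count >= 1;
the percentile cut is strict (> threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = [
    "InteractionTable",
    "ModulationAnnotation",
    "filter_interactions",
    "targets_of_set",
    "modulators_of_gene",
]

COLUMNS = ["mirna", "gene", "percentile", "clip_count"]


@dataclass
class InteractionTable:
    """(miRNA, gene) interaction records with score and CLIP support."""

    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise ContractError(f"interaction table missing columns: {missing}")
        self.records = self.records[COLUMNS].reset_index(drop=True)
        dup = self.records.duplicated(subset=["mirna", "gene"])
        if dup.any():
            pairs = self.records.loc[dup, ["mirna", "gene"]].head(5).to_records(index=False)
            raise ContractError(f"duplicate (miRNA, gene) pairs, e.g. {list(pairs)}")
        pct = self.records["percentile"].to_numpy(float)
        if ((pct <= 0) | (pct > 100)).any():
            raise ContractError("percentiles must lie in (0, 100]")
        if (self.records["clip_count"].to_numpy() < 0).any():
            raise ContractError("CLIP support counts must be >= 0")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mirnas(self) -> set:
        return set(self.records["mirna"])

    @property
    def genes(self) -> set:
        return set(self.records["gene"])


@dataclass
class ModulationAnnotation:
    """miRNAs modulating one gene, per signature, with direction and FC."""

    gene: str
    # signature name -> list of dicts {mirna, direction, fc}
    by_signature: dict[str, list[dict]] = field(default_factory=dict)


def filter_interactions(
    table: InteractionTable, min_percentile: float = 50.0, require_clip: bool = True
) -> InteractionTable:
    """Keep records with percentile strictly above the cut and, when
    ``require_clip``, CLIP support count >= 1.  Idempotent."""
    r = table.records
    keep = r["percentile"] > min_percentile
    if require_clip:
        keep &= r["clip_count"] >= 1
    return InteractionTable(r[keep].reset_index(drop=True))


def targets_of_set(filtered: InteractionTable, mirna_set) -> set:
    """Union of genes interacting with any miRNA of the set."""
    mirna_set = set(mirna_set)
    if not mirna_set:
        return set()
    r = filtered.records
    return set(r.loc[r["mirna"].isin(mirna_set), "gene"])


def modulators_of_gene(
    filtered: InteractionTable,
    gene: str,
    signatures: dict[str, set],
    de_result,
) -> ModulationAnnotation:
    """miRNAs of each signature with a filtered interaction to ``gene``.

    Direction (up/down) and fold change are pulled from the classified
    ``DEResult``; miRNAs absent from a signature, or unclassified, are
    excluded from that signature's list.
    """
    r = filtered.records
    if gene not in set(r["gene"]):
        raise KeyError(f"gene {gene!r} has no record in the filtered interaction table")
    interacting = set(r.loc[r["gene"] == gene, "mirna"])
    table = de_result.table
    if "class" not in table:
        raise ContractError("de_result must be classified (run classify_de)")
    ann = ModulationAnnotation(gene=gene)
    for name, members in signatures.items():
        entries = []
        for m in sorted(interacting & set(members)):
            if m not in table.index:
                continue
            label = table.at[m, "class"]
            if label == "not-significant":
                continue
            entries.append(
                {"mirna": m, "direction": label, "fc": float(table.at[m, "fc"])}
            )
        ann.by_signature[name] = entries
    return ann
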