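"""Pathway over-representation with Fisher and permutation nulls.

Two engines on the same counts:

* one-sided hypergeometric (Fisher) tail ``P(X >= k)`` for the overlap
  ``k`` between a targeted gene set (size ``n``) and a pathway (size
  ``K``) drawn from a background of ``N`` genes;
* a miRNA-level permutation null: random miRNA subsets of the same size
  as the signature are drawn from the expressed miRNAs, mapped through
  the filtered interaction table, and the per-pathway statistic is
  recomputed, yielding ``p = (1 + #{stat_b >= stat_obs}) / (B + 1)``.

The permutation null corrects the targetability bias of the
hypergeometric analysis: genes with long, site-rich 3'UTRs are targeted
by almost any miRNA set, so pathways made of such genes look enriched
under hypergeometric sampling of genes while remaining unremarkable
under resampling of miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .targets import InteractionTable, targets_of_set

__all__ = [
    "PathwayDB",
    "fisher_enrichment",
    "permutation_enrichment",
    "stratified_enrichment",
    "significance_tier",
]


@dataclass
class PathwayDB:
    """Pathway name -> gene set, with an explicit gene universe."""

    pathways: dict[str, frozenset]
    universe: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.pathways = {k: frozenset(v) for k, v in self.pathways.items()}
        for name, members in self.pathways.items():
            if not members:
                raise ContractError(f"pathway {name!r} is empty")
        union = frozenset().union(*self.pathways.values()) if self.pathways else frozenset()
        if self.universe is None:
            self.universe = union
        else:
            self.universe = frozenset(self.universe)
            stray = union - self.universe
            if stray:
                raise ContractError(
                    f"pathway genes outside the declared universe, e.g. {sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.pathways)

    def names(self) -> list[str]:
        return sorted(self.pathways)


def significance_tier(p: float) -> str:
    """Reporting tiers for enrichment P-values: *** / ** / * / ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def fisher_enrichment(gene_set, db: PathwayDB, background=None) -> pd.DataFrame:
    """One-sided over-representation P per pathway.

    ``background`` defaults to the database universe.  Pathways are
    intersected with the background before counting, so an externally
    supplied (e.g. targetable-gene) background is honoured consistently.
    Returns a DataFrame indexed by pathway with columns
    k, K, n, N, fisher_p, overlap (semicolon-joined sorted genes).
    """
    gene_set = set(gene_set)
    bg = frozenset(background) if background is not None else db.universe
    stray = gene_set - bg
    if stray:
        raise ContractError(
            f"gene set members outside the background: {sorted(stray)[:10]}"
        )
    n = len(gene_set)
    N = len(bg)
    rows = []
    for name in db.names():
        members = db.pathways[name] & bg
        K = len(members)
        overlap = sorted(gene_set & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "pathway": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fisher_p": min(p, 1.0),
                "overlap": ";".join(overlap),
            }
        )
    return pd.DataFrame(rows).set_index("pathway")


def _target_matrix(filtered: InteractionTable, mirnas: list[str], gene_index: dict):
    """Boolean (n_mirna x n_gene) matrix of filtered targets."""
    mat = np.zeros((len(mirnas), len(gene_index)), dtype=bool)
    midx = {m: i for i, m in enumerate(mirnas)}
    r = filtered.records
    for m, g in zip(r["mirna"], r["gene"]):
        if m in midx and g in gene_index:
            mat[midx[m], gene_index[g]] = True
    return mat


def permutation_enrichment(
    mirna_set,
    expressed_mirnas,
    filtered_interactions: InteractionTable,
    db: PathwayDB,
    B: int = 999,
    seed: int | None = None,
    statistic: str = "count",
    background=None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Size-matched miRNA-resampling enrichment test.

    For b = 1..B a uniform random subset of ``expressed_mirnas`` with
    ``|mirna_set|`` members is drawn, its targeted gene set computed,
    and the per-pathway statistic evaluated.  ``statistic`` is either
    ``"count"`` (targeted genes in the pathway; larger is more extreme)
    or ``"fisher"`` (the one-sided hypergeometric P of the resampled
    set; smaller is more extreme).  With ``exhaustive=True`` every
    subset is enumerated instead of sampled (only sensible for tiny
    problems) and B is ignored.

    Returns the :func:`fisher_enrichment` table of the observed set with
    columns ``perm_p`` and ``B`` appended.
    """
    mirna_set = sorted(set(mirna_set))
    expressed = sorted(set(expressed_mirnas))
    if not set(mirna_set) <= set(expressed):
        raise ContractError("mirna_set must be a subset of expressed_mirnas")
    if len(mirna_set) > len(expressed):
        raise ContractError("mirna_set larger than the expressed universe")
    if B < 1 and not exhaustive:
        raise ContractError("B must be >= 1")
    if statistic not in ("count", "fisher"):
        raise ContractError("statistic must be 'count' or 'fisher'")

    bg = frozenset(background) if background is not None else db.universe
    genes = sorted(bg)
    gene_index = {g: i for i, g in enumerate(genes)}
    tmat = _target_matrix(filtered_interactions, expressed, gene_index)
    names = db.names()
    pmat = np.zeros((len(names), len(genes)), dtype=bool)
    for i, name in enumerate(names):
        for g in db.pathways[name] & bg:
            pmat[i, gene_index[g]] = True
    K = pmat.sum(axis=1)
    N = len(genes)

    obs = fisher_enrichment(
        targets_of_set(filtered_interactions, mirna_set) & bg, db, background=bg
    )
    k = len(mirna_set)
    eidx = {m: i for i, m in enumerate(expressed)}
    set_rows = np.array([eidx[m] for m in mirna_set], dtype=int)

    if exhaustive:
        from itertools import combinations

        draws = [np.array(c, dtype=int) for c in combinations(range(len(expressed)), k)]
    else:
        rng = np.random.default_rng(seed)
        draws = [
            rng.choice(len(expressed), size=k, replace=False) for _ in range(B)
        ]

    def stat_of(rows: np.ndarray) -> np.ndarray:
        tgt = tmat[rows].any(axis=0)
        counts = (pmat & tgt[None, :]).sum(axis=1)
        if statistic == "count":
            return counts.astype(float)
        n = int(tgt.sum())
        return stats.hypergeom.sf(counts - 1, N, K, n)

    stat_obs = stat_of(set_rows)
    extreme = np.zeros(len(names), dtype=int)
    for rows in draws:
        s = stat_of(np.asarray(rows))
        if statistic == "count":
            extreme += s >= stat_obs
        else:
            extreme += s <= stat_obs
    nb = len(draws)
    perm_p = (1.0 + extreme) / (nb + 1.0)

    out = obs.copy()
    out["perm_p"] = perm_p
    out["B"] = nb
    return out


def stratified_enrichment(
    up_set,
    down_set,
    expressed_mirnas,
    filtered_interactions: InteractionTable,
    db: PathwayDB,
    B: int = 999,
    seed: int | None = None,
    statistic: str = "count",
    background=None,
) -> dict[str, pd.DataFrame]:
    """Run both enrichment engines separately on up- and down-regulated
    miRNA strata.  Strata must be disjoint; empty strata yield empty
    result tables."""
    up_set, down_set = set(up_set), set(down_set)
    if up_set & down_set:
        raise ContractError(f"up/down strata overlap: {sorted(up_set & down_set)[:5]}")
    out = {}
    for label, members in (("up", up_set), ("down", down_set)):
        if not members:
            out[label] = pd.DataFrame(
                columns=["k", "K", "n", "N", "fisher_p", "overlap", "perm_p", "B"]
            )
            continue
        out[label] = permutation_enrichment(
            members,
            expressed_mirnas,
            filtered_interactions,
            db,
            B=B,
            seed=seed,
            statistic=statistic,
            background=background,
        )
    return out
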