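"""Phenotype signature sets: Venn partition, z-scoring, subset clustering.

Three pairwise differential-expression contrasts (modelA vs reference,
modelB vs reference, modelB vs modelA) define up to seven disjoint Venn
cells.  Aggregates of interest: the "E2-independent growth" set (DE in
both model-vs-reference contrasts), the model-specific sets, and the
members contributed only by the direct model-vs-model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexp import ExpressionStudy
from .errors import ContractError

__all__ = ["SignaturePartition", "partition_signatures", "zscore_rows", "cluster_within_subsets"]

CELLS = ("ABC", "AB", "A_only", "AC", "B_only", "BC", "C_only")
#: display order of the seven cells: shared core first, then the
#: modelA-specific block, the modelB-specific block, and the
#: direct-contrast-only block (mirrors the heatmap's colour groups).


@dataclass
class SignaturePartition:
    """Seven disjoint cells keyed by membership over contrasts A, B, C.

    A = modelA vs reference, B = modelB vs reference, C = modelB vs modelA.
    Cell keys: ``A_only``, ``B_only``, ``C_only``, ``AB``, ``AC``, ``BC``,
    ``ABC`` (pairwise cells exclude the triple intersection).
    """

    cells: dict[str, frozenset]

    @property
    def union(self) -> frozenset:
        return frozenset().union(*self.cells.values())

    @property
    def e2_independent(self) -> frozenset:
        """DE in both model-vs-reference contrasts (A and B)."""
        return self.cells["AB"] | self.cells["ABC"]

    @property
    def specific_a(self) -> frozenset:
        """modelA-specific: in A but not in B."""
        return self.cells["A_only"] | self.cells["AC"]

    @property
    def specific_b(self) -> frozenset:
        """modelB-specific: in B but not in A."""
        return self.cells["B_only"] | self.cells["BC"]

    @property
    def direct_only(self) -> frozenset:
        """Contributed only by the direct model-vs-model contrast."""
        return self.cells["C_only"]

    def counts(self) -> dict[str, int]:
        out = {cell: len(members) for cell, members in self.cells.items()}
        out.update(
            union=len(self.union),
            e2_independent=len(self.e2_independent),
            specific_a=len(self.specific_a),
            specific_b=len(self.specific_b),
            direct_only=len(self.direct_only),
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell in CELLS:
            for f in sorted(self.cells[cell]):
                rows.append(
                    {
                        "feature": f,
                        "cell": cell,
                        "e2_independent": f in self.e2_independent,
                        "specific_a": f in self.specific_a,
                        "specific_b": f in self.specific_b,
                        "direct_only": f in self.direct_only,
                    }
                )
        return pd.DataFrame(rows, columns=["feature", "cell", "e2_independent",
                                           "specific_a", "specific_b", "direct_only"])


def partition_signatures(de_a, de_b, de_c) -> SignaturePartition:
    """Exact set-algebra partition of three DE feature sets."""
    a, b, c = frozenset(de_a), frozenset(de_b), frozenset(de_c)
    cells = {
        "ABC": a & b & c,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "A_only": a - b - c,
        "B_only": b - a - c,
        "C_only": c - a - b,
    }
    return SignaturePartition(cells)


def zscore_rows(study: ExpressionStudy, features=None) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each retained row to mean 0, sd 1 (sample sd, n-1).

    Zero-variance rows are excluded and returned in the second element.
    """
    values = study.values if features is None else study.values.loc[list(features)]
    sd = values.std(axis=1, ddof=1)
    excluded = list(values.index[sd == 0])
    kept = values.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return z, excluded


def correlation_linkage(matrix: pd.DataFrame) -> np.ndarray:
    """Complete-linkage agglomeration on d = 1 - Pearson r between rows."""
    if len(matrix) < 2:
        raise ContractError("need >= 2 rows to cluster")
    r = np.corrcoef(matrix.to_numpy(float))
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize away rounding
    return hierarchy.linkage(squareform(d, checks=False), method="complete")


def cluster_within_subsets(
    matrix: pd.DataFrame,
    partition: SignaturePartition,
    subset_order: tuple[str, ...] = CELLS,
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Order features subset-by-subset, clustering within each cell.

    Features are laid out in the fixed ``subset_order`` of Venn cells;
    inside each cell the order is the dendrogram leaf order of
    complete-linkage clustering on 1 - Pearson r across the matrix
    columns.  Cells of size 0 are skipped, singletons pass through with
    no dendrogram.  Only features present in ``matrix`` participate
    (z-scoring may have excluded constant rows).
    """
    order: list[str] = []
    dendrograms: dict[str, np.ndarray] = {}
    present = set(matrix.index)
    for cell in subset_order:
        members = sorted(partition.cells[cell] & present)
        if not members:
            continue
        if len(members) == 1:
            order.extend(members)
            continue
        linkage = correlation_linkage(matrix.loc[members])
        leaves = hierarchy.leaves_list(linkage)
        order.extend(members[i] for i in leaves)
        dendrograms[cell] = linkage
    return order, dendrograms


def plot_heatmap(matrix: pd.DataFrame, order: list[str], path) -> None:
    """Basic z-score heatmap in the subset-wise clustered order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.loc[order]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.08 * len(order))))
    im = ax.imshow(data.to_numpy(float), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
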