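"""Readers and writers for every tabular dialect the pipeline uses.

All tabular files are TSV (tab-separated, UTF-8, '.' decimal) with a
header row; pathway databases use the standard GMT convention
(name, description, tab-separated genes); networks are written both as
edge-list TSV and GraphML.  Writers emit a fixed column order so runs
are byte-reproducible; readers validate schemas and report the file and
line of the first offending record.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffexp import ExpressionStudy
from .enrichment import PathwayDB
from .errors import SchemaError
from .simulate import ClinicalCohort
from .targets import COLUMNS as INTERACTION_COLUMNS
from .targets import InteractionTable

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "read_study",
    "write_study",
    "read_interactions",
    "write_interactions",
    "read_gmt",
    "write_gmt",
    "read_cohort",
    "write_cohort",
    "write_de_result",
    "write_network",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SchemaError(f"malformed TSV: {exc}", path=path) from exc
    except FileNotFoundError:
        raise SchemaError("file not found", path=path) from None


def read_matrix(path) -> pd.DataFrame:
    """Expression/count matrix: features in rows, sample-id header."""
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = int(np.nonzero(df.index == dup)[0][1]) + 2
        raise SchemaError(f"duplicate feature id {dup!r}", path=path, line=line)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise SchemaError(
                f"non-numeric cell {df[col][bad].iloc[0]!r}", path=path, line=line, column=col
            )
        if coerced.isna().any():
            line = int(np.nonzero(coerced.isna().to_numpy())[0][0]) + 2
            raise SchemaError("missing value", path=path, line=line, column=col)
        df[col] = coerced
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature")


def read_samples(path) -> pd.Series:
    """Sample sheet: columns sample, group."""
    df = _read_tsv(path)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise SchemaError(f"sample sheet missing column {col!r}", path=path)
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate sample id {dup!r}", path=path)
    return pd.Series(df["group"].to_numpy(), index=df["sample"].to_numpy())


def write_samples(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_study(matrix_path, samples_path) -> ExpressionStudy:
    return ExpressionStudy(read_matrix(matrix_path), read_samples(samples_path))


def write_study(study: ExpressionStudy, matrix_path, samples_path) -> None:
    write_matrix(study.values, matrix_path)
    write_samples(study.groups, samples_path)


def read_interactions(path) -> InteractionTable:
    df = _read_tsv(path)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"interaction table missing columns: {missing}", path=path)
    dup = df.duplicated(subset=["mirna", "gene"])
    if dup.any():
        line = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise SchemaError("duplicate (miRNA, gene) pair", path=path, line=line)
    return InteractionTable(df)


def write_interactions(table: InteractionTable, path) -> None:
    table.records[INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> PathwayDB:
    """GMT: one pathway per line — name, description, >=1 gene."""
    path = Path(path)
    pathways = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"GMT line needs name, description and >=1 gene; got {len(fields)} field(s)",
                    path=path,
                    line=lineno,
                )
            name = fields[0]
            if name in pathways:
                raise SchemaError(f"duplicate pathway {name!r}", path=path, line=lineno)
            genes = [g for g in fields[2:] if g]
            if len(set(genes)) != len(genes):
                raise SchemaError(f"duplicate gene within pathway {name!r}", path=path, line=lineno)
            pathways[name] = frozenset(genes)
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in db.names():
            genes = "\t".join(sorted(db.pathways[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_cohort(counts_path, clinical_path) -> ClinicalCohort:
    counts = read_matrix(counts_path)
    df = _read_tsv(clinical_path)
    for col in ("patient", "subtype", "time", "event"):
        if col not in df.columns:
            raise SchemaError(f"clinical table missing column {col!r}", path=clinical_path)
    if df["patient"].duplicated().any():
        raise SchemaError("duplicate patient id", path=clinical_path)
    clinical = df.set_index("patient")[["subtype", "time", "event"]]
    missing = [p for p in counts.columns if p not in clinical.index]
    if missing:
        raise SchemaError(f"patients without clinical record: {missing[:5]}", path=clinical_path)
    lib = None
    if "library_size" in df.columns:
        lib = df.set_index("patient")["library_size"].loc[list(counts.columns)]
    return ClinicalCohort(counts, clinical.loc[list(counts.columns)], library_sizes=lib)


def write_cohort(cohort: ClinicalCohort, counts_path, clinical_path) -> None:
    cohort.counts.to_csv(counts_path, sep="\t", index_label="feature")
    out = cohort.clinical.reset_index()
    out.columns = ["patient", "subtype", "time", "event"]
    out["library_size"] = cohort.library_sizes.to_numpy()
    out.to_csv(clinical_path, sep="\t", index=False)


def write_de_result(result, path) -> None:
    """DEResult table with fixed column order."""
    t = result.table
    mean_cols = [c for c in t.columns if c.startswith("mean_")]
    cols = mean_cols + ["log2fc", "fc", "t_ord", "t_mod", "p_raw", "p_holm"]
    if "class" in t.columns:
        cols.append("class")
    t[cols].to_csv(path, sep="\t", index_label="feature")


def write_network(net: nx.Graph, edges_path, graphml_path=None) -> None:
    rows = [
        {"pathway1": u, "pathway2": v, "jaccard": data["weight"]}
        for u, v, data in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["pathway1", "pathway2", "jaccard"]).to_csv(
        edges_path, sep="\t", index=False
    )
    if graphml_path is not None:
        g = net.copy()
        for _, data in g.nodes(data=True):
            data["regulated"] = ";".join(data["regulated"])
        nx.write_graphml(g, graphml_path)
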