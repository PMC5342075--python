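"""End-to-end orchestration of the analysis stages.

Stages: differential expression on the three contrasts -> signature
partition -> interaction filtering and target sets -> pathway
enrichment (Fisher + permutation) per model-specific signature ->
pathway networks and their comparison -> optional clinical layer.
Every intermediate artifact is written as TSV; a JSON manifest records
package/library versions, the seed, thresholds, input checksums and the
per-stage record counts, and suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import clinical as clin
from .diffexp import classify_de, fit_moderated_t
from .enrichment import permutation_enrichment
from .errors import ConfigError
from .io import (
    read_cohort,
    read_gmt,
    read_interactions,
    read_study,
    write_de_result,
    write_network,
)
from .network import build_network, compare_networks
from .signatures import cluster_within_subsets, partition_signatures, zscore_rows
from .targets import filter_interactions, targets_of_set

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("diffexp", "signatures", "targets", "enrichment", "network", "clinical")


@dataclass
class PipelineConfig:
    matrix: str
    samples: str
    interactions: str
    gmt: str
    out_dir: str
    counts: str | None = None
    clinical: str | None = None
    # contrasts: (modelA, reference), (modelB, reference), (modelB, modelA)
    contrasts: tuple | None = None
    fc: float = 1.5
    alpha: float = 0.05
    adjust: str = "holm"
    min_percentile: float = 50.0
    require_clip: bool = True
    pathway_p: float = 0.05
    perms: int = 999
    survival_mirna: str | None = None
    seed: int = 0
    resume: bool = False

    def validate(self) -> None:
        if not self.fc > 1:
            raise ConfigError("fc threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.adjust not in ("holm", "none"):
            raise ConfigError("adjust must be 'holm' or 'none'")
        if not 0 <= self.min_percentile < 100:
            raise ConfigError("min_percentile must lie in [0, 100)")
        if self.perms < 1:
            raise ConfigError("perms must be >= 1")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"

    previous: dict = {}
    if config.resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())

    inputs = {"matrix": config.matrix, "samples": config.samples,
              "interactions": config.interactions, "gmt": config.gmt}
    if config.counts and config.clinical:
        inputs.update(counts=config.counts, clinical=config.clinical)
    checksums = {k: _sha256(v) for k, v in inputs.items()}
    if previous and previous.get("input_checksums") != checksums:
        previous = {}  # inputs changed: restart from scratch

    import pandas as _pd
    import scipy as _sp

    manifest: dict = {
        "package_version": __version__,
        "library_versions": {"numpy": np.__version__, "pandas": _pd.__version__,
                             "scipy": _sp.__version__},
        "seed": config.seed,
        "thresholds": {k: v for k, v in asdict(config).items()
                       if k in ("fc", "alpha", "adjust", "min_percentile",
                                "require_clip", "pathway_p", "perms")},
        "input_checksums": checksums,
        "stages": dict(previous.get("stages", {})),
    }

    def done(stage: str) -> bool:
        return config.resume and stage in manifest["stages"]

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    study = read_study(config.matrix, config.samples)
    groups = study.group_names
    if config.contrasts is None:
        if len(groups) < 3:
            raise ConfigError("need >= 3 groups or explicit contrasts")
        ref, ma, mb = groups[0], groups[1], groups[2]
        contrasts = ((ma, ref), (mb, ref), (mb, ma))
    else:
        contrasts = tuple(tuple(c) for c in config.contrasts)

    use_adjusted = config.adjust == "holm"
    de_results = {}
    de_sets = []
    for ga, gb in contrasts:
        res = classify_de(
            fit_moderated_t(study, ga, gb),
            fc_threshold=config.fc,
            p_threshold=config.alpha,
            use_adjusted=use_adjusted,
        )
        de_results[(ga, gb)] = res
        de_sets.append(frozenset(res.significant()))
        if not done("diffexp"):
            write_de_result(res, out / f"de_{ga}_vs_{gb}.tsv")
    if not done("diffexp"):
        record("diffexp", contrasts=[list(c) for c in contrasts],
               n_significant=[len(s) for s in de_sets])

    partition = partition_signatures(*de_sets)
    if not done("signatures"):
        partition.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
        # heatmap-style ordering over the non-reference-72h sample layout
        z, _ = zscore_rows(study, sorted(partition.union & set(study.features)))
        order, _ = cluster_within_subsets(z, partition)
        (out / "feature_order.txt").write_text("\n".join(order) + "\n")
        record("signatures", counts=partition.counts())

    interactions = read_interactions(config.interactions)
    filtered = filter_interactions(
        interactions, min_percentile=config.min_percentile, require_clip=config.require_clip
    )
    sig_a = set(partition.specific_a)
    sig_b = set(partition.specific_b)
    targets_a = targets_of_set(filtered, sig_a)
    targets_b = targets_of_set(filtered, sig_b)
    if not done("targets"):
        from .io import write_interactions

        write_interactions(filtered, out / "interactions_filtered.tsv")
        (out / "targets_specific_a.txt").write_text("\n".join(sorted(targets_a)) + "\n")
        (out / "targets_specific_b.txt").write_text("\n".join(sorted(targets_b)) + "\n")
        record("targets", n_records_in=len(interactions), n_records_kept=len(filtered),
               n_targets_a=len(targets_a), n_targets_b=len(targets_b))

    db = read_gmt(config.gmt)
    background = filtered.genes & set(db.universe)
    expressed = sorted(filtered.mirnas | sig_a | sig_b)
    enrich = {}
    for label, sig in (("a", sig_a), ("b", sig_b)):
        enrich[label] = permutation_enrichment(
            sig, expressed, filtered, db, B=config.perms,
            seed=config.seed, background=background,
        )
        if not done("enrichment"):
            enrich[label].to_csv(out / f"enrichment_specific_{label}.tsv", sep="\t")
    if not done("enrichment"):
        record("enrichment", n_pathways=len(db),
               n_enriched_a=int((enrich["a"]["fisher_p"] < config.pathway_p).sum()),
               n_enriched_b=int((enrich["b"]["fisher_p"] < config.pathway_p).sum()))

    nets = {}
    for label, sig_targets in (("a", targets_a), ("b", targets_b)):
        nets[label] = build_network(
            enrich[label], db, sig_targets & background, p_threshold=config.pathway_p
        )
        if not done("network"):
            write_network(nets[label], out / f"network_{label}_edges.tsv",
                          out / f"network_{label}.graphml")
    comparison = compare_networks(nets["a"], nets["b"])
    if not done("network"):
        comparison.frequency.rename("n_pathways").to_csv(
            out / "gene_pathway_frequency.tsv", sep="\t", index_label="gene"
        )
        record("network",
               nodes=[nets["a"].number_of_nodes(), nets["b"].number_of_nodes()],
               comparison_sizes=list(comparison.sizes()))

    if config.counts and config.clinical:
        if not done("clinical"):
            cohort = read_cohort(config.counts, config.clinical)
            expr = clin.log2cpm(cohort.counts, cohort.library_sizes)
            rho, _, order, _ = clin.spearman_cluster(expr)
            rho.loc[order, order].to_csv(out / "spearman_rho.tsv", sep="\t")
            info = {"n_patients": cohort.clinical.shape[0]}
            if config.survival_mirna:
                cp = clin.find_cutpoint(
                    cohort.clinical["time"].to_numpy(),
                    cohort.clinical["event"].to_numpy(),
                    expr.loc[config.survival_mirna].to_numpy(),
                    n_perm=config.perms,
                    seed=config.seed,
                )
                info["cutpoint"] = {
                    "mirna": config.survival_mirna,
                    "threshold": cp.threshold,
                    "hr": cp.cox.hr,
                    "ci": list(cp.cox.ci),
                    "logrank_p": cp.logrank_p,
                    "p_adjusted": cp.p_adjusted,
                }
            record("clinical", **info)
    else:
        record("clinical", skipped=True)

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
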