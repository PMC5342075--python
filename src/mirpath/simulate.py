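"""Synthetic data generators for every pipeline input.

The generators emulate the statistical structure the analysis assumes:

* a three-group (reference / modelA / modelB) log2 expression study with
  a handful of replicates per group, planted differential shifts, an
  optionally co-regulated feature cluster (a genomic mega-cluster read
  out as a shared transcriptional factor) and a detection floor that
  produces near-floor "silenced" signals;
* miRNA->gene interaction tables carrying a prediction-score percentile
  and a CLIP support count;
* pathway databases (GMT-writable) with planted enriched pathways;
* clinical cohorts with negative-binomial miRNA-Seq counts, subtype
  labels, and exponential survival times with a planted hazard ratio
  tied to dichotomized miRNA expression.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import ExpressionStudy
from .enrichment import PathwayDB
from .errors import ConfigError
from .targets import InteractionTable

__all__ = [
    "ClusterSpec",
    "StudyConfig",
    "CohortConfig",
    "ClinicalCohort",
    "generate_expression_study",
    "generate_interaction_table",
    "generate_pathway_db",
    "generate_clinical_cohort",
]

DEFAULT_GROUPS = ("reference", "modelA", "modelB")


@dataclass
class ClusterSpec:
    """A co-regulated feature cluster sharing one shift and one factor.

    members: feature ids belonging to the cluster.
    shift: log2 shift applied to every member in ``group``.
    correlation: target pairwise Pearson correlation of the replicate
        noise among members, induced by a shared Gaussian factor.
    group: group receiving the shift (default: the last group, the
        "overexpressing" model).
    """

    members: list[str]
    shift: float
    correlation: float
    group: str | None = None


@dataclass
class StudyConfig:
    n_features: int = 1000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_replicates: int = 3
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    cluster_spec: ClusterSpec | None = None
    noise_sd: float = 0.3
    floor: float = 0.3
    seed: int = 0
    # per-feature baseline means (e.g. near-floor silenced features)
    baseline_overrides: dict[str, float] = field(default_factory=dict)

    def feature_ids(self) -> list[str]:
        width = len(str(self.n_features))
        return [f"mir{i:0{width}d}" for i in range(self.n_features)]

    def validate(self) -> None:
        if self.n_features < 1:
            raise ConfigError("n_features must be positive")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if len(set(self.groups)) != len(self.groups) or not self.groups:
            raise ConfigError("groups must be distinct and non-empty")
        ids = set(self.feature_ids())
        for fid, grp, _ in self.planted_effects:
            if fid not in ids:
                raise ConfigError(f"planted effect on unknown feature {fid!r}")
            if grp not in self.groups:
                raise ConfigError(f"planted effect in unknown group {grp!r}")
        for fid in self.baseline_overrides:
            if fid not in ids:
                raise ConfigError(f"baseline override for unknown feature {fid!r}")
        if self.cluster_spec is not None:
            cs = self.cluster_spec
            if not set(cs.members) <= ids:
                raise ConfigError("cluster members must be a subset of features")
            if not 0.0 <= cs.correlation <= 1.0:
                raise ConfigError("cluster correlation must lie in [0, 1]")
            if cs.group is not None and cs.group not in self.groups:
                raise ConfigError(f"cluster group {cs.group!r} not in groups")


@dataclass
class CohortConfig:
    n_patients: int = 746
    # proportions follow the PAM50-annotated TCGA breast cohort layout
    subtypes: dict[str, float] = field(
        default_factory=lambda: {
            "LumA": 0.493,
            "LumB": 0.224,
            "Basal": 0.168,
            "Her2": 0.084,
            "Normal": 0.031,
        }
    )
    n_mirnas: int = 50
    library_size_range: tuple[float, float] = (5e5, 2e6)
    planted_survival: list[tuple[str, float, float]] = field(default_factory=list)
    censoring_rate: float = 0.65
    baseline_rate: float = 0.08  # events per year, exponential baseline
    dispersion: float = 0.3  # NB dispersion of miRNA-Seq counts
    expression_sd: float = 1.5  # patient-level log2 expression spread
    seed: int = 0

    def mirna_ids(self) -> list[str]:
        width = len(str(self.n_mirnas))
        return [f"hsa-mir-{i:0{width}d}" for i in range(self.n_mirnas)]

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        if abs(sum(self.subtypes.values()) - 1.0) > 1e-6:
            raise ConfigError("subtype proportions must sum to 1")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigError("censoring_rate must lie in [0, 1)")
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be positive")
        ids = set(self.mirna_ids())
        for mid, hr, q in self.planted_survival:
            if mid not in ids:
                raise ConfigError(f"planted survival on unknown miRNA {mid!r}")
            if hr <= 0:
                raise ConfigError("hazard ratios must be positive")
            if not 0.0 < q < 1.0:
                raise ConfigError("cutpoint quantile must lie in (0, 1)")


@dataclass
class ClinicalCohort:
    """Per-patient miRNA counts plus clinical annotation.

    counts: DataFrame, miRNAs x patients (integer counts).
    clinical: DataFrame indexed by patient with columns
        subtype, time (years), event (0/1).
    library_sizes: total sequencing depth per patient; the simulated
        counts cover only a subset of the miRNome, so the depth is kept
        explicitly rather than recomputed as a column sum.
    """

    counts: pd.DataFrame
    clinical: pd.DataFrame
    library_sizes: pd.Series | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ConfigError("counts must be non-negative")
        if (self.clinical["time"].to_numpy() < 0).any():
            raise ConfigError("follow-up times must be non-negative")
        if not set(self.clinical["event"].unique()) <= {0, 1}:
            raise ConfigError("event indicator must be 0/1")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            self.library_sizes = pd.Series(self.library_sizes).loc[list(self.counts.columns)]
            if (self.library_sizes.to_numpy() <= 0).any():
                raise ConfigError("library sizes must be positive")


def generate_expression_study(config: StudyConfig) -> ExpressionStudy:
    """Simulate a log2 expression study with planted effects.

    Per feature f and sample s in group g:
    ``x_fs = baseline_f + shift(f, g) + noise_fs``, clipped at the
    detection floor.  Cluster members share a per-sample factor so that
    their noise correlates at the configured level (``noise = sqrt(rho) *
    factor_s + sqrt(1-rho) * eps_fs``, both scaled to noise_sd).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    features = config.feature_ids()
    n = config.n_features
    samples, group_of = [], {}
    for g in config.groups:
        for r in range(1, config.n_replicates + 1):
            sid = f"{g}_r{r}"
            samples.append(sid)
            group_of[sid] = g
    m = len(samples)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    shift = np.zeros((n, m))
    fidx = {f: i for i, f in enumerate(features)}
    for fid, mean in config.baseline_overrides.items():
        baseline[fidx[fid]] = mean
    gcols = {g: [j for j, s in enumerate(samples) if group_of[s] == g] for g in config.groups}
    for fid, grp, delta in config.planted_effects:
        shift[fidx[fid], gcols[grp]] += delta

    eps = rng.normal(0.0, 1.0, size=(n, m))
    noise = eps.copy()
    cs = config.cluster_spec
    if cs is not None and cs.members:
        rows = [fidx[f] for f in cs.members]
        factor = rng.normal(0.0, 1.0, size=m)
        rho = cs.correlation
        noise[rows] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps[rows]
        grp = cs.group if cs.group is not None else config.groups[-1]
        shift[np.ix_(rows, gcols[grp])] += cs.shift
    values = baseline[:, None] + shift + config.noise_sd * noise
    values = np.maximum(values, config.floor)
    df = pd.DataFrame(values, index=features, columns=samples)
    groups = pd.Series(group_of)
    return ExpressionStudy(df, groups)


def generate_interaction_table(
    mirnas, genes, density: float, clip_rate: float, seed: int = 0
) -> InteractionTable:
    """Random scored miRNA->gene interaction table.

    Each pair enters independently with probability ``density``; present
    records carry a score percentile uniform on (0, 100] and a CLIP
    support count that is 0 with probability ``1 - clip_rate`` and
    ``1 + Poisson(1)`` otherwise.
    """
    mirnas, genes = list(mirnas), list(genes)
    if not mirnas or not genes:
        raise ConfigError("mirna and gene lists must be non-empty")
    if not 0.0 < density <= 1.0:
        raise ConfigError("density must lie in (0, 1]")
    if not 0.0 <= clip_rate <= 1.0:
        raise ConfigError("clip_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random((len(mirnas), len(genes))) < density
    mi, gi = np.nonzero(keep)
    k = mi.size
    percentile = 100.0 * (1.0 - rng.random(k))  # uniform on (0, 100]
    clip = np.where(rng.random(k) < clip_rate, 1 + rng.poisson(1.0, size=k), 0)
    df = pd.DataFrame(
        {
            "mirna": np.asarray(mirnas, dtype=object)[mi],
            "gene": np.asarray(genes, dtype=object)[gi],
            "percentile": percentile,
            "clip_count": clip.astype(int),
        }
    )
    return InteractionTable(df)


def generate_pathway_db(
    genes,
    n_pathways: int,
    size_range: tuple[int, int],
    planted: list[tuple[str, int, float]] | None = None,
    target_genes=None,
    seed: int = 0,
) -> PathwayDB:
    """Random pathway database with optional planted enrichment.

    Unplanted pathways draw their members uniformly from ``genes`` with
    sizes uniform on ``size_range``.  A planted pathway
    ``(name, size, fraction)`` takes ``round(fraction * size)`` members
    from ``target_genes`` (the designated gene subset it is enriched
    for) and the remainder from the rest of the universe.
    """
    genes = list(genes)
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(genes):
        raise ConfigError(
            f"size_range {size_range} incompatible with universe of {len(genes)} genes"
        )
    rng = np.random.default_rng(seed)
    pathways: dict[str, frozenset] = {}
    planted = planted or []
    tgt = list(target_genes or [])
    for name, size, fraction in planted:
        if size > len(genes):
            raise ConfigError(f"planted pathway {name!r} exceeds the gene universe")
        if not 0.0 <= fraction <= 1.0:
            raise ConfigError("planted fraction must lie in [0, 1]")
        k = int(round(fraction * size))
        if k > len(tgt):
            raise ConfigError(
                f"planted pathway {name!r} needs {k} target genes, have {len(tgt)}"
            )
        members = list(rng.choice(tgt, size=k, replace=False))
        pool = [g for g in genes if g not in set(members)]
        members += list(rng.choice(pool, size=size - k, replace=False))
        pathways[name] = frozenset(members)
    for i in range(n_pathways - len(planted)):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pathways[f"PW{i:04d}"] = frozenset(members.tolist())
    return PathwayDB(pathways, universe=frozenset(genes))


def generate_clinical_cohort(config: CohortConfig) -> ClinicalCohort:
    """Simulate a miRNA-Seq cohort with planted survival effects.

    Patient-level log2 expression of each miRNA varies around a
    miRNA-specific mean; counts are negative-binomial around the implied
    CPM-scaled mean.  Survival is exponential with the baseline rate,
    multiplied by the planted hazard ratio for patients whose underlying
    expression exceeds the planted cutpoint quantile; censoring comes
    from an independent exponential calibrated to the configured rate.
    The planted dichotomy per miRNA is recorded in ``truth``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mirnas = config.mirna_ids()
    n, p = config.n_mirnas, config.n_patients
    patients = [f"pt{i:04d}" for i in range(p)]

    lib = rng.uniform(*config.library_size_range, size=p)
    base_log2cpm = rng.uniform(1.0, 9.0, size=n)
    midx0 = {m: i for i, m in enumerate(mirnas)}
    for mid, _, _ in config.planted_survival:
        # planted miRNAs sit at a readily quantifiable abundance so the
        # dichotomy survives count noise
        base_log2cpm[midx0[mid]] = 6.0
    log2cpm = base_log2cpm[:, None] + rng.normal(0.0, config.expression_sd, size=(n, p))
    mu = np.exp2(log2cpm) * lib[None, :] / 1e6
    # NB with var = mu + dispersion * mu^2
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    labels = list(config.subtypes)
    probs = np.array([config.subtypes[s] for s in labels], dtype=float)
    probs = probs / probs.sum()
    subtype = rng.choice(labels, size=p, p=probs)

    # the planted dichotomy is defined on the *realized* log2CPM (with
    # the true library sizes), so the survival signal is exactly
    # encoded in the data the analyst sees, not in a latent variable
    obs_log2cpm = np.log2((counts + 0.5) / (lib[None, :] + 1.0) * 1e6)
    loghr = np.zeros(p)
    truth: dict[str, dict] = {}
    midx = {m: i for i, m in enumerate(mirnas)}
    for mid, hr, q in config.planted_survival:
        expr = obs_log2cpm[midx[mid]]
        cut = float(np.quantile(expr, q))
        high = expr > cut
        loghr = loghr + np.log(hr) * high
        truth[mid] = {"hr": hr, "quantile": q, "cutpoint_log2cpm": cut, "high": high}

    rate = config.baseline_rate * np.exp(loghr)
    t_event = rng.exponential(1.0 / rate)
    c = config.censoring_rate
    if c > 0:
        # competing exponential calibrated to the cohort's marginal
        # hazard so the realized censored fraction tracks the config
        rate_c = float(rate.mean()) * c / (1.0 - c)
        t_cens = rng.exponential(1.0 / rate_c, size=p)
    else:
        t_cens = np.full(p, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    counts_df = pd.DataFrame(counts, index=mirnas, columns=patients)
    clinical = pd.DataFrame(
        {"subtype": subtype, "time": time, "event": event}, index=pd.Index(patients, name="patient")
    )
    lib_series = pd.Series(np.round(lib).astype(int), index=patients)
    return ClinicalCohort(counts_df, clinical, library_sizes=lib_series, truth=truth)


@dataclass
class PlantedBundle:
    """A complete synthetic input set with known ground truth.

    truth keys: ``sig_a`` / ``sig_b`` (the model-specific miRNA
    signatures the study plants), ``cluster`` (the silenced co-regulated
    mega-cluster, a subset of sig_b), ``shared_pathways`` /
    ``pathways_a`` / ``pathways_b`` (planted enriched pathway names),
    and ``genes_specific_a`` / ``genes_shared`` / ``genes_specific_b``
    (the expected partition of pooled network-regulated genes).
    """

    study: ExpressionStudy
    interactions: InteractionTable
    db: PathwayDB
    truth: dict


def generate_planted_bundle(
    seed: int = 0,
    n_features: int = 200,
    n_sig_a: int = 12,
    n_sig_b: int = 15,
    n_cluster: int = 10,
    n_shared: int = 8,
    n_shared_pathways: int = 11,
    n_pathways_a: int = 8,
    n_pathways_b: int = 10,
    n_null_pathways: int = 20,
    noise_sd: float = 0.3,
) -> PlantedBundle:
    """Expression study + interactions + pathways with planted truth.

    modelA carries ``n_sig_a`` shifted miRNAs (its specific signature),
    modelB carries ``n_sig_b`` including a near-floor silenced
    co-regulated cluster of ``n_cluster`` members that is strongly
    overexpressed in modelB only; ``n_shared`` miRNAs shift in both
    models (the shared "estrogen-independent growth" set).  Signature
    miRNAs target three disjoint gene pools (A-specific / shared /
    B-specific) with guaranteed coverage, so the planted pathways -
    drawn entirely from those pools - are enriched for the respective
    signature targets, while null pathways draw from genes targeted
    only by non-signature miRNAs.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_features))
    features = [f"mir{i:0{width}d}" for i in range(n_features)]
    pos = 0

    def take(k):
        nonlocal pos
        out = features[pos : pos + k]
        pos += k
        return out

    cluster = take(n_cluster)
    sig_b_rest = take(n_sig_b - n_cluster)
    sig_a = take(n_sig_a)
    shared_mirnas = take(n_shared)
    sig_b = cluster + sig_b_rest

    planted: list[tuple[str, str, float]] = []
    for i, f in enumerate(sig_a):
        planted.append((f, "modelA", 2.0 if i % 2 == 0 else -2.0))
    for i, f in enumerate(sig_b_rest):
        planted.append((f, "modelB", 2.5 if i % 2 == 0 else -2.0))
    for i, f in enumerate(shared_mirnas):
        delta = 2.0 if i % 2 == 0 else -2.0
        planted.append((f, "modelA", delta))
        planted.append((f, "modelB", delta))

    config = StudyConfig(
        n_features=n_features,
        baseline_mean=8.0,
        baseline_sd=1.0,
        planted_effects=planted,
        cluster_spec=ClusterSpec(members=cluster, shift=6.0, correlation=0.8, group="modelB"),
        noise_sd=noise_sd,
        seed=seed,
        baseline_overrides={f: 0.8 for f in cluster},  # silenced outside modelB
    )
    study = generate_expression_study(config)

    # gene pools: targeted by sig_a only / both / sig_b only / neither
    def genes(prefix, k):
        return [f"{prefix}{i:03d}" for i in range(k)]

    pool_a, pool_s, pool_b, pool_null = (
        genes("GA", 120),
        genes("GS", 150),
        genes("GB", 180),
        genes("GN", 200),
    )
    other_mirnas = [f"bg_mir{i:02d}" for i in range(40)]

    rows = []

    def cover(mirnas, gene_pool, extra_density=0.15):
        """Round-robin coverage of the pool plus random extra records."""
        for j, g in enumerate(gene_pool):
            rows.append((mirnas[j % len(mirnas)], g))
        extra = rng.random((len(mirnas), len(gene_pool))) < extra_density
        for i, m in enumerate(mirnas):
            for j in np.nonzero(extra[i])[0]:
                rows.append((m, gene_pool[j]))

    cover(sig_a, pool_a + pool_s)
    cover(sig_b, pool_b + pool_s)
    cover(other_mirnas, pool_null, extra_density=0.05)
    uniq = sorted(set(rows))
    df = pd.DataFrame(uniq, columns=["mirna", "gene"])
    df["percentile"] = 50.0 + 50.0 * (1.0 - rng.random(len(df)))  # all pass > 50
    df["clip_count"] = 1 + rng.poisson(1.0, size=len(df))
    # sub-threshold decoys exercising the percentile and CLIP filters
    decoys = pd.DataFrame(
        {
            "mirna": rng.choice(sig_a + sig_b, size=60),
            "gene": rng.choice(pool_null, size=60),
            "percentile": 50.0 * rng.random(60),
            "clip_count": 0,
        }
    )
    table = InteractionTable(
        pd.concat([df, decoys], ignore_index=True).drop_duplicates(["mirna", "gene"])
    )

    pathways: dict[str, frozenset] = {}

    def plant(prefix, count, pool):
        names = []
        for i in range(count):
            size = int(rng.integers(12, 25))
            members = rng.choice(pool, size=size, replace=False)
            name = f"{prefix}{i:02d}"
            pathways[name] = frozenset(members.tolist())
            names.append(name)
        return names

    shared_pathways = plant("PW_SHARED", n_shared_pathways, pool_s)
    pathways_a = plant("PW_A", n_pathways_a, pool_a)
    pathways_b = plant("PW_B", n_pathways_b, pool_b)
    plant("PW_NULL", n_null_pathways, pool_null)
    db = PathwayDB(pathways, universe=frozenset(pool_a + pool_s + pool_b + pool_null))

    union = lambda names: frozenset().union(*(pathways[n] for n in names))
    shared_genes = union(shared_pathways)
    truth = {
        "sig_a": frozenset(sig_a),
        "sig_b": frozenset(sig_b),
        "cluster": frozenset(cluster),
        "shared_mirnas": frozenset(shared_mirnas),
        "shared_pathways": list(shared_pathways),
        "pathways_a": list(pathways_a),
        "pathways_b": list(pathways_b),
        "genes_specific_a": union(pathways_a) - shared_genes,
        "genes_shared": shared_genes,
        "genes_specific_b": union(pathways_b) - shared_genes,
    }
    return PlantedBundle(study=study, interactions=table, db=db, truth=truth)
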