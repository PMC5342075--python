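"""Clinical cohort layer: normalization, co-expression, subtypes, survival.

Covers log2CPM transformation of miRNA-Seq counts, Spearman
co-expression clustering, non-parametric subtype comparisons, and
survival stratification by a maximally selected log-rank cutpoint with
permutation-adjusted inference, Kaplan-Meier curves and a
binary-covariate Cox model (Newton-Raphson on the Breslow partial
likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ContractError, EstimationError

__all__ = [
    "log2cpm",
    "spearman_cluster",
    "subtype_compare",
    "star_tier",
    "km_estimate",
    "logrank",
    "CoxResult",
    "cox_hr_binary",
    "CutpointResult",
    "find_cutpoint",
]

_Z975 = stats.norm.ppf(0.975)


def log2cpm(counts, library_sizes=None):
    """log2 counts-per-million: ``log2((c + 0.5) / (L + 1) * 1e6)``.

    ``library_sizes`` defaults to the per-sample column sums.  Counts
    must be non-negative; the transform is strictly increasing in the
    count at fixed library size.
    """
    counts = pd.DataFrame(counts)
    arr = counts.to_numpy(float)
    if (arr < 0).any():
        raise ContractError("counts must be non-negative")
    if library_sizes is None:
        lib = arr.sum(axis=0)
    else:
        lib = np.asarray(library_sizes, dtype=float)
        if (lib <= 0).any():
            raise ContractError("library sizes must be positive")
    out = np.log2((arr + 0.5) / (lib[None, :] + 1.0) * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def spearman_cluster(expr: pd.DataFrame):
    """Pairwise Spearman rho between rows + complete-linkage ordering.

    Ties receive average ranks.  Constant rows (rho undefined) are
    excluded with a warning and reported.  Returns
    ``(rho DataFrame, linkage, ordered row list, excluded rows)``.
    """
    if expr.shape[1] < 3:
        raise ContractError("need >= 3 patients for correlation clustering")
    sd = expr.std(axis=1, ddof=1)
    excluded = list(expr.index[sd == 0])
    if excluded:
        warnings.warn(f"excluding constant rows from correlation: {excluded}")
    kept = expr.loc[sd > 0]
    if len(kept) == 1:
        rho = np.ones((1, 1))
    elif len(kept) == 2:
        r = float(stats.spearmanr(kept.iloc[0], kept.iloc[1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = stats.spearmanr(kept.to_numpy(float), axis=1).statistic
    rho_df = pd.DataFrame(rho, index=kept.index, columns=kept.index)
    if len(kept) < 2:
        return rho_df, None, list(kept.index), excluded
    d = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(d, 0.0)
    linkage = hierarchy.linkage(squareform((d + d.T) / 2.0, checks=False), method="complete")
    order = [kept.index[i] for i in hierarchy.leaves_list(linkage)]
    return rho_df, linkage, order, excluded


def star_tier(p: float) -> str:
    """Figure-style star tiers: **** <1e-4, *** <1e-3, ** <0.01, * <0.05."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def subtype_compare(expr: pd.DataFrame, labels: pd.Series):
    """Kruskal-Wallis global test + pairwise Wilcoxon rank-sum per row.

    Groups with fewer than 2 patients are excluded with a warning.
    Returns ``(global DataFrame, pairwise DataFrame)``; the pairwise
    table has columns mirna, group1, group2, p, stars (unadjusted
    two-sided P mapped to star tiers).
    """
    labels = pd.Series(labels).loc[list(expr.columns)]
    counts = labels.value_counts()
    keep_groups = sorted(counts.index[counts >= 2])
    dropped = sorted(counts.index[counts < 2])
    if dropped:
        warnings.warn(f"excluding degenerate subtype groups: {dropped}")
    if len(keep_groups) < 2:
        raise ContractError("need >= 2 groups with >= 2 patients each")
    cols = {g: [c for c in expr.columns if labels[c] == g] for g in keep_groups}

    global_rows, pair_rows = [], []
    for mirna, row in expr.iterrows():
        samples = [row[cols[g]].to_numpy(float) for g in keep_groups]
        try:
            kw = stats.kruskal(*samples)
            gp = float(kw.pvalue)
        except ValueError:  # all values identical
            gp = 1.0
        global_rows.append({"mirna": mirna, "kruskal_p": gp, "stars": star_tier(gp)})
        for i, g1 in enumerate(keep_groups):
            for g2 in keep_groups[i + 1 :]:
                mw = stats.mannwhitneyu(
                    row[cols[g1]], row[cols[g2]], alternative="two-sided"
                )
                pp = float(mw.pvalue)
                pair_rows.append(
                    {"mirna": mirna, "group1": g1, "group2": g2, "p": pp,
                     "stars": star_tier(pp)}
                )
    return pd.DataFrame(global_rows).set_index("mirna"), pd.DataFrame(pair_rows)


def _check_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ContractError("times and events must be 1-d arrays of equal length")
    if (t < 0).any():
        raise ContractError("times must be >= 0")
    if not set(np.unique(e)) <= {0, 1}:
        raise ContractError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with columns
    time, n_risk, n_event, survival; ``S(t) = prod (1 - d_i/n_i)`` over
    event times up to t.  All-censored input yields the flat curve 1.
    """
    t, e = _check_surv(times, events)
    if e.sum() == 0:
        warnings.warn("no events observed; survival curve is flat at 1")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    uniq, first = np.unique(t, return_index=True)
    n_risk = len(t) - first
    d = np.add.reduceat(e, first)
    mask = d > 0
    surv = np.cumprod(1.0 - d[mask] / n_risk[mask])
    return pd.DataFrame(
        {"time": uniq[mask], "n_risk": n_risk[mask], "n_event": d[mask], "survival": surv}
    )


def _logrank_scan(times, events, membership):
    """Log-rank score over columns of a membership matrix.

    ``membership`` is (n_subjects x n_splits) boolean: True marks the
    "high" group of that split.  Returns (O_minus_E, V, z) arrays of
    length n_splits, where O-E sums, over distinct event times, the
    observed minus hypergeometric-expected events in the high group and
    V the matching variance; ``z = (O-E)/sqrt(V)``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    Z = np.asarray(membership, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    order = np.argsort(t, kind="mergesort")
    t, e, Z = t[order], e[order], Z[order]
    uniq, first = np.unique(t, return_index=True)
    R = (len(t) - first).astype(float)  # total at risk at each distinct time
    d = np.add.reduceat(e, first).astype(float)  # events at each distinct time
    # at-risk and event counts in the high group, per split
    suffix = np.cumsum(Z[::-1], axis=0)[::-1]
    R1 = suffix[first]
    d1 = np.add.reduceat(e[:, None] * Z, first, axis=0)
    m = d > 0
    R, d, R1, d1 = R[m], d[m], R1[m], d1[m]
    p1 = R1 / R[:, None]
    o_minus_e = (d1 - d[:, None] * p1).sum(axis=0)
    denom = np.maximum(R - 1.0, 1.0)
    vt = d * (R - d) / denom
    V = (vt[:, None] * p1 * (1.0 - p1)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(V > 0, o_minus_e / np.sqrt(V), 0.0)
    return o_minus_e, V, z


def logrank(times_a, events_a, times_b, events_b):
    """Two-group log-rank test: 1-df chi-square statistic and P."""
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ContractError("both groups must be non-empty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    if e.sum() == 0:
        raise EstimationError("no events in either group; log-rank undefined")
    member = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    _, _, z = _logrank_scan(t, e, member[:, None])
    chi2 = float(z[0] ** 2)
    return chi2, float(stats.chi2.sf(chi2, 1))


@dataclass
class CoxResult:
    hr: float
    ci: tuple[float, float]
    p: float
    coef: float
    se: float
    converged: bool


def cox_hr_binary(times, events, group, max_iter: int = 50, tol: float = 1e-10) -> CoxResult:
    """Cox proportional-hazards fit for a single binary covariate.

    Newton-Raphson maximization of the Breslow partial likelihood; Wald
    95% CI and P from the observed information.  Monotone likelihoods
    (complete separation of event order) trigger a warning and a capped
    estimate at |coef| = 15.
    """
    t, e = _check_surv(times, events)
    g = np.asarray(group).astype(bool)
    if g.shape != t.shape:
        raise ContractError("group indicator must match times in length")
    if e.sum() == 0:
        raise EstimationError("no events; hazard ratio not identifiable")
    if e[g].sum() == 0 or e[~g].sum() == 0:
        warnings.warn("one group has no events; estimate is not identifiable")

    order = np.argsort(t, kind="mergesort")
    t, e, z = t[order], e[order], g[order].astype(float)
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first).astype(float)
    suffix1 = np.cumsum(z[::-1])[::-1]
    r1 = suffix1[first]
    r_tot = (len(t) - first).astype(float)
    r0 = r_tot - r1
    s1 = np.add.reduceat(e * z, first)
    m = d > 0
    d, r0, r1, s1 = d[m], r0[m], r1[m], s1[m]

    beta = 0.0
    converged = False
    info = np.nan
    for _ in range(max_iter):
        w = r1 * np.exp(beta)
        denom = r0 + w
        score = s1.sum() - (d * w / denom).sum()
        info = (d * r0 * w / denom**2).sum()
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(beta) > 15.0:
            warnings.warn("diverging Cox estimate (monotone likelihood); capped at |coef|=15")
            beta = float(np.sign(beta) * 15.0)
            break
        if abs(step) < tol:
            converged = True
            break
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - _Z975 * se)), float(np.exp(beta + _Z975 * se)))
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if np.isfinite(se) and se > 0 else 1.0
    return CoxResult(hr=hr, ci=ci, p=p, coef=float(beta), se=se, converged=converged)


@dataclass
class CutpointResult:
    threshold: float
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    p_adjusted: float | None
    cox: CoxResult
    candidates: pd.DataFrame
    n_perm: int


def find_cutpoint(
    times,
    events,
    expression,
    quantile_window: tuple[float, float] = (0.1, 0.9),
    n_perm: int = 999,
    seed: int | None = None,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint with permutation adjustment.

    Candidate thresholds are the observed expression values whose
    empirical CDF lies strictly inside ``quantile_window`` (patients
    with expression above the threshold form the "high" group).  The
    standardized log-rank score is evaluated at every candidate; the
    threshold maximizing |z| is selected.  Because the maximum over many
    candidate splits inflates the naive minimum P, a selection-adjusted
    P is computed by permuting expression against outcomes ``n_perm``
    times and re-maximizing:
    ``p_adj = (1 + #{max_b >= max_obs}) / (n_perm + 1)``.
    ``n_perm=0`` skips the adjustment (p_adjusted is None).

    Also reports the log-rank test and Cox hazard ratio (high vs low)
    at the chosen split.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(expression, dtype=float)
    if x.shape != t.shape:
        raise ContractError("expression must match times in length")
    if len(t) < 20:
        raise ContractError("need >= 20 patients for cutpoint selection")
    if e.sum() == 0:
        raise EstimationError("no events; cutpoint selection undefined")

    n = len(x)
    lo, hi = quantile_window
    sorted_x = np.sort(x)
    cdf = np.searchsorted(sorted_x, x, side="right") / n
    cand = np.unique(x[(cdf >= lo) & (cdf <= hi) & (x < sorted_x[-1])])
    if cand.size == 0:
        raise EstimationError(
            f"no admissible threshold inside the quantile window {quantile_window}"
        )
    member = x[:, None] > cand[None, :]
    _, _, zscores = _logrank_scan(t, e, member)
    absz = np.abs(zscores)
    best = int(np.argmax(absz))  # ties: smallest threshold
    threshold = float(cand[best])
    max_obs = float(absz[best])

    p_adj = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        extreme = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            _, _, zp = _logrank_scan(t, e, member[perm])
            if np.abs(zp).max() >= max_obs:
                extreme += 1
        p_adj = (1.0 + extreme) / (n_perm + 1.0)

    high = x > threshold
    chi2, lr_p = logrank(t[high], e[high], t[~high], e[~high])
    cox = cox_hr_binary(t, e, high)
    candidates = pd.DataFrame({"threshold": cand, "z": zscores})
    return CutpointResult(
        threshold=threshold,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        logrank_chi2=chi2,
        logrank_p=lr_p,
        p_adjusted=p_adj,
        cox=cox,
        candidates=candidates,
        n_perm=n_perm,
    )
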