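"""Moderated differential expression between replicate groups.

Implements the empirical-Bayes variance-shrinkage t-test for log2-scale
expression matrices with a small number of replicates per group, followed
by step-down Holm adjustment and fold-change/significance classification.

The model places a scaled inverse-chi-square prior on the per-feature
residual variance: ``1/sigma_g^2 ~ chi^2_{d0} / (d0 * s0^2)``.  Given the
observed residual variances ``s_g^2`` on ``d_g`` degrees of freedom, the
posterior mean variance

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces ``s_g^2`` in the two-sample t statistic, which then follows a t
reference with ``d0 + d_g`` degrees of freedom under the null.  The prior
hyperparameters ``(d0, s0^2)`` are estimated from all features by the
method of moments on log residual variances (digamma/trigamma moment
equations, with the trigamma function inverted by Newton iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ContractError, EstimationError

__all__ = [
    "ExpressionStudy",
    "DEResult",
    "fold_change",
    "fit_moderated_t",
    "holm_adjust",
    "classify_de",
]


@dataclass
class ExpressionStudy:
    """A log2-scale expression matrix (features x samples) with group labels.

    Parameters
    ----------
    values
        DataFrame of log2 signals, one row per feature, one column per sample.
    groups
        Series mapping each sample id (index) to its group name.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ContractError(f"samples without group assignment: {missing}")
        self.groups = self.groups.loc[list(self.values.columns)]
        if self.values.isna().any().any():
            raise ContractError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ContractError(f"duplicate feature ids: {dups}")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise KeyError(
                f"unknown group {group!r}; available: {sorted(set(self.groups))}"
            )
        return list(self.groups.index[self.groups == group])

    def subset_groups(self, keep: list[str]) -> "ExpressionStudy":
        """Restrict to samples belonging to the given groups."""
        cols = [s for s in self.values.columns if self.groups[s] in set(keep)]
        return ExpressionStudy(self.values[cols], self.groups.loc[cols])


@dataclass
class DEResult:
    """Per-feature contrast statistics for groupA versus groupB.

    ``table`` columns: ``mean_<group>`` for every group in the study,
    ``log2fc``, ``fc``, ``t_ord``, ``t_mod``, ``p_raw``, ``p_holm`` and
    (after :func:`classify_de`) ``class``.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    prior_df: float
    prior_var: float
    residual_df: float
    fc_threshold: float | None = None
    p_threshold: float | None = None
    counts: dict = field(default_factory=dict)

    def significant(self) -> pd.Index:
        """Features classified up or down (requires classify_de)."""
        if "class" not in self.table:
            raise ContractError("run classify_de before requesting significant features")
        return self.table.index[self.table["class"] != "not-significant"]


def fold_change(study: ExpressionStudy, group_a: str, group_b: str) -> pd.DataFrame:
    """Per-feature log2 fold change and linear fold change, A versus B.

    ``log2fc = mean(A) - mean(B)`` on the log2 scale; ``fc = 2**log2fc``.
    Swapping the groups maps ``fc`` to ``1/fc``.
    """
    mean_a = study.values[study.samples_of(group_a)].mean(axis=1)
    mean_b = study.values[study.samples_of(group_b)].mean(axis=1)
    log2fc = mean_a - mean_b
    return pd.DataFrame({"log2fc": log2fc, "fc": np.exp2(log2fc)})


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic starting value x ~ 0.5 + 1/y and the update in
    terms of the tetragamma function, which converges monotonically.
    """
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y).copy()
    out = np.empty_like(y)
    tiny = y < 1e-6
    huge = y > 1e7
    out[tiny] = 1.0 / y[tiny]
    out[huge] = 1.0 / np.sqrt(y[huge])
    mid = ~(tiny | huge)
    x = 0.5 + 1.0 / y[mid]
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y[mid]) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    out[mid] = x
    return float(out[0]) if scalar else out


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Moment equations on z = log(s2): E[z] and Var[z] involve digamma and
    trigamma at d/2 and d0/2.  Returns ``d0 = inf`` when the excess
    dispersion of log variances is non-positive (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise EstimationError(
            "all features have zero residual variance; the variance prior "
            "cannot be estimated - check for constant/duplicated samples"
        )
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(e.mean())
    n = e.size
    if n < 2:
        return 0.0, float(np.exp(ebar))
    evar = float(((e - ebar) ** 2).sum() / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(evar)
    if d0 > 1e6:
        return np.inf, float(np.exp(ebar))
    s02 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s02


def fit_moderated_t(
    study: ExpressionStudy,
    group_a: str,
    group_b: str,
    shared_variance: bool = False,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> DEResult:
    """Empirical-Bayes moderated two-sample t-test, A versus B.

    Parameters
    ----------
    shared_variance
        When True, the residual variance pools replicates of *all* groups
        in the study (one-way layout), not just the two contrasted ones.
    prior_df, prior_var
        Override the estimated hyperparameters (``prior_df=0`` gives the
        ordinary pooled t; ``prior_df=np.inf`` with a fixed ``prior_var``
        gives the complete-shrinkage statistic).

    Raises
    ------
    ContractError
        If either group has fewer than 2 replicates.
    EstimationError
        If every feature has zero residual variance.
    """
    sa = study.samples_of(group_a)
    sb = study.samples_of(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ContractError(
            f"need >=2 replicates per group; got {len(sa)} in {group_a!r} "
            f"and {len(sb)} in {group_b!r}"
        )
    x = study.values[sa].to_numpy(float)
    y = study.values[sb].to_numpy(float)
    na, nb = x.shape[1], y.shape[1]
    log2fc = x.mean(axis=1) - y.mean(axis=1)

    if shared_variance:
        ss = 0.0
        df = 0
        for g in study.group_names:
            vg = study.values[study.samples_of(g)].to_numpy(float)
            if vg.shape[1] >= 2:
                ss = ss + ((vg - vg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                df += vg.shape[1] - 1
    else:
        ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (y - y.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        df = na + nb - 2
    s2 = ss / df

    if prior_df is None:
        if len(log2fc) < 2:
            # hyperparameter fit impossible from one feature: no shrinkage
            d0, s02 = 0.0, float(s2[0]) if s2.size else 0.0
        else:
            d0, s02 = estimate_prior(s2, df)
    else:
        d0 = float(prior_df)
        if d0 > 0 and prior_var is None:
            raise ContractError("prior_var must be given when prior_df is forced > 0")
        s02 = float(prior_var) if prior_var is not None else 0.0

    stderr_scale = np.sqrt(1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = log2fc / (np.sqrt(s2) * stderr_scale)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / (np.sqrt(s2_post) * stderr_scale)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    cols = {}
    for g in study.group_names:
        cols[f"mean_{g}"] = study.values[study.samples_of(g)].mean(axis=1)
    cols["log2fc"] = log2fc
    cols["fc"] = np.exp2(log2fc)
    cols["t_ord"] = t_ord
    cols["t_mod"] = t_mod
    cols["p_raw"] = p_raw
    cols["p_holm"] = holm_adjust(np.nan_to_num(p_raw, nan=1.0))
    table = pd.DataFrame(cols, index=study.features)
    return DEResult(
        table=table,
        group_a=group_a,
        group_b=group_b,
        prior_df=d0,
        prior_var=s02,
        residual_df=float(df),
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm family-wise error adjustment.

    Sorting ascending (ties broken by original index for determinism),
    ``adj_(i) = min(1, max_{j<=i} (m-j+1) * p_(j))``, returned in the
    original order.  Dominates Bonferroni elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    mults = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(mults))
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def classify_de(
    result: DEResult,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    use_adjusted: bool = True,
) -> DEResult:
    """Label features up / down / not-significant and count them.

    A feature is ``up`` when FC > fc_threshold and P < p_threshold,
    ``down`` when FC < 1/fc_threshold and P < p_threshold.  Inequalities
    are strict: FC exactly at the threshold is not significant.  P is the
    Holm-adjusted column when ``use_adjusted`` else the raw column.
    """
    if not fc_threshold > 1:
        raise ContractError("fc_threshold must exceed 1")
    if not 0 < p_threshold < 1:
        raise ContractError("p_threshold must lie in (0, 1)")
    t = result.table
    p = t["p_holm"] if use_adjusted else t["p_raw"]
    up = (t["fc"] > fc_threshold) & (p < p_threshold)
    down = (t["fc"] < 1.0 / fc_threshold) & (p < p_threshold)
    labels = np.where(up, "up", np.where(down, "down", "not-significant"))
    t = t.copy()
    t["class"] = labels
    result.table = t
    result.fc_threshold = fc_threshold
    result.p_threshold = p_threshold
    result.counts = {"n_up": int(up.sum()), "n_down": int(down.sum())}
    return result
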