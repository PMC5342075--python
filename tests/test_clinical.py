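"""log2CPM, co-expression, subtype tests, KM/log-rank/Cox, cutpoints."""

import numpy as np
import pandas as pd
import pytest

from mirpath.clinical import (
    cox_hr_binary,
    find_cutpoint,
    km_estimate,
    log2cpm,
    logrank,
    spearman_cluster,
    star_tier,
    subtype_compare,
)
from mirpath.errors import ContractError, EstimationError
from mirpath.simulate import CohortConfig, generate_clinical_cohort


class TestLog2CPM:
    def test_closed_form_and_monotonicity(self):
        m = pd.DataFrame({"s": [0, 1, 2]})
        out = log2cpm(m, [1_000_000])
        assert out.iloc[0, 0] == pytest.approx(-1.0, abs=1e-4)
        assert out["s"].is_monotonic_increasing

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(20, 30)))
        lib = rng.uniform(1e5, 1e6, size=30)
        out = log2cpm(counts, lib)
        expected = np.log2((counts.to_numpy() + 0.5) / (lib[None, :] + 1.0) * 1e6)
        np.testing.assert_allclose(out.to_numpy(), expected, rtol=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ContractError):
            log2cpm(pd.DataFrame({"s": [-1]}), [100])


class TestSpearman:
    def test_self_and_antitone_correlations(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, -(x**3)], index=["a", "b"])
        rho, _, order, excluded = spearman_cluster(expr)
        assert rho.loc["a", "a"] == 1.0
        assert rho.loc["a", "b"] == pytest.approx(-1.0)
        assert not excluded

    def test_constant_row_excluded_with_warning(self):
        expr = pd.DataFrame([[1.0, 2, 3, 4], [5.0, 5, 5, 5]], index=["a", "b"])
        with pytest.warns(UserWarning):
            rho, _, _, excluded = spearman_cluster(expr)
        assert excluded == ["b"]
        assert list(rho.index) == ["a"]

    def test_planted_correlated_block_clusters_together(self):
        """Shared-factor block: intra-block rho exceeds inter-block."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            factor = rng.normal(size=50)
            block = factor + 0.6 * rng.normal(size=(5, 50))
            rest = rng.normal(size=(5, 50))
            expr = pd.DataFrame(np.vstack([block, rest]))
            rho, _, _, _ = spearman_cluster(expr)
            r = rho.to_numpy()
            intra = r[:5, :5][np.triu_indices(5, 1)]
            inter = r[:5, 5:].ravel()
            hits += np.median(intra) > np.median(inter)
        assert hits >= 95


class TestSubtypes:
    def test_star_tier_mapping(self):
        assert star_tier(0.02) == "*"
        assert star_tier(0.0005) == "***"
        assert star_tier(5e-5) == "****"
        assert star_tier(0.2) == "ns"

    def test_null_calibration_of_global_test(self):
        """Label permutations of one sample: ~5% rejections at alpha=0.05."""
        rng = np.random.default_rng(1)
        n = 90
        expr = pd.DataFrame(rng.normal(size=(500, n)),
                            columns=[f"p{i}" for i in range(n)])
        labels = pd.Series(
            rng.permutation(["A"] * 30 + ["B"] * 30 + ["C"] * 30), index=expr.columns
        )
        global_df, _ = subtype_compare(expr, labels)
        rate = (global_df["kruskal_p"] < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / 500)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_large_shift_reaches_four_stars(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, size=50)
            b = rng.normal(3, 1, size=50)
            expr = pd.DataFrame([np.concatenate([a, b])],
                                columns=[f"p{i}" for i in range(100)])
            labels = pd.Series(["A"] * 50 + ["B"] * 50, index=expr.columns)
            _, pair = subtype_compare(expr, labels)
            hits += pair["stars"].iloc[0] == "****"
        assert hits >= 95

    def test_degenerate_group_dropped(self):
        expr = pd.DataFrame([[1.0, 2, 3, 4, 5]], columns=list("abcde"))
        labels = pd.Series(["X", "X", "Y", "Y", "Z"], index=expr.columns)
        with pytest.warns(UserWarning):
            global_df, pair = subtype_compare(expr, labels)
        assert set(pair[["group1", "group2"]].to_numpy().ravel()) == {"X", "Y"}


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        with pytest.warns(UserWarning):
            km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.empty  # no event rows; curve stays at 1

    def test_hand_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(km["n_risk"], [3, 2, 1])

    def test_monotone_within_unit_interval_and_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = rng.exponential(5, size=80)
        e = rng.integers(0, 2, size=80)
        km = km_estimate(t, e)
        s = km["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all() and (s >= 0).all() and (s <= 1).all()
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_.loc[km["time"], "KM_estimate"].to_numpy()
        np.testing.assert_allclose(s, ref, atol=1e-10)


def exponential_cohort(rng, n, hr, frac_high=0.5, censor_rate=0.05):
    high = rng.random(n) < frac_high
    t_event = rng.exponential(1.0 / (0.1 * np.where(high, hr, 1.0)))
    t_cens = rng.exponential(1.0 / censor_rate, size=n)
    return np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int), high


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_small_instance_matches_risk_set_enumeration(self):
        """O-E assembled by hand over every distinct event time."""
        ta, ea = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 0])
        tb, eb = np.array([2.0, 4.0, 6.0]), np.array([1, 1, 1])
        t = np.concatenate([ta, tb])
        e = np.concatenate([ea, eb])
        grp = np.array([1, 1, 1, 0, 0, 0])
        o_minus_e = 0.0
        var = 0.0
        for tt in sorted(t[e == 1]):
            at_risk = t >= tt
            d = int(((t == tt) & (e == 1)).sum())
            r = int(at_risk.sum())
            r1 = int((at_risk & (grp == 1)).sum())
            d1 = int(((t == tt) & (e == 1) & (grp == 1)).sum())
            o_minus_e += d1 - d * r1 / r
            if r > 1:
                var += d * (r - d) / (r - 1) * (r1 / r) * (1 - r1 / r)
        chi2, _ = logrank(ta, ea, tb, eb)
        assert chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-12)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(3)
        for _ in range(10):
            t, e, high = exponential_cohort(rng, 60, hr=2.0)
            chi2, p = logrank(t[high], e[high], t[~high], e[~high])
            ref = logrank_test(t[high], t[~high], e[high], e[~high])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
            assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_power_under_planted_hazard(self):
        """HR 3 with 350 per group: median P well below 0.001."""
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t, e, high = exponential_cohort(rng, 700, hr=3.0)
            pvals.append(logrank(t[high], e[high], t[~high], e[~high])[1])
        assert np.median(pvals) < 0.001

    def test_no_events_is_an_error(self):
        with pytest.raises(EstimationError):
            logrank([1.0], [0], [2.0], [0])


class TestCox:
    def test_label_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(4)
        t, e, high = exponential_cohort(rng, 100, hr=2.5)
        a = cox_hr_binary(t, e, high)
        b = cox_hr_binary(t, e, ~high)
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-8)

    def test_tiny_instance_matches_grid_search_oracle(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 1, 1])
        z = np.array([1, 0, 1, 0, 1])

        def neg_partial_loglik(beta):
            ll = 0.0
            for tt in t[e == 1]:
                at_risk = t >= tt
                i = int(np.nonzero(t == tt)[0][0])
                ll += beta * z[i] - np.log(np.sum(np.exp(beta * z[at_risk])))
            return -ll

        grid = np.arange(-5, 5, 1e-3)
        best = grid[np.argmin([neg_partial_loglik(b) for b in grid])]
        res = cox_hr_binary(t, e, z)
        assert res.coef == pytest.approx(best, abs=1e-3)

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        t, e, high = exponential_cohort(rng, 150, hr=2.0)
        df = pd.DataFrame({"t": t, "e": e, "z": high.astype(int)})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        res = cox_hr_binary(t, e, high)
        assert res.coef == pytest.approx(cph.params_["z"], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_["z"], abs=1e-6)

    def test_direction_agrees_with_logrank(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            t, e, high = exponential_cohort(rng, 80, hr=rng.uniform(0.3, 3.0))
            res = cox_hr_binary(t, e, high)
            from mirpath.clinical import _logrank_scan

            o_minus_e, _, _ = _logrank_scan(t, e, high[:, None].astype(float))
            assert (res.hr > 1) == (o_minus_e[0] > 0) or res.hr == pytest.approx(1.0)

    def test_separation_warns_and_caps(self):
        t = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        e = np.ones(6, dtype=int)
        z = np.array([1, 1, 1, 0, 0, 0])
        with pytest.warns(UserWarning):
            res = cox_hr_binary(t, e, z)
        assert abs(res.coef) == 15.0


class TestCutpoint:
    def test_maximizer_matches_exhaustive_split_scan(self):
        """n=25: the selected split maximizes the log-rank chi-square
        over every admissible dichotomy, evaluated independently."""
        rng = np.random.default_rng(7)
        t = rng.exponential(5, size=25)
        e = rng.integers(0, 2, size=25)
        e[0] = 1
        x = rng.normal(size=25)
        res = find_cutpoint(t, e, x, n_perm=0)
        lo, hi = np.quantile(x, [0.1, 0.9])
        best_chi2, best_thr = -1.0, None
        for thr in np.sort(x):
            frac = (x <= thr).mean()
            if not (0.1 <= frac) or thr >= x.max() or frac > 0.9 + 1e-12:
                continue
            cdf_ok = (np.searchsorted(np.sort(x), thr, side="right") / 25)
            if not (0.1 <= cdf_ok <= 0.9):
                continue
            high = x > thr
            chi2, _ = logrank(t[high], e[high], t[~high], e[~high])
            if chi2 > best_chi2:
                best_chi2, best_thr = chi2, thr
        assert res.threshold == pytest.approx(best_thr)
        assert res.logrank_chi2 == pytest.approx(best_chi2, rel=1e-10)

    def test_selection_adjusted_p_calibrated_naive_p_anticonservative(self):
        """Expression independent of survival: the permutation-adjusted P
        rejects at the nominal rate while the naive minimum-P log-rank at
        the selected split grossly over-rejects."""
        adj_rej = naive_rej = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            t = rng.exponential(8, size=100)
            c = rng.exponential(20, size=100)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            x = rng.normal(size=100)
            res = find_cutpoint(time, event, x, n_perm=199, seed=seed)
            adj_rej += res.p_adjusted <= 0.05
            naive_rej += res.logrank_p <= 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_seeds)
        assert 0.05 - half <= adj_rej / n_seeds <= 0.05 + half
        assert naive_rej / n_seeds > 0.05 + half

    def test_planted_cutpoint_recovered(self):
        """Planted 40th-percentile dichotomy with HR 3: threshold found
        within 10 percentile points in >=80/100 cohorts."""
        hits = 0
        for seed in range(100):
            co = generate_clinical_cohort(
                CohortConfig(
                    n_patients=400,
                    n_mirnas=5,
                    seed=seed,
                    planted_survival=[("hsa-mir-2", 3.0, 0.4)],
                    censoring_rate=0.4,
                )
            )
            expr = log2cpm(co.counts, co.library_sizes).loc["hsa-mir-2"].to_numpy()
            res = find_cutpoint(
                co.clinical["time"].to_numpy(),
                co.clinical["event"].to_numpy(),
                expr,
                n_perm=0,
            )
            hits += abs((expr <= res.threshold).mean() - 0.4) <= 0.10
        assert hits >= 80

    def test_contracts(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ContractError):
            find_cutpoint(rng.exponential(size=10), np.ones(10, int), rng.normal(size=10))
        with pytest.raises(EstimationError):
            find_cutpoint(
                rng.exponential(size=30), np.zeros(30, int), rng.normal(size=30)
            )


class TestPooledCurveSanity:
    def test_pooled_km_lies_between_group_curves(self):
        rng = np.random.default_rng(9)
        t, e, high = exponential_cohort(rng, 200, hr=4.0, censor_rate=0.01)
        km_all = km_estimate(t, e)
        km_hi = km_estimate(t[high], e[high])
        km_lo = km_estimate(t[~high], e[~high])

        def at(km, tt):
            s = km[km["time"] <= tt]["survival"]
            return 1.0 if s.empty else s.iloc[-1]

        mid = np.median(t)
        lo_v, hi_v = sorted([at(km_hi, mid), at(km_lo, mid)])
        assert lo_v - 1e-9 <= at(km_all, mid) <= hi_v + 1e-9
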