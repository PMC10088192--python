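import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import qmristats as q
from qmristats.inference import InferenceError, build_design
from qmristats.phantom import simulate_observation_table


def _mixed_table(seed=0, n_per_group=6, pixels=21, intercept_sd=50.0, residual_sd=100.0, effects=None):
    """Pixel table with a shared per-animal intercept; optional dict
    {(state, condition, region): shift} of mean effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in ("control", "tumor"):
        for c in ("fed", "fasted"):
            for i in range(n_per_group):
                aid = f"{s}-{c}-{i}"
                u = intercept_sd * rng.standard_normal()
                for r in ("cortex", "hippocampus", "hypothalamus", "thalamus"):
                    mu = 1500.0 + (effects or {}).get((s, c, r), 0.0)
                    for j, v in enumerate(mu + u + residual_sd * rng.standard_normal(pixels)):
                        rows.append(
                            dict(value=v, parameter="T1", animal_id=aid, state=s, condition=c, region=r, voxel_index=j)
                        )
    return pd.DataFrame(rows)


class TestDesign:
    def test_sixteen_columns_for_full_factorial(self):
        table = _mixed_table(n_per_group=1, pixels=1)
        x, design = build_design(table)
        assert x.shape[1] == 16
        assert np.linalg.matrix_rank(x) == 16

    def test_cell_vector_reproduces_cell_mean(self):
        """In a saturated model the cell vector times beta equals the
        cell sample mean exactly (OLS on a balanced table)."""
        table = _mixed_table(seed=5, n_per_group=2, pixels=3)
        res = q.fit_gee(table, working_correlation="independence")
        for (s, c, r), grp in table.groupby(["state", "condition", "region"]):
            v = res.design.cell_vector(s, c, r)
            assert v @ res.params.to_numpy() == pytest.approx(grp["value"].mean(), rel=1e-9)

    def test_missing_cell_rejected(self):
        table = _mixed_table(n_per_group=1, pixels=2)
        table = table[~((table.state == "tumor") & (table.condition == "fasted"))]
        with pytest.raises(InferenceError, match="rank-deficient"):
            build_design(table)


class TestGEE:
    def test_one_pixel_per_animal_equals_ols(self):
        """With one observation per cluster and independence working
        correlation, GEE coefficients equal the OLS closed form."""
        table = _mixed_table(seed=2, n_per_group=2, pixels=1)
        table = table.groupby(["animal_id", "region"], as_index=False).first()
        # one row per animal: keep only cortex
        table = table[table.region == "cortex"]
        # need all cells; cortex-only table has 2x2 cells -> 4 params
        res = q.fit_gee(table, working_correlation="independence")
        x, _ = build_design(table)
        beta_ols = np.linalg.lstsq(x, table["value"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), beta_ols, rtol=1e-8)

    def test_matches_statsmodels_gee(self):
        """Independent oracle: statsmodels GEE with exchangeable
        covariance on the same table (coefficients, robust SEs, alpha
        and dispersion)."""
        sm = pytest.importorskip("statsmodels.api")
        import statsmodels.formula.api as smf

        table = _mixed_table(seed=3)
        res = q.fit_gee(table)
        f = "value ~ C(state, Treatment('control'))*C(condition, Treatment('fed'))*C(region, Treatment('cortex'))"
        oracle = smf.gee(
            f, groups="animal_id", data=table, cov_struct=sm.cov_struct.Exchangeable()
        ).fit()
        np.testing.assert_allclose(res.params.to_numpy(), oracle.params.to_numpy(), rtol=1e-7, atol=1e-8)
        np.testing.assert_allclose(np.sqrt(np.diag(res.cov_robust)), oracle.bse.to_numpy(), rtol=1e-6)
        assert res.alpha == pytest.approx(float(oracle.cov_struct.dep_params), rel=1e-6)
        assert res.scale == pytest.approx(float(oracle.scale), rel=1e-6)

    def test_positive_intraclass_correlation_detected(self):
        res = q.fit_gee(_mixed_table(seed=4, intercept_sd=80.0, residual_sd=80.0))
        # true ICC = 0.5; moment estimate should be clearly positive
        assert res.alpha > 0.2
        assert res.converged

    def test_sandwich_psd_and_symmetric(self):
        res = q.fit_gee(_mixed_table(seed=6))
        np.testing.assert_allclose(res.cov_robust, res.cov_robust.T)
        assert np.all(np.linalg.eigvalsh(res.cov_robust) > -1e-12)

    def test_robust_approaches_naive_with_many_independent_clusters(self):
        """With correctly specified working correlation the sandwich
        SEs converge to the model-based SEs as clusters grow."""
        table = _mixed_table(seed=7, n_per_group=60, pixels=4)
        res = q.fit_gee(table)
        ratio = np.sqrt(np.diag(res.cov_robust)) / np.sqrt(np.diag(res.cov_naive))
        assert np.all(np.abs(ratio - 1) < 0.25)
        assert np.abs(np.median(ratio) - 1) < 0.1

    def test_exchangeable_ci_coverage_beats_ols_naive(self):
        """At ICC 0.3 the exchangeable-GEE CI for the state effect
        covers the truth near-nominally while independence-OLS naive
        SEs undercover badly (ignoring within-animal correlation)."""
        hits_gee, hits_ols = 0, 0
        n_rep = 120
        for rep in range(n_rep):
            # intercept_sd chosen so ICC = 60^2/(60^2+92^2) ~ 0.30;
            # 20 animals/group so the z-based interval is appropriate
            table = _mixed_table(seed=1000 + rep, n_per_group=20, pixels=5, intercept_sd=60.0, residual_sd=92.0)
            res = q.fit_gee(table)
            i = list(res.params.index).index("state[tumor]")
            se = np.sqrt(res.cov_naive[i, i])
            hits_gee += abs(res.params.iloc[i]) < 1.96 * se
            ols = q.fit_gee(table, working_correlation="independence")
            # independence naive covariance is the OLS covariance
            se_ols = np.sqrt(ols.cov_naive[i, i])
            hits_ols += abs(ols.params.iloc[i]) < 1.96 * se_ols
        assert 0.92 <= hits_gee / n_rep <= 0.99
        assert hits_ols / n_rep < 0.90

    def test_effect_recovery(self):
        """A -150 ms tumor shift in the cortex is recovered by the
        state coefficient without material bias (40 replicates)."""
        effects = {("tumor", c, "cortex"): -150.0 for c in ("fed", "fasted")}
        est = []
        for rep in range(40):
            res = q.fit_gee(_mixed_table(seed=2000 + rep, effects=effects))
            est.append(res.params["state[tumor]"])
        assert np.mean(est) == pytest.approx(-150.0, rel=0.10)

    def test_too_few_clusters_rejected(self):
        table = _mixed_table(n_per_group=1, pixels=2)
        table = table[table.animal_id == table.animal_id.iloc[0]]
        with pytest.raises(InferenceError, match="clusters"):
            q.fit_gee(table)


class TestContrasts:
    def test_zero_contrast(self):
        res = q.fit_gee(_mixed_table(seed=8))
        c = q.pairwise_contrast(res, "state", "control", "control", condition="fed", region="cortex")
        assert c.estimate == 0.0 and c.p == 1.0

    def test_contrast_equals_cell_mean_difference(self):
        """Saturated model: the state contrast equals the difference of
        the two cell sample means (balanced independence fit)."""
        table = _mixed_table(seed=9, n_per_group=2, pixels=4)
        res = q.fit_gee(table, working_correlation="independence")
        c = q.pairwise_contrast(res, "state", "control", "tumor", condition="fed", region="thalamus")
        cells = table.groupby(["state", "condition", "region"])["value"].mean()
        want = cells[("tumor", "fed", "thalamus")] - cells[("control", "fed", "thalamus")]
        assert c.estimate == pytest.approx(want, rel=1e-8)

    def test_detects_injected_cortex_effect(self):
        effects = {("tumor", c, "cortex"): -150.0 for c in ("fed", "fasted")}
        res = q.fit_gee(_mixed_table(seed=10, effects=effects))
        c = q.pairwise_contrast(res, "state", "control", "tumor", condition="fed", region="cortex")
        assert c.estimate < 0 and c.p < 0.05


class TestHolmSidak:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(q.holm_sidak_adjust([0.02]), [0.02])

    def test_worked_example(self):
        adj = q.holm_sidak_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[0] == pytest.approx(0.0199, abs=1e-4)
        assert adj[1] == pytest.approx(0.04)

    def test_matches_statsmodels(self):
        multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(size=12)
        np.testing.assert_allclose(q.holm_sidak_adjust(p), multipletests(p, method="holm-sidak")[1], rtol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_adjusted_at_least_raw_and_order_invariant(self, p):
        p = np.asarray(p)
        adj = q.holm_sidak_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(q.holm_sidak_adjust(p[perm]), adj[perm], rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            q.holm_sidak_adjust([0.5, 1.5])


class TestTTests:
    def test_identical_groups(self):
        t, _, p = q.unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_welch_matches_scipy(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]
        t, df, p = q.unpaired_ttest(a, b)
        oracle = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(oracle.statistic) and p == pytest.approx(oracle.pvalue)
        # balanced equal-variance case: Welch df equals pooled df
        assert df == pytest.approx(6.0)

    def test_constant_equal_groups(self):
        t, _, p = q.unpaired_ttest([5.0, 5.0], [5.0, 5.0])
        assert t == 0.0 and p == 1.0

    def test_constant_different_groups(self):
        t, _, p = q.unpaired_ttest([5.0, 5.0], [7.0, 7.0])
        assert p == 0.0 and np.isinf(t)

    def test_physiology_family_adjustment(self):
        """Body-weight-style endpoint: four comparisons with Holm-Šídák
        correction; adjusted never below raw."""
        rng = np.random.default_rng(1)
        rows = []
        for s, c, mu in [("control", "fed", 242.0), ("control", "fasted", 231.0), ("tumor", "fed", 282.0), ("tumor", "fasted", 271.0)]:
            for _ in range(6):
                rows.append({"state": s, "condition": c, "weight": mu + rng.normal(0, 8)})
        out = q.physiology_ttests(pd.DataFrame(rows), "weight")
        assert len(out) == 4
        assert np.all(out["p_adjusted"] >= out["p"] - 1e-15)
        assert (out["method"] == "holm-sidak").all()
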