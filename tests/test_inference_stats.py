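"""Mixed ANOVA, partial correlations, FDR and asymmetry tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neomode import inference_stats as infs
from conftest import make_edge_cohort


def _long_table(y, groups, subjects=None):
    """(N, 2) state values + group labels -> long-format frame."""
    n = len(y)
    subjects = subjects or [f"s{i}" for i in range(n)]
    rows = []
    for i in range(n):
        for k, state in enumerate(("AS", "QS")):
            rows.append({"subject": subjects[i], "state": state,
                         "group": groups[i], "value": y[i][k]})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_states_give_zero_within_F(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=10)
        y = np.column_stack([vals, vals])
        tab = infs.mixed_anova(_long_table(y, ["EP"] * 5 + ["HC"] * 5))
        assert tab.within.F == 0.0

    def test_reference_design_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(94, 2))
        tab = infs.mixed_anova(_long_table(y, ["EP"] * 42 + ["HC"] * 52))
        assert tab.within.df_den == 92          # (94 - 2)(2 - 1)
        assert tab.between.df_den == 92
        assert tab.interaction.df_den == 92

    def test_balanced_toy_table_matches_hand_computed_sums_of_squares(self):
        # 2 groups x 2 subjects x 2 states, worked by hand:
        # EP: (1, 3), (2, 4); HC: (5, 5), (6, 8)
        y = np.array([[1., 3.], [2., 4.], [5., 5.], [6., 8.]])
        tab = infs.mixed_anova(_long_table(y, ["EP", "EP", "HC", "HC"]))
        # grand mean 4.25; group means EP 2.5, HC 6 -> SS_group = 24.5;
        # subject means 2,3,5,7 -> SS_between_subjects = 2*14.75 = 29.5,
        # so SS_subject_error = 5.0 on df 2 (MS 2.5)
        assert tab.between.F == pytest.approx(24.5 / 2.5, abs=1e-12)
        # state means AS 3.5, QS 5 -> SS_state = 4.5; cell means EP (1.5,
        # 3.5), HC (5.5, 6.5) -> SS_interaction = 0.5; SS_total = 35.5, so
        # the within error is 35.5 - 29.5 - 4.5 - 0.5 = 1.0 on df 2 (MS 0.5)
        assert tab.within.F == pytest.approx(4.5 / 0.5, abs=1e-12)
        assert tab.interaction.F == pytest.approx(0.5 / 0.5, abs=1e-12)
        # classic eta squared uses the total SS
        assert tab.within.eta_sq == pytest.approx(4.5 / 35.5, abs=1e-12)

    def test_agrees_with_pingouin_on_unbalanced_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        y = rng.normal(size=(30, 2))
        y[:12, 1] += 0.8
        df = _long_table(y, ["EP"] * 12 + ["HC"] * 18)
        ours = infs.mixed_anova(df)
        theirs = pg.mixed_anova(data=df, dv="value", within="state",
                                between="group", subject="subject")
        t = theirs.set_index("Source")
        assert ours.between.F == pytest.approx(t.loc["group", "F"], rel=1e-6)
        assert ours.within.F == pytest.approx(t.loc["state", "F"], rel=1e-6)
        assert ours.interaction.F == pytest.approx(t.loc["Interaction", "F"],
                                                   rel=1e-6)
        assert ours.within.p == pytest.approx(t.loc["state", "p_unc"],
                                              rel=1e-6)

    def test_missing_cell_rejected(self):
        df = _long_table(np.ones((4, 2)), ["EP"] * 2 + ["HC"] * 2)
        with pytest.raises(ValueError):
            infs.mixed_anova(df.iloc[:-1])

    def test_group_permutation_null_p_uniform(self):
        # between-effect p values under label permutation are uniform
        from scipy.stats import kstest
        rng = np.random.default_rng(3)
        y = rng.normal(size=(24, 2))
        labels = np.array(["EP"] * 12 + ["HC"] * 12)
        ps = []
        for _ in range(300):
            perm = rng.permutation(labels)
            ps.append(infs.mixed_anova(_long_table(y, perm)).between.p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPartialPearson:
    def test_orthogonal_covariate_reduces_to_plain_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        x -= x.mean()
        y -= y.mean()
        z = np.ones(40)                     # intercept-only covariate
        res = infs.partial_pearson(x, y, z)
        plain = np.corrcoef(x, y)[0, 1]
        assert res.r == pytest.approx(plain, abs=1e-12)

    def test_self_correlation_is_one(self):
        x = np.random.default_rng(1).normal(size=20)
        z = np.random.default_rng(2).normal(size=20)
        assert infs.partial_pearson(x, x, z).r == pytest.approx(1.0)

    def test_matches_two_stage_regression_oracle(self):
        # six-point worked example against the explicit residual oracle
        x = np.array([2.0, 4.0, 1.0, 7.0, 5.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 8.0, 4.0, 6.0])
        z = np.array([0.5, 1.0, 0.2, 2.5, 1.5, 1.2])
        Z = np.column_stack([np.ones(6), z])
        rx = x - Z @ np.linalg.solve(Z.T @ Z, Z.T @ x)
        ry = y - Z @ np.linalg.solve(Z.T @ Z, Z.T @ y)
        oracle = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
        assert infs.partial_pearson(x, y, z).r == pytest.approx(oracle,
                                                                abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=32)})
        df["z"] = rng.normal(size=32)
        df["y"] = -0.5 * df.x + 0.3 * df.z + rng.normal(size=32)
        ours = infs.partial_pearson(df.x, df.y, df.z)
        theirs = pg.partial_corr(df, x="x", y="y", covar="z")
        assert ours.r == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-9)
        assert ours.p == pytest.approx(float(theirs["p_val"].iloc[0]),
                                       rel=1e-6)

    def test_fisher_ci_coverage_near_nominal(self):
        # true partial R = -0.5, n = 32: the 95% CI covers the truth at
        # close to nominal rate
        rng = np.random.default_rng(4)
        rho, n = -0.5, 32
        covered = 0
        n_sim = 1000
        for _ in range(n_sim):
            z = rng.normal(size=n)
            u = rng.normal(size=n)
            x = u
            y = rho * u + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
            res = infs.partial_pearson(x + 0.5 * z, y + 0.5 * z, z)
            covered += res.ci95[0] <= rho <= res.ci95[1]
        assert 0.93 <= covered / n_sim <= 0.97

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            infs.partial_pearson([1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert infs.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_equal_ps_unchanged(self):
        out = infs.bh_fdr([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_matches_step_up_enumeration(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.99])
        m = len(p)
        order = np.argsort(p)
        # brute-force step-up: adj_i = min over j >= i of m p_(j) / j, capped
        adj_sorted = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        assert np.allclose(infs.bh_fdr(p), expected, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=12),
           st.randoms(use_true_random=False))
    def test_order_invariance(self, pvals, rnd):
        p = np.asarray(pvals)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = infs.bh_fdr(p)
        shuffled = infs.bh_fdr(p[perm])
        assert np.allclose(direct[perm], shuffled, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            infs.bh_fdr([0.5, 1.5])


class TestAsymmetry:
    def test_perfectly_mirrored_weights_are_null(self):
        rng = np.random.default_rng(0)
        cc = make_edge_cohort(rng, 6, 6, n_parcels=8)
        r_idx, l_idx = infs.hemisphere_edge_sets(cc.edge_index, n_pairs=4)
        cc.weights[:, :, l_idx] = cc.weights[:, :, r_idx]
        res = infs.hemispheric_asymmetry(cc, n_pairs=4)
        assert (res.table["p"] == 1.0).all()
        assert (res.table["p_fdr"] >= res.table["p"]).all()

    def test_symmetric_cohorts_show_no_asymmetry(self):
        hits = 0
        for rep in range(6):
            rng = np.random.default_rng(100 + rep)
            cc = make_edge_cohort(rng, 10, 10, n_parcels=10)
            res = infs.hemispheric_asymmetry(cc, n_pairs=5)
            hits += (res.table["p_fdr"] > 0.05).all()
        assert hits >= 5

    def test_planted_left_boost_detected(self):
        rng = np.random.default_rng(1)
        cc = make_edge_cohort(rng, 25, 25, n_parcels=10, noise_sd=0.1)
        cc.weights += 1.0                   # positive baseline connectivity
        _, l_idx = infs.hemisphere_edge_sets(cc.edge_index, n_pairs=5)
        cc.weights[:, :, l_idx] *= 1.2      # 20% left-hemisphere boost
        res = infs.hemispheric_asymmetry(cc, n_pairs=5)
        assert (res.table["p_fdr"] < 0.05).any()

    def test_four_tests_adjusted_jointly(self):
        rng = np.random.default_rng(2)
        cc = make_edge_cohort(rng, 5, 5, n_parcels=6)
        res = infs.hemispheric_asymmetry(cc, n_pairs=3)
        assert len(res.table) == 4
        assert set(res.table["group"]) == {"EP", "HC"}


class TestBrainBehavior:
    def _outcomes(self, n, rng):
        return pd.DataFrame({"visual": rng.normal(50, 5, n),
                             "social_emotional": rng.normal(50, 5, n),
                             "conceptional_age": rng.normal(41, 1.5, n)})

    def test_null_coupling_stays_null(self):
        rng = np.random.default_rng(0)
        out = self._outcomes(32, rng)
        changes = {b: rng.normal(size=32) for b in ("theta", "alpha", "beta")}
        res = infs.brain_behavior(changes, out)
        assert len(res) == 6
        assert (res["p_fdr"] > 0.05).all()

    def test_exact_negative_coupling_gives_minus_one(self):
        rng = np.random.default_rng(1)
        out = self._outcomes(20, rng)
        change = rng.normal(size=20)
        out["visual"] = -change
        res = infs.brain_behavior({"alpha": change}, out,
                                  score_columns=("visual",))
        assert res["R"].iloc[0] == pytest.approx(-1.0, abs=1e-9)

    def test_planted_effect_survives_fdr(self):
        rng = np.random.default_rng(2)
        hits = 0
        for rep in range(10):
            out = self._outcomes(32, rng)
            changes = {b: rng.normal(size=32)
                       for b in ("theta", "alpha", "beta")}
            # plant R ~ -0.5 on the alpha-visual pair
            c = changes["alpha"]
            out["visual"] = (-0.5 * (c - c.mean()) / c.std()
                             + np.sqrt(1 - 0.25) * rng.normal(size=32))
            res = infs.brain_behavior(changes, out)
            row = res[(res.band == "alpha") & (res.score == "visual")]
            hits += bool((row["p_fdr"] < 0.05).iloc[0])
        # analytic power of the BH-adjusted test at R = -0.5, n = 32 is
        # roughly 0.6 (Fisher-z with the step-up threshold near 0.05/6)
        assert hits >= 4

    def test_connectivity_change_is_as_minus_qs(self):
        rng = np.random.default_rng(3)
        cc = make_edge_cohort(rng, 4, 4, n_parcels=6)
        edges = np.array([0, 2, 5])
        change = infs.connectivity_change(cc, edges)
        expected = (cc.weights[:, 0, edges] - cc.weights[:, 1, edges]).mean(1)
        assert np.allclose(change, expected, atol=1e-12)

    def test_empty_edge_set_rejected(self):
        rng = np.random.default_rng(4)
        cc = make_edge_cohort(rng, 4, 4, n_parcels=6)
        with pytest.raises(ValueError):
            infs.connectivity_change(cc, np.array([], dtype=int))
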