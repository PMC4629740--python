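"""Direction-constrained forward selection, pruning and diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from oplur import lur_model as lm
from oplur.metrics import METRICS

from conftest import fitting_inputs


def table_from(df, directions):
    meta = {c: lm.PredictorMeta(c, directions.get(c, "+")) for c in df.columns}
    return lm.PredictorTable(df, meta)


def random_table(n, names, seed, directions=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(size=(n, len(names))),
        columns=names,
        index=[f"s{i}" for i in range(n)],
    )
    return table_from(df, directions or {})


# ---------------------------------------------------------------------------
# screening and adjusted R^2
# ---------------------------------------------------------------------------

class TestScreening:
    def make(self, zeros):
        n = 40
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 2, n)
        z = rng.uniform(1, 2, n)
        z[:zeros] = 0.0
        df = pd.DataFrame({"dense": x, "sparse": z}, index=[f"s{i}" for i in range(n)])
        return table_from(df, {})

    def test_boundary_is_strict(self):
        assert "sparse" not in lm.screen_predictors(self.make(31)).names
        assert "sparse" in lm.screen_predictors(self.make(30)).names
        assert "dense" in lm.screen_predictors(self.make(31)).names

    def test_all_dropped_is_error(self):
        tab = self.make(40).drop(["dense"])
        with pytest.raises(ValueError):
            lm.screen_predictors(tab)


class TestAdjustedR2:
    def test_collapses_to_r2_without_predictors(self):
        assert lm.adjusted_r2(0.42, 25, 0) == pytest.approx(0.42)

    def test_hand_computed(self):
        assert lm.adjusted_r2(0.6, 40, 4) == pytest.approx(1 - 0.4 * 39 / 35)

    def test_perfect_fit_stays_one(self):
        assert lm.adjusted_r2(1.0, 40, 4) == pytest.approx(1.0)

    def test_degenerate_dof_rejected(self):
        with pytest.raises(ValueError):
            lm.adjusted_r2(0.5, 5, 4)


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

class TestForwardSelect:
    def test_exact_single_predictor_model(self):
        tab = random_table(30, ["x1", "x2", "x3"], seed=1)
        y = pd.Series(2.0 * tab.values["x1"], index=tab.values.index)
        model = lm.forward_select(y, tab)
        assert model.term_names == ["x1"]
        assert model.terms[0].slope == pytest.approx(2.0)
        assert model.adjusted_r2 == pytest.approx(1.0)

    def test_direction_constraint_excludes_wrong_sign(self):
        tab = random_table(30, ["x1"], seed=2, directions={"x1": "+"})
        y = pd.Series(-3.0 * tab.values["x1"], index=tab.values.index)
        model = lm.forward_select(y, tab)
        assert model.terms == []
        assert model.model_r2 == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_path_matches_exhaustive_enumeration(self, seed):
        # independent oracle: enumerate all candidates at each step
        tab = random_table(15, ["a", "b", "c", "d"], seed=100 + seed)
        rng = np.random.default_rng(seed)
        y = pd.Series(
            0.8 * tab.values["a"] - 0.5 * tab.values["b"] + rng.normal(0, 0.5, 15),
            index=tab.values.index,
        )
        tab.meta["b"] = lm.PredictorMeta("b", "-")
        model = lm.forward_select(y, tab)

        def oracle():
            selected = []
            current = 0.0
            while True:
                best = None
                for cand in tab.names:
                    if cand in selected:
                        continue
                    X = sm.add_constant(tab.values[selected + [cand]])
                    res = sm.OLS(y, X).fit()
                    signs_ok = all(
                        np.sign(res.params[nm]) == tab.meta[nm].sign
                        for nm in selected + [cand]
                    )
                    if not signs_ok:
                        continue
                    key = (res.rsquared_adj, abs(res.tvalues[cand]))
                    if best is None or key > best[0]:
                        best = (key, cand)
                if best is None or best[0][0] - current <= 0.01:
                    return selected
                selected = selected + [best[1]]
                current = best[0][0]

        assert model.term_names == oracle()

    def test_empty_candidate_pool_rejected(self):
        tab = random_table(10, ["a"], seed=0)
        y = pd.Series(np.ones(10), index=tab.values.index)
        with pytest.raises(ValueError):
            lm.forward_select(y, tab, blacklist={"a"})


class TestPrunePvalues:
    def test_noise_term_removed_and_truth_recovered(self):
        tab = random_table(30, ["sig", "noise"], seed=3)
        y = pd.Series(1.5 * tab.values["sig"], index=tab.values.index)
        start = lm._build_model(y, tab, ["sig", "noise"])
        pruned = lm.prune_pvalues(start, y, tab)
        assert pruned.term_names == ["sig"]
        assert pruned.terms[0].slope == pytest.approx(1.5)

    def test_significant_model_unchanged(self):
        tab = random_table(40, ["x"], seed=4)
        rng = np.random.default_rng(4)
        y = pd.Series(2 * tab.values["x"] + rng.normal(0, 0.1, 40), index=tab.values.index)
        start = lm._build_model(y, tab, ["x"])
        assert lm.prune_pvalues(start, y, tab).term_names == ["x"]

    def test_empty_model_passthrough(self):
        tab = random_table(10, ["x"], seed=5)
        y = pd.Series(np.arange(10.0), index=tab.values.index)
        empty = lm._build_model(y, tab, [])
        assert lm.prune_pvalues(empty, y, tab).terms == []


# ---------------------------------------------------------------------------
# collinearity and influence
# ---------------------------------------------------------------------------

class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        v = lm.vif(pd.DataFrame({"x": x, "z": z}))
        assert np.allclose(v, 1.0)

    def test_matches_closed_form_for_two_predictors(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        z = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=200)
        v = lm.vif(pd.DataFrame({"x": x, "z": z}))
        r2 = np.corrcoef(x, z)[0, 1] ** 2
        assert v["x"] == pytest.approx(1 / (1 - r2))
        assert v["z"] == pytest.approx(1 / (1 - r2))

    def test_duplicate_column_flags_infinity(self):
        x = np.arange(10.0)
        v = lm.vif(pd.DataFrame({"x": x, "x2": x.copy()}))
        assert np.isinf(v).all()

    def test_single_column_is_one(self):
        assert lm.vif(pd.DataFrame({"x": np.arange(5.0)}))["x"] == 1.0


class TestPruneVif:
    def test_near_duplicates_resolved_below_threshold(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        dup = x + rng.normal(0, 0.05, 40)  # r ~ 0.999, VIF huge
        w = rng.normal(size=40)
        df = pd.DataFrame(
            {"x": x, "dup": dup, "w": w}, index=[f"s{i}" for i in range(40)]
        )
        tab = table_from(df, {})
        y = pd.Series(
            x + dup + 0.5 * w + rng.normal(0, 0.05, 40), index=df.index
        )
        model = lm.forward_select(y, tab, delta=0.001)
        model = lm.prune_vif(model, y, tab, threshold=3.0, delta=0.001)
        assert len(model.terms) >= 1
        if len(model.terms) >= 2:
            assert lm.vif(tab.values[model.term_names]).max() <= 3.0
        assert not {"x", "dup"} <= set(model.term_names)


class TestCooksD:
    def test_zero_for_noiseless_fit(self):
        tab = random_table(20, ["x"], seed=8)
        y = pd.Series(3 * tab.values["x"] + 1, index=tab.values.index)
        d = lm.cooks_d(y, tab, ["x"])
        assert float(d.max()) == pytest.approx(0.0, abs=1e-16)

    def test_gross_outlier_attains_max(self):
        tab = random_table(15, ["x"], seed=9)
        y = pd.Series(2 * tab.values["x"], index=tab.values.index)
        y.iloc[4] += 25.0
        d = lm.cooks_d(y, tab, ["x"])
        assert d.idxmax() == y.index[4]

    def test_matches_statsmodels(self):
        tab = random_table(25, ["x", "z"], seed=10)
        rng = np.random.default_rng(10)
        y = pd.Series(
            tab.values["x"] - tab.values["z"] + rng.normal(0, 1, 25),
            index=tab.values.index,
        )
        d = lm.cooks_d(y, tab, ["x", "z"])
        X = sm.add_constant(tab.values[["x", "z"]])
        ref = sm.OLS(y, X).fit().get_influence().cooks_distance[0]
        assert np.allclose(d.to_numpy(), ref)


class TestMoransI:
    def test_expected_value_closed_form(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 1, size=(5, 2))
        w = lm.spatial_weights(coords)
        out = lm.morans_i(rng.normal(size=5), w)
        assert out["expected"] == pytest.approx(-0.25)

    def test_constant_residuals_rejected(self):
        w = lm.spatial_weights(np.random.default_rng(0).uniform(size=(6, 2)))
        with pytest.raises(ValueError, match="zero variance"):
            lm.morans_i(np.ones(6), w)

    def test_matches_brute_force_double_sum(self):
        # n = 6, binary adjacency ring, integer residuals
        n = 6
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[i, (i - 1) % n] = 1.0
        e = np.array([3.0, -1.0, 2.0, -4.0, 1.0, -1.0])
        ec = e - e.mean()
        s0 = w.sum()
        num = sum(
            w[i, j] * ec[i] * ec[j] for i in range(n) for j in range(n)
        )
        expected = (n / s0) * num / (ec ** 2).sum()
        out = lm.morans_i(e, w)
        assert out["I"] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_fixture_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        coords = rng.uniform(0, 10, size=(n, 2))
        w = lm.spatial_weights(coords, scheme="idw")
        e = rng.normal(size=n)
        ec = e - e.mean()
        brute = (n / w.sum()) * float(ec @ w @ ec) / float(ec @ ec)
        out = lm.morans_i(e, w)
        assert out["I"] == pytest.approx(brute)
        assert out["expected"] == pytest.approx(-1 / (n - 1))

    def test_clustered_residuals_detected(self):
        # two spatial blobs with opposite residual signs: strong positive I
        rng = np.random.default_rng(12)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(5, 0.1, size=(10, 2))
        coords = np.vstack([a, b])
        e = np.r_[np.full(10, 1.0), np.full(10, -1.0)] + rng.normal(0, 0.1, 20)
        out = lm.morans_i(e, lm.spatial_weights(coords))
        assert out["I"] > 0.5
        assert out["p"] < 0.05


# ---------------------------------------------------------------------------
# reporting and prediction
# ---------------------------------------------------------------------------

class TestStandardizeAndPredict:
    def test_standardized_coefficient_scaling(self):
        tab = random_table(20, ["x"], seed=13)
        y = pd.Series(2.0 * tab.values["x"], index=tab.values.index)
        model = lm._build_model(y, tab, ["x"])
        out = lm.standardize_coefficients(model, tab)[0]
        span = np.percentile(tab.values["x"], 90) - np.percentile(tab.values["x"], 10)
        assert out["std_coefficient"] == pytest.approx(2.0 * span)
        assert out["p10_p90_span"] == pytest.approx(span)

    def test_unit_span_reports_raw_slope(self):
        df = pd.DataFrame(
            {"x": np.linspace(0, 1.25, 20)}, index=[f"s{i}" for i in range(20)]
        )
        tab = table_from(df, {})
        span = tab.percentile_span("x")
        y = pd.Series(4.0 * df["x"], index=df.index)
        model = lm._build_model(y, tab, ["x"])
        out = lm.standardize_coefficients(model, tab)[0]
        assert out["std_coefficient"] == pytest.approx(4.0 * span)

    def test_degenerate_predictor_rejected(self):
        df = pd.DataFrame({"x": np.ones(10)}, index=[f"s{i}" for i in range(10)])
        tab = table_from(df, {})
        model = lm.LurModel(
            metric="", intercept=0, intercept_se=0, intercept_p=1,
            terms=[lm.LurTerm("x", 1.0, 0.1, 0.01, 0.5)],
            model_r2=0.5, adjusted_r2=0.5, rmse=1.0, n_sites=10,
            training_site_ids=list(df.index),
        )
        with pytest.raises(ValueError, match="P90"):
            lm.standardize_coefficients(model, tab)

    def test_prediction_at_training_mean_is_mean_response(self):
        tab = random_table(30, ["x", "z"], seed=14)
        rng = np.random.default_rng(14)
        y = pd.Series(
            tab.values["x"] + 2 * tab.values["z"] + rng.normal(0, 1, 30),
            index=tab.values.index,
        )
        model = lm._build_model(y, tab, ["x", "z"])
        mean_row = tab.values.mean().to_frame().T
        pred = lm.predict(model, mean_row)
        assert pred.iloc[0] == pytest.approx(y.mean())

    def test_training_predictions_reproduce_model_r2(self):
        tab = random_table(30, ["x", "z"], seed=15)
        rng = np.random.default_rng(15)
        y = pd.Series(
            tab.values["x"] - tab.values["z"] + rng.normal(0, 1, 30),
            index=tab.values.index,
        )
        model = lm._build_model(y, tab, ["x", "z"])
        pred = lm.predict(model, tab.values)
        r2 = np.corrcoef(pred, y)[0, 1] ** 2
        assert r2 == pytest.approx(model.model_r2)

    def test_empty_model_predicts_training_mean(self):
        tab = random_table(10, ["x"], seed=16)
        y = pd.Series(np.arange(10.0), index=tab.values.index)
        model = lm._build_model(y, tab, [])
        pred = lm.predict(model, tab.values)
        assert np.allclose(pred, y.mean())

    def test_missing_predictor_column_rejected(self):
        tab = random_table(10, ["x"], seed=17)
        y = pd.Series(np.arange(10.0), index=tab.values.index)
        model = lm._build_model(y, tab, ["x"])
        with pytest.raises(KeyError, match="x"):
            lm.predict(model, tab.values.drop(columns=["x"]))


# ---------------------------------------------------------------------------
# full development protocol on synthetic campaigns
# ---------------------------------------------------------------------------

class TestDevelopModel:
    @pytest.mark.parametrize("metric", METRICS)
    def test_final_model_satisfies_all_constraints(self, noisy_campaign, metric):
        y, aug = fitting_inputs(noisy_campaign, metric)
        coords = noisy_campaign.sites.set_index("site_id").loc[y.index, ["x", "y"]]
        model = lm.develop_model(y, aug, metric=metric, coords=coords.to_numpy(float))
        assert model.terms, "default campaign should yield a non-empty model"
        for term in model.terms:
            assert np.sign(term.slope) == aug.meta[term.name].sign
            assert term.pvalue <= 0.10
        if len(model.terms) >= 2:
            assert lm.vif(aug.values[model.term_names]).max() <= 3.0
        assert model.diagnostics["max_vif"] <= 3.0
        assert "morans_i" in model.diagnostics

    @pytest.mark.parametrize("metric", METRICS)
    def test_cumulative_adjusted_r2_is_increasing(self, noisy_campaign, metric):
        y, aug = fitting_inputs(noisy_campaign, metric)
        model = lm.develop_model(y, aug, metric=metric)
        cums = [t.cum_adj_r2 for t in model.terms if np.isfinite(t.cum_adj_r2)]
        assert all(b - a > 0.01 for a, b in zip(cums, cums[1:]))

    def test_noiseless_campaign_recovers_generating_slopes(self, noiseless_campaign):
        for metric in METRICS:
            y, aug = fitting_inputs(noiseless_campaign, metric)
            model = lm.develop_model(y, aug, metric=metric)
            tm = noiseless_campaign.config.true_models[metric]
            truth = dict(tm.slopes)
            truth[f"regional_estimate_{metric}"] = tm.background_slope
            got = {t.name: t.slope for t in model.terms}
            for name, slope in truth.items():
                assert name in got
                assert got[name] == pytest.approx(slope, abs=1e-8)
            assert model.intercept == pytest.approx(tm.intercept, abs=1e-6)
            assert model.model_r2 == pytest.approx(1.0, abs=1e-10)

    def test_serialization_round_trip(self, tmp_path, noisy_campaign):
        y, aug = fitting_inputs(noisy_campaign, "OP_DTT")
        model = lm.develop_model(y, aug, metric="OP_DTT")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = lm.LurModel.from_json(path)
        assert back.term_names == model.term_names
        assert back.intercept == pytest.approx(model.intercept)
        pred_a = lm.predict(model, aug.values)
        pred_b = lm.predict(back, aug.values)
        assert np.allclose(pred_a, pred_b)
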