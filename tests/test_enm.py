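import numpy as np
import pandas as pd
import pytest

from snakemaps import enm
from snakemaps import synthetic as syn
from snakemaps.enm import (
    balance_threshold,
    build_features,
    fit_model,
    hinge_value,
    model_from_json,
    model_to_json,
    predict,
    threshold_and_rescale,
)
from snakemaps.grid import Grid, GridSpec


@pytest.fixture(scope="module")
def niche_data():
    """Single-driver synthetic niche: env0 drives suitability, env1 is noise."""
    rng = np.random.default_rng(0)
    spec = GridSpec(0, 1, 100, 100)
    stack_g = syn.gen_env_stack(spec, 2, [], seed=1)
    truth = syn.gen_true_suitability(stack_g, syn.TruthModel([2.5, 0.0], intercept=-1))
    occs = syn.gen_occurrences(truth, 500, None, seed=2)
    stack = {"env0": stack_g[0], "env1": stack_g[1]}
    pres = enm.extract_values(stack, occs.cells(spec))
    bg_cells = np.column_stack(
        [rng.integers(0, 100, 3000), rng.integers(0, 100, 3000)]
    )
    bg = enm.extract_values(stack, bg_cells)
    return {"spec": spec, "stack": stack, "truth": truth, "pres": pres, "bg": bg}


class TestFeatures:
    def test_linear_feature_zero_at_training_mean(self, rng):
        X = pd.DataFrame({"v": rng.normal(10, 3, 50)})
        fs = build_features(X, classes=("linear",))
        at_mean = pd.DataFrame({"v": [X["v"].mean()]})
        assert fs.transform(at_mean)[0, 0] == pytest.approx(0.0)

    def test_forward_hinge_at_training_max_is_zero_column(self, rng):
        x = rng.uniform(0, 5, 100)
        col = hinge_value(x, knot=x.max(), lo=x.min(), hi=x.max(), forward=True)
        assert np.all(col == 0)

    def test_quadratic_and_product_match_direct_computation(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["u", "v"])
        fs = build_features(X, classes=("linear", "quadratic", "product"))
        rows = X.iloc[rng.choice(40, 5, replace=False)]
        F = fs.transform(rows)
        names = fs.names
        zu = (rows["u"] - X["u"].mean()) / X["u"].std(ddof=0)
        zv = (rows["v"] - X["v"].mean()) / X["v"].std(ddof=0)
        np.testing.assert_allclose(F[:, names.index("quadratic:u")], zu**2)
        np.testing.assert_allclose(F[:, names.index("product:u*v")], zu * zv)

    def test_product_features_suppressed_when_disallowed(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["u", "v"])
        fs = build_features(X, allow_product=False)
        assert not any(n.startswith("product") for n in fs.names)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            build_features(pd.DataFrame({"v": [1.0]}))


class TestFit:
    def test_null_data_shrinks_weights_to_zero(self, rng):
        # n large enough that sampling noise (~1/sqrt(n)) sits below the bound
        pres = pd.DataFrame({"a": rng.normal(size=1500), "b": rng.normal(size=1500)})
        bg = pd.DataFrame({"a": rng.normal(size=2000), "b": rng.normal(size=2000)})
        m = fit_model(pres, bg)
        assert np.all(np.abs(m.weights) <= 0.05)
        scores = m.score_rows(bg)
        assert scores.std() <= 0.05  # essentially flat surface

    def test_recovers_single_driver_niche(self, niche_data):
        from scipy.stats import spearmanr

        m = fit_model(niche_data["pres"], niche_data["bg"])
        pred = predict(m, niche_data["stack"])
        truth = niche_data["truth"]
        rho = spearmanr(pred.values.ravel(), truth.values.ravel()).statistic
        assert rho >= 0.9

    def test_stronger_penalty_never_adds_features(self, niche_data):
        m1 = fit_model(niche_data["pres"].iloc[:100], niche_data["bg"], beta=1.0)
        m10 = fit_model(niche_data["pres"].iloc[:100], niche_data["bg"], beta=10.0)
        assert m10.nonzero_weights <= m1.nonzero_weights

    def test_gibbs_probabilities_sum_to_one(self, niche_data):
        m = fit_model(niche_data["pres"], niche_data["bg"])
        assert m.train_raw.sum() == pytest.approx(1.0, abs=1e-8)

    def test_too_few_rows_rejected(self, rng):
        one = pd.DataFrame({"a": [1.0]})
        bg = pd.DataFrame({"a": rng.normal(size=50)})
        with pytest.raises(ValueError):
            fit_model(one, bg)


class TestPredict:
    def test_training_row_scores_match_in_sample(self, niche_data):
        m = fit_model(niche_data["pres"], niche_data["bg"])
        pred = predict(m, niche_data["stack"])
        spec = niche_data["spec"]
        # a background cell's grid score equals scoring its row directly
        row = niche_data["bg"].iloc[[17]]
        direct = m.score_rows(row)[0]
        env0 = niche_data["stack"]["env0"].values
        i, j = np.argwhere(np.isclose(env0, row["env0"].iloc[0]))[0]
        assert pred.values[i, j] == pytest.approx(direct, rel=1e-9)

    def test_clamping_stops_extrapolation(self, niche_data):
        m = fit_model(niche_data["pres"], niche_data["bg"])
        vmax = m.features.maxs["env0"]
        above = pd.DataFrame({"env0": [vmax + 5.0], "env1": [0.0]})
        at_max = pd.DataFrame({"env0": [vmax], "env1": [0.0]})
        assert m.score_rows(above)[0] == pytest.approx(m.score_rows(at_max)[0])

    def test_nodata_propagates(self, niche_data):
        m = fit_model(niche_data["pres"], niche_data["bg"])
        stack = {k: g.copy_with(g.values.copy()) for k, g in niche_data["stack"].items()}
        stack["env0"].values[5, 5] = np.nan
        pred = predict(m, stack)
        assert np.isnan(pred.values[5, 5])
        assert np.isfinite(pred.values[6, 6])

    def test_missing_variable_named(self, niche_data):
        m = fit_model(niche_data["pres"], niche_data["bg"])
        with pytest.raises(KeyError, match="env1"):
            predict(m, {"env0": niche_data["stack"]["env0"]})

    def test_prediction_invariant_to_affine_input_rescaling(self, niche_data):
        pres, bg = niche_data["pres"], niche_data["bg"]
        m = fit_model(pres, bg)
        scale = lambda df: pd.DataFrame(
            {"env0": df["env0"] * 37.0 + 5.0, "env1": df["env1"] * 0.01 - 2.0}
        )
        m2 = fit_model(scale(pres), scale(bg))
        np.testing.assert_allclose(
            m.score_rows(bg), m2.score_rows(scale(bg)), atol=1e-4
        )


class TestCrossValidate:
    def test_returns_k_aucs(self, niche_data):
        aucs = enm.cross_validate(
            niche_data["pres"].iloc[:60], niche_data["bg"].iloc[:500], k=10, seed=1
        )
        assert len(aucs) == 10
        assert all(0 <= a <= 1 for a in aucs)

    def test_separable_data_scores_high(self, rng):
        pres = pd.DataFrame({"a": rng.normal(5, 0.5, 60), "b": rng.normal(size=60)})
        bg = pd.DataFrame({"a": rng.normal(0, 0.5, 600), "b": rng.normal(size=600)})
        aucs = enm.cross_validate(pres, bg, k=5, seed=2)
        assert np.mean(aucs) > 0.95

    def test_null_data_scores_at_chance(self, rng):
        pres = pd.DataFrame({"a": rng.normal(size=80), "b": rng.normal(size=80)})
        bg = pd.DataFrame({"a": rng.normal(size=800), "b": rng.normal(size=800)})
        aucs = enm.cross_validate(pres, bg, k=5, seed=3)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_too_few_presences_rejected(self, niche_data):
        with pytest.raises(ValueError):
            enm.cross_validate(niche_data["pres"].iloc[:5], niche_data["bg"], k=10)


class TestPermutationImportance:
    def test_single_driver_dominates(self, niche_data):
        m = fit_model(niche_data["pres"], niche_data["bg"])
        imp = enm.permutation_importance(
            m, niche_data["pres"], niche_data["bg"], n_perm=3, seed=4
        )
        assert imp["env0"] >= 90.0

    def test_importances_sum_to_100(self, niche_data):
        m = fit_model(niche_data["pres"], niche_data["bg"])
        imp = enm.permutation_importance(
            m, niche_data["pres"], niche_data["bg"], n_perm=2, seed=5
        )
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)

    def test_zero_weight_variable_has_zero_importance(self, rng):
        pres = pd.DataFrame({"a": rng.normal(3, 1, 80), "b": rng.normal(size=80)})
        bg = pd.DataFrame({"a": rng.normal(size=800), "b": rng.normal(size=800)})
        m = fit_model(pres, bg)
        names = m.features.names
        b_cols = [k for k, n in enumerate(names) if ":b" in n or "*b" in n or n.endswith("b")]
        m.weights[b_cols] = 0.0
        imp = enm.permutation_importance(m, pres, bg, n_perm=2, seed=6)
        assert imp["b"] == 0.0


class TestThreshold:
    def test_balance_threshold_matches_brute_force(self, rng):
        """Exhaustive enumeration of the balance objective over observed values."""
        pres = pd.DataFrame({"a": rng.normal(1.5, 1, 10), "b": rng.normal(size=10)})
        bg = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        m = fit_model(pres, bg)
        cands = np.unique(np.concatenate([m.train_scores, m.train_presence_scores]))
        objs = [
            6.0 * np.mean(m.train_presence_scores < t)
            + 0.04 * 100.0 * m.train_raw[m.train_scores < t].sum()
            + 1.6 * np.mean(m.train_scores >= t)
            for t in cands
        ]
        assert balance_threshold(m) == cands[int(np.argmin(objs))]

    def test_rescaled_max_is_one(self, random_grid):
        out = threshold_and_rescale(random_grid, 0.5)
        assert np.nanmax(out.values) == pytest.approx(1.0)
        assert np.nanmin(out.values) == 0.0

    def test_all_cells_below_threshold_warns_and_zeroes(self, random_grid):
        with pytest.warns(UserWarning):
            out = threshold_and_rescale(random_grid, 2.0)
        assert np.nanmax(out.values) == 0.0

    def test_nodata_preserved(self, random_grid):
        random_grid.values[0, 0] = np.nan
        out = threshold_and_rescale(random_grid, 0.5)
        assert np.isnan(out.values[0, 0])


def test_model_json_round_trip(niche_data):
    m = fit_model(niche_data["pres"].iloc[:50], niche_data["bg"].iloc[:500])
    back = model_from_json(model_to_json(m))
    np.testing.assert_allclose(back.weights, m.weights)
    assert back.threshold == m.threshold
    np.testing.assert_allclose(
        back.score_rows(niche_data["bg"].iloc[:20]),
        m.score_rows(niche_data["bg"].iloc[:20]),
    )
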