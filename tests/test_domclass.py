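"""Domestication classifier: splitting, OLS fitting, scoring, ablation."""

import numpy as np
import pandas as pd
import pytest

from grainct import domclass, simgrain


def _table(n_wild=50, n_dom=50, seed=0, **kw):
    return simgrain.generate_trait_table(
        simgrain.PopulationSpec(n_wild=n_wild, n_dom=n_dom, seed=seed, **kw)
    )


class TestEncodeStatus:
    def test_mapping(self):
        t = pd.DataFrame({"status": ["wild", "domesticated", "wild"]})
        assert list(domclass.encode_status(t)) == [0.0, 1.0, 0.0]

    def test_empty(self):
        assert len(domclass.encode_status(pd.DataFrame({"status": []}))) == 0

    def test_unknown_value_named(self):
        t = pd.DataFrame({"status": ["wild", "feral"]})
        with pytest.raises(ValueError, match="feral"):
            domclass.encode_status(t)


class TestSplit:
    def test_750_records_give_150_600(self):
        t = _table(237, 513, seed=1)
        train, test = domclass.split_train_test(t, 0.2, seed=0)
        assert len(train) == 150
        assert len(test) == 600
        assert len(set(train.index) & set(test.index)) == 0

    def test_same_seed_identical(self):
        t = _table()
        a1, b1 = domclass.split_train_test(t, 0.2, seed=9)
        a2, b2 = domclass.split_train_test(t, 0.2, seed=9)
        assert list(a1.index) == list(a2.index)
        assert list(b1.index) == list(b2.index)

    def test_stratification_exhaustive_small_case(self):
        t = _table(5, 5, seed=2)
        train, test = domclass.split_train_test(t, 0.5, seed=0)
        assert len(train) == 5 and len(test) == 5
        # stratified: each side holds one class 2/3 or 3/2, never 1/4 or worse
        for part in (train, test):
            counts = part.status.value_counts()
            assert set(counts) <= {2, 3}

    def test_tiny_class_error(self):
        t = _table(1, 10, seed=0)
        with pytest.raises(ValueError, match="< 2"):
            domclass.split_train_test(t, 0.2, seed=0)


class TestFit:
    def test_exact_linear_response_recovered(self):
        rng = np.random.default_rng(0)
        n = 40
        depth = rng.normal(2000, 100, n)
        t = pd.DataFrame(
            {
                "status": ["wild"] * (n // 2) + ["domesticated"] * (n // 2),
                "length_um": rng.normal(6000, 100, n),
                "width_um": rng.normal(2500, 100, n),
                "depth_um": depth,
            }
        )
        # response exactly linear in standardized depth -> OLS must recover
        # the coefficients to numerical precision, other betas zero
        d_std = (depth - depth.mean()) / depth.std(ddof=0)
        model = domclass.fit(t, response=0.5 + 0.3 * d_std)
        assert model.coefficients["intercept"] == pytest.approx(0.5, abs=1e-8)
        assert model.coefficients["depth_um"] == pytest.approx(0.3, abs=1e-8)
        assert model.coefficients["length_um"] == pytest.approx(0.0, abs=1e-8)
        assert model.coefficients["width_um"] == pytest.approx(0.0, abs=1e-8)

    def test_normal_equations_oracle_six_rows(self):
        t = pd.DataFrame(
            {
                "status": ["wild", "wild", "wild", "domesticated", "domesticated", "domesticated"],
                "length_um": [6000.0, 6100, 5900, 6050, 6200, 5950],
                "width_um": [2400.0, 2500, 2450, 2600, 2700, 2650],
                "depth_um": [1900.0, 1950, 1850, 2400, 2500, 2450],
            }
        )
        model = domclass.fit(t)
        x = np.asarray(t[domclass.FEATURES])
        xs = (x - x.mean(0)) / x.std(0)
        design = np.column_stack([np.ones(6), xs])
        y = np.array([0.0, 0, 0, 1, 1, 1])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        got = [model.coefficients["intercept"]] + [
            model.coefficients[f] for f in domclass.FEATURES
        ]
        np.testing.assert_allclose(got, beta, atol=1e-10)

    def test_duplicate_column_collinearity_error(self):
        t = _table(20, 20, seed=3)
        t["width_um"] = t["depth_um"]
        with pytest.raises(ValueError, match="collinear"):
            domclass.fit(t)

    def test_constant_feature_named(self):
        t = _table(20, 20, seed=3)
        t["length_um"] = 6000.0
        with pytest.raises(ValueError, match="length_um"):
            domclass.fit(t)


class TestRSquared:
    def test_perfect_prediction(self):
        assert domclass.r_squared([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_mean_prediction_zero(self):
        assert domclass.r_squared([0, 1, 0, 1], [0.5] * 4) == 0.0

    def test_hand_example_three_quarters(self):
        assert domclass.r_squared([0, 1, 0, 1], [0.25, 0.75, 0.25, 0.75]) == pytest.approx(0.75)

    def test_constant_truth_error(self):
        with pytest.raises(ValueError):
            domclass.r_squared([1, 1, 1], [1, 1, 1])

    def test_agrees_with_one_line_oracle_on_evaluations(self):
        t = _table(100, 100, seed=4)
        train, test = domclass.split_train_test(t, 0.2, seed=4)
        model = domclass.fit(train)
        ev = domclass.evaluate(model, test)
        y = domclass.encode_status(test)
        oracle = 1 - np.sum((y - ev.predictions) ** 2) / np.sum((y - y.mean()) ** 2)
        assert ev.r_squared == pytest.approx(oracle, rel=1e-12)


class TestEvaluate:
    def test_separated_populations_high_r2_no_misclassification(self):
        t = _table(100, 100, seed=5)
        t["depth_um"] = np.where(t.status == "wild", 1500.0, 3000.0) + np.arange(200) * 0.01
        train, test = domclass.split_train_test(t, 0.2, seed=5)
        ev = domclass.evaluate(domclass.fit(train), test)
        assert ev.r_squared > 0.95
        assert len(ev.misclassified) == 0

    def test_permuted_labels_destroy_signal(self):
        for seed in range(10):
            t = _table(100, 100, seed=seed)
            rng = np.random.default_rng(seed)
            t["status"] = rng.permutation(t["status"].to_numpy())
            train, test = domclass.split_train_test(t, 0.2, seed=seed)
            ev = domclass.evaluate(domclass.fit(train), test)
            assert ev.r_squared <= 0.05

    def test_train_test_overlap_forbidden(self):
        t = _table(30, 30, seed=6)
        train, _ = domclass.split_train_test(t, 0.5, seed=6)
        with pytest.raises(ValueError, match="overlap"):
            domclass.evaluate(domclass.fit(train), train)

    def test_missing_feature_error(self):
        t = _table(30, 30, seed=6)
        train, test = domclass.split_train_test(t, 0.5, seed=6)
        with pytest.raises(ValueError, match="depth_um"):
            domclass.fit(train).predict(test.drop(columns=["depth_um"]))


class TestAblation:
    def test_depth_only_signal_collapses_without_depth(self):
        pop = simgrain.shifted_population(depth_shift=0.35, n_wild=300, n_dom=300, seed=7)
        t = simgrain.generate_trait_table(pop)
        rep = domclass.ablation(t, seed=7)
        full = rep.r_squared[("length_um", "width_um", "depth_um")]
        no_depth = rep.r_squared[("length_um", "width_um")]
        assert full - no_depth > 0.4

    def test_null_populations_no_subset_fits(self):
        pop = simgrain.shifted_population(n_wild=300, n_dom=300, seed=8)
        rep = domclass.ablation(simgrain.generate_trait_table(pop), seed=8)
        assert all(r2 <= 0.05 for r2 in rep.r_squared.values())

    def test_all_subsets_share_test_records(self):
        t = _table(100, 100, seed=9)
        rep = domclass.ablation(t, seed=9)
        assert len(rep.r_squared) == 7  # every non-empty subset of 3 features
        _, test = domclass.split_train_test(t, 0.2, seed=9)
        assert list(rep.test_index) == list(test.index)

    def test_end_to_end_determinism(self):
        t = _table(80, 80, seed=10)
        r1 = domclass.ablation(t, seed=10)
        r2 = domclass.ablation(t, seed=10)
        assert r1.r_squared == r2.r_squared
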