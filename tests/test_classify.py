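"""Feature plans, random-forest harness, and map prediction."""

import numpy as np
import pandas as pd
import pytest

from marshphen.classify import (
    PLAN_FEATURES,
    assemble_features,
    plan_feature_names,
    predict_map,
    stack_for_plan,
    train_and_cv,
)
from marshphen.errors import ConfigError, DegenerateLabelsError, SchemaError


@pytest.mark.parametrize(
    "plan,n", [(1, 6), (2, 24), (3, 18), (4, 18), (5, 30)]
)
def test_plan_feature_counts(plan, n):
    assert len(plan_feature_names(plan)) == n


def test_plan_contents():
    assert plan_feature_names(1) == ("SOS", "EOS", "MV", "BV", "ROI", "ROD")
    assert all(f.startswith(("VVminusVH", "VHoverVV")) for f in plan_feature_names(2))
    assert not any(f.startswith("VVminusVH") for f in plan_feature_names(3))
    assert not any(f.startswith("VHoverVV") for f in plan_feature_names(4))


def test_invalid_plan_rejected():
    with pytest.raises(ConfigError):
        plan_feature_names(6)
    with pytest.raises(ConfigError):
        plan_feature_names(0)


def _stacks(rows=4, cols=4, seed=0):
    rng = np.random.default_rng(seed)
    return rng.random((6, rows, cols)), rng.random((24, rows, cols))


def test_assemble_columns_match_plan():
    pheno, sar = _stacks()
    samples = pd.DataFrame({"row": [0, 1], "col": [0, 1], "class_code": [1, 2]})
    for plan in PLAN_FEATURES:
        table = assemble_features(plan, pheno, sar, samples)
        assert tuple(table.columns[2:]) == plan_feature_names(plan)
        assert len(table) == 2


def test_assemble_drops_undefined_pixels():
    pheno, sar = _stacks()
    pheno[:, 1, 1] = np.nan  # tidally excluded / unfit pixel
    samples = pd.DataFrame({"row": [0, 1], "col": [0, 1], "class_code": [1, 2]})
    table = assemble_features(1, pheno, sar, samples)
    assert len(table) == 1
    assert table.attrs["n_dropped"] == 1
    # SAR-only plan is unaffected by missing phenology
    assert len(assemble_features(2, pheno, sar, samples)) == 2


def test_sample_outside_grid_rejected():
    pheno, sar = _stacks()
    samples = pd.DataFrame({"row": [9], "col": [0], "class_code": [1]})
    with pytest.raises(SchemaError):
        assemble_features(1, pheno, sar, samples)


def _separable_table(n=40, seed=0, n_classes=2):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(1, n_classes + 1), n // n_classes)
    X = y[:, None] + 0.05 * rng.standard_normal((n, 3))
    table = pd.DataFrame(X, columns=["SOS", "EOS", "MV"])
    table.insert(0, "class_code", y)
    table.insert(0, "pixel_id", np.arange(n))
    return table


def test_separable_classes_get_perfect_cv():
    report, model = train_and_cv(_separable_table(), seed=1, n_estimators=50)
    assert report.cv_mean == pytest.approx(1.0)
    assert report.f1_macro == pytest.approx(1.0)
    assert report.best_params["max_features"] in ("sqrt", "log2")


def test_random_labels_score_at_chance(rng):
    n = 200
    X = rng.standard_normal((n, 6))
    y = np.tile([1, 2, 3, 4], n // 4)
    table = pd.DataFrame(X, columns=list("abcdef"))
    table.insert(0, "class_code", rng.permutation(y))
    table.insert(0, "pixel_id", np.arange(n))
    report, _ = train_and_cv(table, seed=3, n_estimators=100)
    assert 0.10 <= report.cv_mean <= 0.45  # chance is 0.25 for 4 balanced classes


def test_same_seed_identical_reports():
    a, _ = train_and_cv(_separable_table(seed=5), seed=9, n_estimators=50)
    b, _ = train_and_cv(_separable_table(seed=5), seed=9, n_estimators=50)
    assert a.to_dict() == b.to_dict()


def test_degenerate_labels_rejected():
    table = _separable_table()
    table["class_code"] = 1
    with pytest.raises(DegenerateLabelsError):
        train_and_cv(table, seed=0)


def test_noise_features_do_not_help(rng):
    """Appending uninformative columns never buys real accuracy."""
    base_table = _separable_table(n=60, seed=2)
    X_noise = rng.standard_normal((60, 10))
    noisy = base_table.copy()
    for i in range(10):
        noisy[f"noise_{i}"] = X_noise[:, i]
    base, _ = train_and_cv(base_table, seed=4, n_estimators=100)
    augmented, _ = train_and_cv(noisy, seed=4, n_estimators=100)
    assert augmented.cv_mean <= base.cv_mean + 0.05


class TestPredictMap:
    def test_memorizes_separable_training_pixels(self):
        rng = np.random.default_rng(0)
        pheno = np.zeros((6, 2, 4))
        sar = rng.random((24, 2, 4))
        labels = np.array([[1, 1, 2, 2], [1, 1, 2, 2]])
        pheno[2] = labels  # MV carries the class signal
        samples = pd.DataFrame(
            {"row": [0, 0, 1, 1], "col": [0, 2, 1, 3], "class_code": [1, 2, 1, 2]}
        )
        table = assemble_features(1, pheno, sar, samples)
        _, model = train_and_cv(table, seed=0, n_estimators=50, n_folds=2)
        cmap = predict_map(model, 1, pheno, sar)
        np.testing.assert_array_equal(cmap, labels)

    def test_nodata_propagates_from_masked_pixels(self):
        pheno, sar = _stacks()
        pheno[:, 0, 0] = np.nan
        samples = pd.DataFrame(
            {"row": [1, 1, 2, 2, 3, 3], "col": [0, 1, 0, 1, 0, 1],
             "class_code": [1, 2, 1, 2, 1, 2]}
        )
        table = assemble_features(5, pheno, sar, samples)
        _, model = train_and_cv(table, seed=0, n_estimators=20, n_folds=3)
        cmap = predict_map(model, 5, pheno, sar)
        assert cmap[0, 0] == 0
        assert np.all(cmap[1:] != 0)

    def test_feature_count_mismatch_rejected(self):
        pheno, sar = _stacks()
        samples = pd.DataFrame(
            {"row": [0, 0, 1, 1, 2, 2], "col": [0, 1, 0, 1, 0, 1],
             "class_code": [1, 2, 1, 2, 1, 2]}
        )
        table = assemble_features(1, pheno, sar, samples)
        _, model = train_and_cv(table, seed=0, n_estimators=20, n_folds=3)
        with pytest.raises(SchemaError):
            predict_map(model, 5, pheno, sar)
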