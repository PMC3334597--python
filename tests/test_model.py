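"""Target calling, feature assembly, CV training and ranking metrics."""

import numpy as np
import pandas as pd
import pytest

from chromotif.model import (
    FeatureTable,
    assemble_features,
    call_targets,
    cv_train_evaluate,
    default_classifier,
    make_splits,
    ppv,
    predict_scores,
    roc_auc,
)
from chromotif.signals import GeneSignalMatrix

from .oracles import concordance_auc


class TestCallTargets:
    def test_strict_cutoff(self):
        pv = pd.DataFrame({"tf": [0.005, 0.01, 0.5, np.nan]}, index=list("abcd"))
        lab = call_targets(pv, 0.01)["tf"]
        assert lab["a"] == 1.0
        assert lab["b"] == 0.0  # boundary: P == cutoff is a non-target
        assert lab["c"] == 0.0
        assert np.isnan(lab["d"])

    def test_invalid_inputs(self):
        pv = pd.DataFrame({"tf": [0.5]})
        with pytest.raises(ValueError):
            call_targets(pv, 0.0)
        with pytest.raises(ValueError):
            call_targets(pd.DataFrame({"tf": [1.5]}), 0.01)


def toy_signals(n=200, n_mods=3, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    cols = {}
    for m in range(n_mods):
        for r in ("up1000", "down1000"):
            cols[f"mod{m}|{r}"] = rng.normal(size=n)
    return GeneSignalMatrix(pd.DataFrame(cols, index=pd.Index(genes, name="gene_id")))


class TestAssembleFeatures:
    def test_pssm_only_single_column(self):
        sig = toy_signals()
        genes = sig.values.index
        labels = pd.Series([1.0] * 20 + [0.0] * 180, index=genes)
        ms = pd.Series(np.arange(200, dtype=float), index=genes)
        t = assemble_features(sig, labels, motif_scores=ms, groups=("pssm",))
        assert list(t.features.columns) == ["pssm_score"]

    def test_hm_column_counting(self):
        sig = toy_signals(n_mods=14)
        genes = sig.values.index
        labels = pd.Series([1.0] * 20 + [0.0] * 180, index=genes)
        t = assemble_features(sig, labels, groups=("hm",), regions=("up1000", "down1000"))
        assert t.features.shape[1] == 28

    def test_expression_adds_one_column(self):
        sig = toy_signals(n_mods=2)
        genes = sig.values.index
        labels = pd.Series([1.0] * 20 + [0.0] * 180, index=genes)
        expr = pd.Series(np.random.default_rng(0).lognormal(size=200), index=genes)
        t0 = assemble_features(sig, labels, groups=("hm",))
        t1 = assemble_features(sig, labels, groups=("hm", "expression"), expression=expr)
        assert t1.features.shape[1] == t0.features.shape[1] + 1

    def test_all_labels_missing_errors(self):
        sig = toy_signals(n_mods=1)
        labels = pd.Series(np.nan, index=sig.values.index)
        with pytest.raises(ValueError):
            assemble_features(sig, labels, groups=("hm",))

    def test_single_class_rejected(self):
        sig = toy_signals(n_mods=1)
        labels = pd.Series(0.0, index=sig.values.index)
        with pytest.raises(ValueError):
            assemble_features(sig, labels, groups=("hm",))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert (roc["tpr"].diff().dropna() >= 0).all()

    def test_three_of_four_concordant_pairs(self):
        auc, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_matches_concordance_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = (rng.random(n) < 0.4).astype(float)
            if labels.sum() in (0, n):
                continue
            auc, roc = roc_auc(scores, labels)
            assert auc == pytest.approx(concordance_auc(scores, labels))
            # rank AUC equals trapezoidal area under the ROC points
            assert auc == pytest.approx(np.trapezoid(roc["tpr"], roc["fpr"]))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.3).astype(float)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPpv:
    def test_all_top_true(self):
        assert ppv([0.9, 0.8, 0.1], [1, 1, 0], 2) == 1.0

    def test_half_right(self):
        assert ppv([0.9, 0.8, 0.7], [1, 0, 1], 2) == 0.5

    def test_k_equals_n_is_prevalence(self, rng):
        labels = (rng.random(50) < 0.3).astype(float)
        scores = rng.normal(size=50)
        assert ppv(scores, labels, 50) == pytest.approx(labels.mean())

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            ppv([0.5], [1], 0)


def informative_table(n=300, seed=0, n_noise=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.15).astype(float)
    X = rng.normal(size=(n, 4 + n_noise))
    X[y == 1, :4] += 1.2
    genes = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    return FeatureTable(pd.DataFrame(X, index=genes), pd.Series(y, index=genes))


class TestCrossValidation:
    def test_too_few_positives(self):
        t = informative_table(n=60, seed=5)
        with pytest.raises(ValueError):
            cv_train_evaluate(t, repeats=2, min_positives=50)

    def test_informative_features_beat_chance(self):
        res = cv_train_evaluate(informative_table(), repeats=3, seed=0)
        assert res.auc > 0.8
        assert len(res.per_repeat_aucs) == 3

    def test_deterministic_given_seed(self):
        t = informative_table()
        r1 = cv_train_evaluate(t, repeats=2, seed=42)
        r2 = cv_train_evaluate(t, repeats=2, seed=42)
        assert r1.auc == r2.auc and r1.per_repeat_aucs == r2.per_repeat_aucs

    def test_noise_columns_barely_move_auc(self):
        base = cv_train_evaluate(informative_table(n=2000, seed=1), repeats=2, seed=0).auc
        noisy = cv_train_evaluate(informative_table(n=2000, seed=1, n_noise=10), repeats=2, seed=0).auc
        assert abs(base - noisy) < 0.05

    def test_no_test_fold_leakage(self):
        """A test-fold-only outlier cannot change a model fit on the train fold."""
        t = informative_table(n=120, seed=3)
        y = t.labels.to_numpy()
        splits = make_splits(y, 1, 2, np.random.default_rng(0))
        train_idx, test_idx = splits[0][0], splits[0][1]
        X = t.features.to_numpy().copy()
        model = default_classifier(seed=0)
        model.fit(X[train_idx], y[train_idx])
        before = predict_scores(model, X[train_idx])
        X2 = X.copy()
        X2[test_idx[0]] += 1e6  # absurd outlier confined to the test fold
        model2 = default_classifier(seed=0)
        model2.fit(X2[train_idx], y[train_idx])
        after = predict_scores(model2, X2[train_idx])
        assert np.array_equal(before, after)

    def test_scores_in_unit_interval(self):
        t = informative_table(n=150, seed=2)
        model = default_classifier(seed=0)
        model.fit(t.features.to_numpy(), t.labels.to_numpy())
        s = predict_scores(model, t.features.to_numpy())
        assert np.all((s >= 0) & (s <= 1))
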