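"""Target modification profiles, sensitivity clustering, differential profiles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from chromotif.profiles import (
    cluster_sensitivity,
    diff_mod_profiles,
    modification_correlation_network,
    target_mod_profiles,
)
from chromotif.signals import GeneSignalMatrix


def toy_signals(n=400, mods=("m1", "m2", "m3"), seed=0, regions=("up1000", "IR")):
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    cols = {f"{m}|{r}": rng.normal(size=n) for m in mods for r in regions}
    return GeneSignalMatrix(pd.DataFrame(cols, index=genes))


def toy_labels(signals, n_tfs=6, prevalence=0.1, seed=1):
    rng = np.random.default_rng(seed)
    genes = signals.values.index
    return pd.DataFrame(
        (rng.random((len(genes), n_tfs)) < prevalence).astype(float),
        index=genes, columns=[f"TF{i}" for i in range(n_tfs)],
    )


class TestTargetProfiles:
    def test_singleton_profile_equals_gene_signal(self):
        sig = toy_signals(n=30)
        labels = pd.DataFrame(0.0, index=sig.values.index, columns=["TF0"])
        labels.iloc[7, 0] = 1.0
        raw, _ = target_mod_profiles(labels, sig, regions=("up1000", "IR"), min_targets=1)
        expected = sig.values.iloc[7][raw.columns]
        assert np.allclose(raw.loc["TF0"].to_numpy(), expected.to_numpy())

    def test_matches_group_mean_oracle(self, rng):
        sig = toy_signals(n=300)
        labels = toy_labels(sig, n_tfs=8)
        raw, _ = target_mod_profiles(labels, sig, min_targets=5)
        for tf in raw.index:
            targets = labels.index[labels[tf] == 1.0]
            expected = sig.values.loc[targets, raw.columns].to_numpy().mean(axis=0)
            assert np.allclose(raw.loc[tf].to_numpy(), expected)

    def test_tf_without_targets_excluded(self):
        sig = toy_signals(n=100)
        labels = toy_labels(sig, n_tfs=3, prevalence=0.2)
        labels["TF2"] = 0.0
        with pytest.warns(UserWarning, match="TF2"):
            raw, _ = target_mod_profiles(labels, sig, min_targets=5)
        assert "TF2" not in raw.index

    def test_normalized_columns_standardized(self):
        sig = toy_signals(n=300)
        labels = toy_labels(sig, n_tfs=10, prevalence=0.15)
        _, norm = target_mod_profiles(labels, sig, min_targets=5)
        assert np.allclose(norm.mean(), 0.0, atol=1e-9)
        assert np.allclose(norm.std(ddof=0), 1.0, atol=1e-9)


def planted_profiles(n_tfs=40, n_mods=10, shift=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=0.3, size=(n_tfs, n_mods))
    truth = np.arange(n_tfs) < n_tfs // 2
    X[truth, : n_mods // 2] += shift * rng.choice([-1, 1], size=n_mods // 2)
    df = pd.DataFrame(X, index=[f"TF{i}" for i in range(n_tfs)])
    df = (df - df.mean()) / df.std(ddof=0)
    return df, truth


class TestClustering:
    def test_recovers_planted_groups(self):
        df, truth = planted_profiles()
        res = cluster_sensitivity(df, seed=0)
        pred = (res.labels == "sensitive").to_numpy()
        agreement = max((pred == truth).mean(), (pred != truth).mean())
        assert agreement >= 0.9

    def test_high_z_cluster_labeled_sensitive(self):
        df, truth = planted_profiles(shift=3.0)
        res = cluster_sensitivity(df, seed=0)
        pred = (res.labels == "sensitive").to_numpy()
        assert (pred == truth).mean() > 0.9  # not just any split: the loud one

    def test_identical_profiles_degenerate(self):
        df = pd.DataFrame(np.ones((8, 5)), index=[f"TF{i}" for i in range(8)])
        with pytest.warns(UserWarning):
            res = cluster_sensitivity(df, seed=0)
        assert (res.labels == "insensitive").all()

    def test_too_few_tfs(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(ValueError):
            cluster_sensitivity(df, k=2)

    def test_invariant_to_row_permutation(self):
        df, _ = planted_profiles(seed=3)
        res1 = cluster_sensitivity(df, seed=0)
        perm = df.sample(frac=1.0, random_state=7)
        res2 = cluster_sensitivity(perm, seed=0)
        assert res1.labels.sort_index().equals(res2.labels.sort_index())

    def test_variance_criterion_option(self):
        df, truth = planted_profiles(shift=3.0)
        res = cluster_sensitivity(df, seed=0, criterion="variance")
        pred = (res.labels == "sensitive").to_numpy()
        assert (pred == truth).mean() > 0.9


class TestDifferentialProfiles:
    def test_null_t_statistics_small(self):
        sig = toy_signals(n=1000, mods=tuple(f"m{i}" for i in range(10)), seed=4)
        labels = toy_labels(sig, n_tfs=4, prevalence=0.2, seed=5)
        t = diff_mod_profiles(labels, sig)
        assert (t.abs() < 4).to_numpy().mean() >= 0.99

    def test_planted_shift_detected(self):
        sig = toy_signals(n=1000, seed=6)
        labels = toy_labels(sig, n_tfs=1, prevalence=0.2, seed=7)
        tgt = labels.index[labels["TF0"] == 1.0]
        sig.values.loc[tgt, "m1|up1000"] += 1.0
        t = diff_mod_profiles(labels, sig)
        from scipy.stats import t as tdist
        assert t.loc["TF0", "m1|up1000"] > 0
        # with ~200 targets a +1 SD shift is overwhelming evidence
        assert t.loc["TF0", "m1|up1000"] > 5

    def test_zero_variance_left_missing(self):
        genes = pd.Index([f"g{i}" for i in range(40)], name="gene_id")
        sig = GeneSignalMatrix(pd.DataFrame({"m1|up1000": np.ones(40)}, index=genes))
        labels = pd.DataFrame({"TF0": [1.0] * 10 + [0.0] * 30}, index=genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = diff_mod_profiles(labels, sig, regions=("up1000",))
        assert np.isnan(t.loc["TF0", "m1|up1000"])

    def test_sign_is_target_minus_nontarget(self):
        sig = toy_signals(n=500, seed=8)
        labels = toy_labels(sig, n_tfs=1, prevalence=0.3, seed=9)
        tgt = labels.index[labels["TF0"] == 1.0]
        sig.values.loc[tgt, "m2|IR"] -= 2.0
        t = diff_mod_profiles(labels, sig)
        assert t.loc["TF0", "m2|IR"] < 0


class TestCorrelationNetwork:
    def base_profiles(self, seed=0, n_tfs=50, n_mods=6):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n_tfs, n_mods)),
                            columns=[f"m{i}" for i in range(n_mods)])

    def test_duplicated_column_gives_perfect_edge(self):
        df = self.base_profiles()
        df["dup"] = df["m0"]
        edges = modification_correlation_network(df)
        hit = edges[(edges.mod1 == "m0") & (edges.mod2 == "dup")]
        assert len(hit) == 1 and hit.iloc[0].r == pytest.approx(1.0)
        assert hit.iloc[0].sign == "positive"

    def test_negated_column_negative_class(self):
        df = self.base_profiles()
        df["neg"] = -df["m1"]
        edges = modification_correlation_network(df)
        hit = edges[(edges.mod1 == "m1") & (edges.mod2 == "neg")]
        assert hit.iloc[0].r == pytest.approx(-1.0)
        assert hit.iloc[0].sign == "negative"

    def test_independent_columns_rarely_connected(self):
        hits = 0
        for seed in range(10):
            edges = modification_correlation_network(self.base_profiles(seed=seed, n_tfs=100))
            hits += len(edges)
        assert hits == 0  # |r|>0.5 with n=100 independent rows is ~impossible

    def test_constant_column_excluded(self):
        df = self.base_profiles()
        df["const"] = 1.0
        edges = modification_correlation_network(df)
        assert not ((edges.mod1 == "const") | (edges.mod2 == "const")).any()

    def test_too_few_tfs(self):
        with pytest.raises(ValueError):
            modification_correlation_network(self.base_profiles(n_tfs=2))
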