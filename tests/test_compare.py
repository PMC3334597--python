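"""Enrichment statistics, co-regulation, bins, condition and site contrasts."""

import numpy as np
import pandas as pd
import pytest

from chromotif.compare import (
    bin_genome_and_label,
    condition_compare,
    coregulation_pairs,
    cross_pssm_aucs,
    fisher_enrichment,
    group_attribute_compare,
    verified_vs_nonverified,
)
from chromotif.model import FeatureTable, assemble_features, call_targets
from chromotif.profiles import SensitivityLabels
from chromotif.signals import build_gene_signal_matrix
from chromotif.pipeline import promoter_motif_scores

from .oracles import fisher_greater_exact


class TestFisherEnrichment:
    def test_balanced_two_by_two(self):
        _, p = fisher_enrichment([[1, 1], [1, 1]])
        assert p == pytest.approx(5 / 6)

    def test_perfect_diagonal(self):
        _, p = fisher_enrichment([[5, 0], [0, 5]])
        assert p == pytest.approx(1 / 252)

    def test_chromatin_modifier_example(self):
        # 20/35 modifier-interacting TFs sensitive vs 68/203 overall
        odds, p = fisher_enrichment([[20, 15], [48, 120]])
        assert round(p, 3) == 0.001
        assert odds > 1

    def test_matches_exact_enumeration(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            _, p = fisher_enrichment([[a, b], [c, d]])
            assert p == pytest.approx(float(fisher_greater_exact(a, b, c, d)), rel=1e-10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([[0, 0], [0, 0]])

    def test_two_sided_option(self):
        from scipy.stats import fisher_exact
        t = [[12, 3], [5, 10]]
        _, p = fisher_enrichment(t, alternative="two-sided")
        assert p == pytest.approx(fisher_exact(t, alternative="two-sided")[1])


class TestCoregulation:
    def test_identical_sets_highly_significant(self):
        sets = {"A": set(range(50)), "B": set(range(50))}
        pairs, _ = coregulation_pairs(sets, universe_size=2000)
        assert len(pairs) == 1 and pairs.iloc[0].p < 1e-20

    def test_p_monotone_in_overlap(self):
        # fixed margins, growing intersection => smaller P
        ps = []
        for k in (5, 10, 20, 40):
            a, b, c = k, 50 - k, 50 - k
            d = 2000 - a - b - c
            _, p = fisher_enrichment([[a, b], [c, d]])
            ps.append(p)
        assert ps == sorted(ps, reverse=True)

    def test_pair_count_bounded(self, rng):
        sets = {f"T{i}": set(rng.choice(2000, size=100, replace=False)) for i in range(6)}
        pairs, _ = coregulation_pairs(sets, universe_size=2000)
        assert len(pairs) <= 15

    def test_class_composition_counts(self):
        sets = {"A": set(range(50)), "B": set(range(50)), "C": set(range(100, 150))}
        lab = SensitivityLabels(pd.Series({"A": "sensitive", "B": "sensitive", "C": "insensitive"}), 0, 1, 0.0)
        pairs, comp = coregulation_pairs(sets, universe_size=2000, sensitivity=lab)
        assert comp["SS"] == 1 and comp["II"] == 0 and comp["SI"] == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            coregulation_pairs({"A": set(), "B": set()}, universe_size=0)


class TestBins:
    def test_counting(self):
        bins = bin_genome_and_label({"c": 1000}, pd.DataFrame(columns=["contig", "start", "end"]))
        assert len(bins) == 10 and (bins.label == 0).all()

    def test_peak_overlap_rule(self):
        peaks = pd.DataFrame({"contig": ["c"], "start": [250], "end": [420]})
        bins = bin_genome_and_label({"c": 1000}, peaks)
        positive = bins[bins.label == 1]
        assert list(positive.start) == [200, 300, 400]

    def test_matches_overlap_enumeration(self, rng):
        length = 5000
        peaks = []
        for _ in range(12):
            s = int(rng.integers(0, length - 10))
            peaks.append(("c", s, s + int(rng.integers(5, 300))))
        pk = pd.DataFrame(peaks, columns=["contig", "start", "end"])
        bins = bin_genome_and_label({"c": length}, pk)
        for b in bins.itertuples():
            expected = any(min(b.end, e) - max(b.start, s) >= 1 for _, s, e in peaks)
            assert bool(b.label) == expected

    def test_invariant_under_peak_splitting(self):
        pk1 = pd.DataFrame({"contig": ["c"], "start": [130], "end": [470]})
        pk2 = pd.DataFrame({"contig": ["c"] * 3, "start": [130, 250, 330], "end": [250, 330, 470]})
        b1 = bin_genome_and_label({"c": 1000}, pk1)
        b2 = bin_genome_and_label({"c": 1000}, pk2)
        assert (b1.label == b2.label).all()

    def test_trailing_partial_bin_kept(self):
        bins = bin_genome_and_label({"c": 1050}, pd.DataFrame(columns=["contig", "start", "end"]))
        assert len(bins) == 11 and bins.iloc[-1].end == 1050

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            bin_genome_and_label({}, pd.DataFrame(columns=["contig", "start", "end"]))


class TestGroupCompare:
    def test_planted_shift_detected_often(self, rng):
        hits = 0
        for s in range(40):
            r = np.random.default_rng(s)
            lab = SensitivityLabels(
                pd.Series(["sensitive"] * 30 + ["insensitive"] * 30,
                          index=[f"T{i}" for i in range(60)]), 0, 1, 0.0)
            attr = pd.Series(np.concatenate([r.normal(1.0, 1, 30), r.normal(0, 1, 30)]),
                             index=lab.labels.index)
            _, p = group_attribute_compare(lab, attr)
            hits += p < 0.05
        assert hits >= 32  # >= 80% power at a 1 SD shift, n=30/30

    def test_null_rejection_rate_calibrated(self):
        rejections = 0
        for s in range(200):
            r = np.random.default_rng(s)
            lab = SensitivityLabels(
                pd.Series(["sensitive"] * 25 + ["insensitive"] * 25,
                          index=[f"T{i}" for i in range(50)]), 0, 1, 0.0)
            attr = pd.Series(r.normal(size=50), index=lab.labels.index)
            _, p = group_attribute_compare(lab, attr)
            rejections += p < 0.05
        assert rejections / 200 <= 0.06

    def test_empty_group_rejected(self):
        lab = SensitivityLabels(pd.Series({"A": "sensitive", "B": "sensitive"}), 0, 1, 0.0)
        with pytest.raises(ValueError):
            group_attribute_compare(lab, pd.Series({"A": 1.0, "B": 2.0}))


class TestConditionCompare:
    def test_identical_features_near_tie(self, world_factory):
        w = world_factory(n_genes=800, n_tfs=4, seed=21, two_conditions=False)
        sig = build_gene_signal_matrix(w.annotations, w.tracks["A"], widths=(1000,),
                                       contig_lengths=w.contig_lengths)
        tf = w.tf_names[0]
        lab = call_targets(w.pvalues["A"])[tf]
        ms = promoter_motif_scores(w, w.pssms[0])
        t = assemble_features(sig, lab, motif_scores=ms, regions=("up1000", "down1000"))
        r1, r2 = condition_compare(t, t, repeats=3, seed=0)
        assert abs(r1.auc - r2.auc) < 1e-12  # same features, same splits

    def test_mismatched_gene_sets_rejected(self):
        genes = pd.Index([f"g{i}" for i in range(60)], name="gene_id")
        rngl = np.random.default_rng(0)
        y = pd.Series((rngl.random(60) < 0.3).astype(float), index=genes)
        X = pd.DataFrame(rngl.normal(size=(60, 3)), index=genes)
        t1 = FeatureTable(X, y)
        t2 = FeatureTable(X.iloc[:50], y.iloc[:50])
        with pytest.raises(ValueError):
            condition_compare(t1, t2)


class TestVerifiedSites:
    def _toy(self, nonv_start):
        hits = pd.DataFrame({
            "contig": ["c", "c"], "start": [1000, nonv_start],
            "end": [1010, nonv_start + 10], "gene_id": ["gv", "gn"],
        })
        verified = pd.DataFrame({"contig": ["c"], "start": [1000], "end": [1010]})
        pvals = pd.Series({"gv": 0.001, "gn": 0.9})
        probes = pd.DataFrame({"contig": "c", "start": np.arange(0, 10000, 60),
                               "end": np.arange(60, 10060, 60), "value": 0.0})
        from chromotif.signals import SignalTrack, WINDOWED
        track = SignalTrack({"m": probes}, {"m": WINDOWED})
        return hits, verified, pvals, track

    def test_exclusion_boundary(self):
        # 1 kb away: inside the 2-kb exclusion zone -> filtered out
        hits, ver, pv, track = self._toy(2000)
        with pytest.raises(ValueError, match="survive"):
            verified_vs_nonverified(hits, ver, pv, track)
        # 3 kb away: retained
        hits, ver, pv, track = self._toy(4010)
        res = verified_vs_nonverified(hits, ver, pv, track)
        assert res.n_nonverified == 1
        assert res.filter_counts["candidate_hits"] == 2

    def test_p_filter_applied(self):
        hits, ver, pv, track = self._toy(4010)
        pv["gn"] = 0.001  # bound gene: not a usable non-verified site
        with pytest.raises(ValueError):
            verified_vs_nonverified(hits, ver, pv, track)


class TestCrossPssmShape:
    def test_matrix_square_with_diagonal(self, world_factory):
        w = world_factory(n_genes=500, n_tfs=3, seed=31, sensitive_fraction=0.0,
                          motif_plant_prob=1.0, site_depletion=0.0)
        sig = build_gene_signal_matrix(w.annotations, w.tracks["A"], widths=(1000,),
                                       contig_lengths=w.contig_lengths)
        lab = call_targets(w.pvalues["A"])
        ms = {p.id: promoter_motif_scores(w, p) for p in w.pssms}
        tables = {}
        for tf in w.tf_names:
            for ptf in w.tf_names:
                tables[(tf, ptf)] = assemble_features(
                    sig, lab[tf], motif_scores=ms[ptf], regions=("up1000", "down1000"))
        mat, flagged = cross_pssm_aucs(lab, tables, tfs=w.tf_names, repeats=2, seed=0, min_positives=5)
        assert mat.shape == (3, 3)
        assert mat.notna().to_numpy().all()
        assert all(0 <= v <= 1 for v in mat.to_numpy().ravel())
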