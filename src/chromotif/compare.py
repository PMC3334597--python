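"""Cross-PSSM cooperativity, condition matching, site contrasts, enrichment.

These are the downstream analyses built on the target-prediction model:

* **cross-PSSM scan** — predict TF A's targets with every TF's motif
  feature; a cell beating A's own-motif AUC by a margin suggests A binds
  indirectly through the other TF (piggy-back cooperation).
* **condition comparison** — the same labels scored by models whose
  histone features come from the matched vs a mismatched growth
  condition, on identical CV splits.
* **verified vs non-verified site contrast** — per-modification Welch t
  between ChIP-verified motif sites and motif matches the ChIP calls
  unbound (nucleosome-depletion-style signatures).
* **bin-level site prediction** — tile the genome into fixed-width bins
  labeled by peak overlap, for ChIP-seq style binding-site models.
* **Fisher enrichment / co-regulation / group comparisons** — the
  contingency and rank statistics behind the class-attribute analyses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu, ttest_ind

from .model import FeatureTable, cv_train_evaluate, make_splits, EvalResult
from .profiles import SensitivityLabels
from .signals import SignalTrack

COOPERATIVITY_MARGIN = 0.02  # AUC gain needed to flag a cross-PSSM pair
SITE_EXCLUSION_BP = 2000  # non-verified sites must be this far from any verified site
NONTARGET_P = 0.4  # ChIP P-value floor for calling a motif match unbound


def cross_pssm_aucs(
    labels: pd.DataFrame,
    feature_tables: dict[tuple[str, str], FeatureTable],
    tfs: list[str] | None = None,
    repeats: int = 10,
    seed: int = 0,
    margin: float = COOPERATIVITY_MARGIN,
    min_positives: int = 10,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Mean CV AUC for every (target TF, predictor PSSM) pair.

    ``feature_tables[(tf, pssm_tf)]`` holds the features (histone signals
    + pssm_tf's motif score) labeled with tf's targets.  Returns the AUC
    matrix (rows = target TF, columns = predictor PSSM; diagonal = own
    motif) and pairs (A, B, gain) where B's motif beats A's own by more
    than ``margin``.  Cells whose CV fails are left missing.
    """
    if tfs is None:
        tfs = sorted({t for t, _ in feature_tables})
    if len(tfs) < 2:
        raise ValueError("cross-PSSM scan needs at least 2 TFs")
    mat = pd.DataFrame(np.nan, index=pd.Index(tfs, name="target_tf"), columns=pd.Index(tfs, name="pssm_tf"))
    for tf in tfs:
        for pssm_tf in tfs:
            table = feature_tables.get((tf, pssm_tf))
            if table is None:
                continue
            try:
                res = cv_train_evaluate(table, repeats=repeats, seed=seed, min_positives=min_positives)
            except ValueError as exc:
                warnings.warn(f"cross-PSSM cell ({tf}, {pssm_tf}) skipped: {exc}")
                continue
            mat.loc[tf, pssm_tf] = res.auc
    flagged = []
    for tf in tfs:
        own = mat.loc[tf, tf]
        if np.isnan(own):
            continue
        for pssm_tf in tfs:
            if pssm_tf == tf:
                continue
            gain = mat.loc[tf, pssm_tf] - own
            if gain > margin:
                flagged.append((tf, pssm_tf, float(gain)))
    return mat, flagged


def condition_compare(
    table_matched: FeatureTable,
    table_mismatched: FeatureTable,
    repeats: int = 10,
    seed: int = 0,
    min_positives: int = 10,
) -> tuple[EvalResult, EvalResult]:
    """Evaluate two feature tables against the same labels on paired splits.

    Both tables must cover the same genes with the same labels (the
    targets of the condition of interest); only the feature values differ
    (histone signals from the matched vs the mismatched condition).
    Returns (matched, mismatched) evaluation results.
    """
    if not table_matched.features.index.equals(table_mismatched.features.index):
        raise ValueError("the two condition tables must cover the same genes in the same order")
    if not table_matched.labels.equals(table_mismatched.labels):
        raise ValueError("the two condition tables must share labels")
    y = table_matched.labels.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    splits = make_splits(y, repeats, 2, rng)
    res_m = cv_train_evaluate(table_matched, seed=seed, splits=splits, min_positives=min_positives)
    res_x = cv_train_evaluate(table_mismatched, seed=seed, splits=splits, min_positives=min_positives)
    return res_m, res_x


@dataclass
class SiteContrast:
    """Per-modification verified vs non-verified site comparison."""

    t_stats: pd.Series  # positive = higher at verified sites
    p_values: pd.Series
    n_verified: int
    n_nonverified: int
    filter_counts: dict[str, int]


def _site_signal(track: SignalTrack, contig: str, start: int, end: int, mod: str, max_widen: int = 500) -> float:
    """Mean of probes covering a site; widened to the nearest probe if uncovered."""
    idx = track.index_for(mod, contig)
    vals = idx.overlapping(start, end)
    if len(vals):
        return float(vals.mean())
    # widen to nearest covering probe on either side
    left = np.searchsorted(idx.starts, start, side="left") - 1
    cands = []
    if left >= 0 and start - idx.ends[left] <= max_widen:
        cands.append(idx.values[left])
    right = np.searchsorted(idx.starts, end, side="left")
    if right < len(idx.starts) and idx.starts[right] - end <= max_widen:
        cands.append(idx.values[right])
    return float(np.mean(cands)) if cands else float("nan")


def verified_vs_nonverified(
    hits: pd.DataFrame,
    verified: pd.DataFrame,
    gene_pvalues: pd.Series,
    track: SignalTrack,
    modifications: list[str] | None = None,
    nontarget_p: float = NONTARGET_P,
    exclusion_bp: int = SITE_EXCLUSION_BP,
) -> SiteContrast:
    """Contrast modification signals at ChIP-verified vs unbound motif sites.

    ``hits`` are genome-wide motif matches (contig, start, end, gene_id);
    ``verified`` are ChIP-supported sites (contig, start, end).
    Non-verified sites are motif matches whose associated gene has ChIP
    P > ``nontarget_p`` and which lie at least ``exclusion_bp`` from every
    verified site.  Per modification, site-level mean probe signals are
    compared with a Welch t-test (positive t = higher at verified sites).
    """
    if modifications is None:
        modifications = track.modifications
    if len(verified) == 0:
        raise ValueError("no verified sites supplied")
    counts = {"candidate_hits": len(hits)}
    pv = hits["gene_id"].map(gene_pvalues)
    nonv = hits[pv > nontarget_p].copy()
    counts["p_filtered"] = len(nonv)
    ver_by_contig = {c: g[["start", "end"]].to_numpy() for c, g in verified.groupby("contig")}

    def far_from_verified(row) -> bool:
        iv = ver_by_contig.get(row["contig"])
        if iv is None:
            return True
        return bool(np.all((row["start"] - iv[:, 1] >= exclusion_bp) | (iv[:, 0] - row["end"] >= exclusion_bp)))

    nonv = nonv[nonv.apply(far_from_verified, axis=1)]
    counts["distance_filtered"] = len(nonv)
    if len(nonv) == 0:
        raise ValueError("no non-verified sites survive the filters")
    t_stats, p_values = {}, {}
    for mod in modifications:
        v_sig = np.array([_site_signal(track, r.contig, r.start, r.end, mod) for r in verified.itertuples()])
        n_sig = np.array([_site_signal(track, r.contig, r.start, r.end, mod) for r in nonv.itertuples()])
        v_sig, n_sig = v_sig[~np.isnan(v_sig)], n_sig[~np.isnan(n_sig)]
        if len(v_sig) < 2 or len(n_sig) < 2:
            t_stats[mod], p_values[mod] = np.nan, np.nan
            continue
        t, p = ttest_ind(v_sig, n_sig, equal_var=False)
        t_stats[mod], p_values[mod] = float(t), float(p)
    return SiteContrast(
        t_stats=pd.Series(t_stats),
        p_values=pd.Series(p_values),
        n_verified=len(verified),
        n_nonverified=len(nonv),
        filter_counts=counts,
    )


def bin_genome_and_label(
    contig_lengths: dict[str, int],
    peaks: pd.DataFrame,
    width: int = 100,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Tile contigs into fixed-width bins labeled by peak overlap.

    Returns (contig, start, end, label) with label 1 iff the bin overlaps
    any peak by at least ``min_overlap`` bp.  The trailing partial bin of
    each contig is kept so every base is covered.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if not contig_lengths:
        raise ValueError("empty genome")
    frames = []
    for contig, length in contig_lengths.items():
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        label = np.zeros(len(starts), dtype=int)
        sub = peaks[peaks["contig"] == contig] if len(peaks) else peaks
        for p in sub.itertuples():
            ov_start = np.maximum(starts, p.start)
            ov_end = np.minimum(ends, p.end)
            label[(ov_end - ov_start) >= min_overlap] = 1
        frames.append(pd.DataFrame({"contig": contig, "start": starts, "end": ends, "label": label}))
    return pd.concat(frames, ignore_index=True)


def fisher_enrichment(table: np.ndarray | list, alternative: str = "greater") -> tuple[float, float]:
    """One-sided (default) Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p).  The one-sided "greater" P is the exact
    hypergeometric upper tail of the top-left cell given the margins; the
    two-sided variant delegates to scipy's fisher_exact.  The sample odds
    ratio is (a*d)/(b*c), infinite when b*c = 0 and a*d > 0.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    if alternative == "greater":
        p = float(hypergeom.sf(a - 1, n, a + b, a + c))
    elif alternative == "two-sided":
        _, p = fisher_exact(t, alternative="two-sided")
        p = float(p)
    else:
        raise ValueError(f"unsupported alternative {alternative!r}")
    return odds, min(p, 1.0)


def coregulation_pairs(
    target_sets: dict[str, set],
    universe_size: int,
    alpha: float = 0.05,
    sensitivity: SensitivityLabels | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """TF pairs whose target sets overlap more than the hypergeometric null.

    Per pair, a one-sided Fisher test on [[|A∩B|, |A\\B|], [|B\\A|, rest]];
    pairs with P < alpha are reported.  When sensitivity labels are given,
    the significant pairs are partitioned into SS / II / SI compositions.
    """
    tfs = sorted(target_sets)
    if len(tfs) < 2:
        raise ValueError("need at least 2 TFs")
    if universe_size <= 0:
        raise ValueError("empty universe")
    rows = []
    for t1, t2 in itertools.combinations(tfs, 2):
        s1, s2 = target_sets[t1], target_sets[t2]
        inter = len(s1 & s2)
        a, b, c = inter, len(s1) - inter, len(s2) - inter
        d = universe_size - a - b - c
        if d < 0:
            raise ValueError("target sets exceed the universe")
        _, p = fisher_enrichment([[a, b], [c, d]])
        if p < alpha:
            rows.append((t1, t2, inter, p))
    pairs = pd.DataFrame(rows, columns=["tf1", "tf2", "overlap", "p"])
    comp = {"SS": 0, "II": 0, "SI": 0}
    if sensitivity is not None and len(pairs):
        lab = sensitivity.labels
        for r in pairs.itertuples():
            s = sorted(lab.get(x, "insensitive")[0].upper() for x in (r.tf1, r.tf2))
            comp["".join(s) if s[0] == s[1] else "SI"] += 1
    return pairs, comp


def group_attribute_compare(labels: SensitivityLabels, attribute: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of an attribute between the two classes.

    Compares sensitive vs insensitive TFs on any per-TF quantity (target
    count, PPI degree, expression, hierarchy level).  Returns (U, p).
    """
    a = attribute.reindex(labels.sensitive).dropna()
    b = attribute.reindex(labels.insensitive).dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sensitivity classes must be nonempty")
    u, p = mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)
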