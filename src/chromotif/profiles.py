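"""Histone-sensitivity profiling of transcription factors.

For each TF with enough called targets we average the selected
modification signals (1-kb upstream windowed set plus intergenic
acetylation set) over its targets, giving a *target modification
profile*.  Profiles are z-normalized per modification across TFs and
clustered with k-means into two groups; the cluster whose profiles swing
further from the mean (larger mean |z|) is labeled *histone-sensitive*,
the other *histone-insensitive*.  A complementary *differential profile*
gives, per modification, the Welch t-statistic contrasting targets with
non-targets, and a correlation network over those differential profiles
exposes redundancy among modifications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from sklearn.cluster import KMeans

from .signals import GeneSignalMatrix

MIN_TARGETS = 10
DEFAULT_PROFILE_REGIONS = ("up1000", "IR")
CORRELATION_THRESHOLD = 0.5


def _profile_columns(signals: GeneSignalMatrix, regions: tuple[str, ...]) -> list[str]:
    cols = signals.columns_for(list(regions))
    if not cols:
        raise ValueError(f"no signal columns for regions {regions}")
    return cols


def target_mod_profiles(
    labels: pd.DataFrame,
    signals: GeneSignalMatrix,
    regions: tuple[str, ...] = DEFAULT_PROFILE_REGIONS,
    min_targets: int = MIN_TARGETS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean target signal per (TF, modification), raw and z-normalized.

    ``labels`` is the binarized gene x TF target matrix.  Returns
    ``(raw, normalized)`` DataFrames of shape TFs x modifications; TFs
    with fewer than ``min_targets`` labeled targets with signal are
    excluded with a warning.  Normalization is per modification across
    TFs (mean 0, SD 1).
    """
    cols = _profile_columns(signals, regions)
    rows, kept = [], []
    for tf in labels.columns:
        lab = labels[tf].dropna()
        targets = lab.index[lab == 1.0].intersection(signals.values.index)
        if len(targets) < min_targets:
            warnings.warn(f"TF {tf}: {len(targets)} targets < {min_targets}; excluded from profiles")
            continue
        rows.append(signals.values.loc[targets, cols].mean())
        kept.append(tf)
    if not rows:
        raise ValueError("no TF has enough targets for a profile")
    raw = pd.DataFrame(rows, index=pd.Index(kept, name="tf"))
    sd = raw.std(ddof=0)
    sd = sd.replace(0.0, np.nan)
    norm = (raw - raw.mean()) / sd
    norm = norm.fillna(0.0)  # constant modification columns carry no signal
    return raw, norm


@dataclass
class SensitivityLabels:
    """Two-way histone-sensitivity classification with clustering provenance."""

    labels: pd.Series  # tf -> "sensitive" | "insensitive"
    seed: int
    restarts: int
    inertia: float

    @property
    def sensitive(self) -> list[str]:
        return list(self.labels.index[self.labels == "sensitive"])

    @property
    def insensitive(self) -> list[str]:
        return list(self.labels.index[self.labels == "insensitive"])


def cluster_sensitivity(
    normalized_profiles: pd.DataFrame,
    k: int = 2,
    restarts: int = 50,
    seed: int = 0,
    criterion: str = "mean_abs",
) -> SensitivityLabels:
    """k-means (k=2) on normalized profiles; high-|z| cluster is 'sensitive'.

    ``criterion`` selects how "larger variation" is operationalized:
    "mean_abs" (default) compares cluster means of |z| averaged over
    modifications; "variance" compares mean per-TF profile variance.
    Degenerate input (all profiles identical) yields all-insensitive with
    a warning.
    """
    X = normalized_profiles.to_numpy(dtype=float)
    if len(X) < 2 * k:
        raise ValueError(f"need at least {2 * k} TFs to form {k} clusters")
    if np.allclose(X, X[0]):
        warnings.warn("all profiles identical; labeling every TF insensitive")
        return SensitivityLabels(
            pd.Series("insensitive", index=normalized_profiles.index), seed, restarts, 0.0
        )
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    assign = km.fit_predict(X)
    if criterion == "variance":
        stat = np.array([X[assign == c].var(axis=1).mean() for c in range(k)])
    else:
        stat = np.array([np.abs(X[assign == c]).mean() for c in range(k)])
    sensitive_cluster = int(np.argmax(stat))
    lab = pd.Series(
        np.where(assign == sensitive_cluster, "sensitive", "insensitive"),
        index=normalized_profiles.index,
    )
    return SensitivityLabels(lab, seed, restarts, float(km.inertia_))


def diff_mod_profiles(
    labels: pd.DataFrame,
    signals: GeneSignalMatrix,
    regions: tuple[str, ...] = DEFAULT_PROFILE_REGIONS,
    min_group: int = 2,
) -> pd.DataFrame:
    """Welch t-statistic per (TF, modification): targets vs non-targets.

    Positive t means the modification is higher at target genes.
    Degenerate cases (a group below ``min_group`` or zero variance in
    both groups) are left missing with a warning.
    """
    cols = _profile_columns(signals, regions)
    out = pd.DataFrame(np.nan, index=pd.Index(labels.columns, name="tf"), columns=cols)
    for tf in labels.columns:
        lab = labels[tf].dropna()
        genes = lab.index.intersection(signals.values.index)
        lab = lab.loc[genes]
        tgt = signals.values.loc[genes[lab == 1.0], cols].to_numpy(dtype=float)
        non = signals.values.loc[genes[lab == 0.0], cols].to_numpy(dtype=float)
        if len(tgt) < min_group or len(non) < min_group:
            warnings.warn(f"TF {tf}: group below {min_group} genes; differential profile missing")
            continue
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, _ = ttest_ind(tgt, non, equal_var=False, nan_policy="omit")
        out.loc[tf] = t
    return out


def modification_correlation_network(
    diff_profiles: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
) -> pd.DataFrame:
    """Pearson correlation edges between modifications across TF profiles.

    Returns an edge list (mod1, mod2, r, sign) for pairs with |r| above
    the threshold; constant (or all-missing) columns are excluded.
    """
    if len(diff_profiles) < 3:
        raise ValueError("need at least 3 TFs to correlate modifications")
    mat = diff_profiles.dropna(axis=0, how="any")
    keep = [c for c in mat.columns if mat[c].std(ddof=0) > 0]
    mat = mat[keep]
    corr = mat.corr()
    edges = []
    cols = list(mat.columns)
    for i, m1 in enumerate(cols):
        for m2 in cols[i + 1 :]:
            r = float(corr.loc[m1, m2])
            if abs(r) > threshold:
                edges.append((m1, m2, r, "positive" if r > 0 else "negative"))
    return pd.DataFrame(edges, columns=["mod1", "mod2", "r", "sign"])
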