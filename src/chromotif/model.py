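"""Target calling, feature assembly, SVM training, ROC/AUC/PPV evaluation.

The classifier mirrors the original setup: a radial-basis-kernel SVM with
e1071-style defaults (gamma = 1/n_features, C = 1), trained per TF on a
feature table combining the promoter cumulative motif score with
per-region histone-modification signals, and evaluated by repeated
two-fold cross-validation.  Feature standardization is fit on the
training fold only (wrapped in a sklearn Pipeline) so no test-fold
statistics leak into the transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .signals import GeneSignalMatrix

DEFAULT_CUTOFF = 0.01  # ChIP binding P-value cutoff for target calling
DEFAULT_REPEATS = 50
DEFAULT_FOLDS = 2
MIN_POSITIVES = 10


def call_targets(pvalues: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Binarize a gene x TF ChIP P-value matrix at a cutoff.

    A gene is a target iff P < cutoff (strict); missing P-values stay
    missing.  Returns floats {1.0, 0.0, NaN}.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    bad = pvalues.lt(0) | pvalues.gt(1)
    if bad.any().any():
        raise ValueError("P-values must lie in [0, 1]")
    return pvalues.lt(cutoff).astype(float).mask(pvalues.isna())


@dataclass
class FeatureTable:
    """Per-gene predictors plus binary labels for one TF."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.features.shape[1] < 1:
            raise ValueError("feature table needs at least one feature column")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values after imputation")
        classes = set(self.labels.unique())
        if not classes <= {0.0, 1.0}:
            raise ValueError("labels must be binary")
        if len(classes) < 2:
            raise ValueError("both classes must be present")


def assemble_features(
    signals: GeneSignalMatrix,
    labels: pd.Series,
    motif_scores: pd.Series | None = None,
    groups: tuple[str, ...] = ("hm", "pssm"),
    regions: tuple[str, ...] = ("up1000", "down1000"),
    expression: pd.Series | None = None,
    max_missing: float = 0.5,
) -> FeatureTable:
    """Build the per-gene feature table for one TF.

    ``groups`` selects feature channels: "hm" (histone signals over the
    given regions), "pssm" (cumulative motif score; requires
    ``motif_scores``), "expression" (log-transformed expression level).
    Genes without a label or missing more than ``max_missing`` of the
    selected columns are dropped; remaining gaps are mean-imputed per
    column.  Standardization is left to the CV pipeline.
    """
    blocks: list[pd.DataFrame] = []
    if "hm" in groups:
        cols = signals.columns_for(list(regions))
        if not cols:
            raise ValueError(f"no signal columns for regions {regions}")
        blocks.append(signals.values[cols])
    if "pssm" in groups:
        if motif_scores is None:
            raise ValueError("'pssm' group requested but no motif scores given")
        blocks.append(motif_scores.rename("pssm_score").to_frame())
    if "expression" in groups:
        if expression is None:
            raise ValueError("'expression' group requested but no expression given")
        blocks.append(np.log1p(expression.clip(lower=0)).rename("expression").to_frame())
    if not blocks:
        raise ValueError("no feature groups selected")
    feats = pd.concat(blocks, axis=1, join="outer")
    labels = labels.dropna()
    genes = feats.index.intersection(labels.index)
    if len(genes) == 0:
        raise ValueError("no genes shared between features and labels")
    feats = feats.loc[genes]
    keep = feats.isna().mean(axis=1) <= max_missing
    feats = feats[keep]
    feats = feats.fillna(feats.mean())
    feats = feats.dropna(axis=1, how="any")  # columns that were all-missing
    return FeatureTable(feats, labels.loc[feats.index].astype(float))


def default_classifier(seed: int = 0) -> Pipeline:
    """Train-fold standardization + RBF SVM with e1071-style defaults.

    gamma="auto" is 1/n_features and C=1, matching the defaults of the
    reference SVM implementation.  Classes are inverse-prevalence
    weighted: target sets are typically ~5% of genes, and an unweighted
    hinge loss at C=1 collapses toward the majority class.
    ``predict_scores`` maps the decision function through a logistic
    squash so scores land in [0, 1]; the map is strictly monotone, so
    ranking metrics are unaffected.
    """
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", gamma="auto", C=1.0, class_weight="balanced", random_state=seed)),
        ]
    )


def predict_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Classifier scores in [0, 1] (logistic of the SVM margin)."""
    margin = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-margin))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Rank-based AUC (ties count half) plus ROC points.

    The AUC is the Mann-Whitney statistic: the probability that a random
    positive outranks a random negative.  ROC points (1-specificity,
    sensitivity) come from sklearn and integrate (trapezoid) to the same
    area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return float(auc), roc


def ppv(scores: np.ndarray, labels: np.ndarray, top_k: int) -> float:
    """Fraction of the top_k scored items that are true positives.

    Ties are broken by stable original order.  At top_k = n this equals
    the class prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if not 1 <= top_k <= len(scores):
        raise ValueError("top_k must be in [1, n]")
    order = np.argsort(-scores, kind="stable")
    return float(labels[order[:top_k]].sum() / top_k)


@dataclass
class EvalResult:
    """Cross-validated performance for one model/TF."""

    auc: float
    per_repeat_aucs: list[float]
    roc: pd.DataFrame
    ppv_at: float
    top_k: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC out of [0, 1]")


def make_splits(
    labels: np.ndarray,
    repeats: int,
    folds: int,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> list[list[np.ndarray]]:
    """Random equal-size fold index sets, redrawn until every fold has both classes."""
    n = len(labels)
    splits = []
    for _ in range(repeats):
        for attempt in range(max_redraws + 1):
            perm = rng.permutation(n)
            fold_idx = np.array_split(perm, folds)
            if all(len(np.unique(labels[f])) == 2 for f in fold_idx):
                splits.append(fold_idx)
                break
        else:
            raise ValueError("could not draw folds containing both classes")
    return splits


def cv_train_evaluate(
    table: FeatureTable,
    repeats: int = DEFAULT_REPEATS,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    min_positives: int = MIN_POSITIVES,
    classifier_factory=default_classifier,
    splits: list[list[np.ndarray]] | None = None,
) -> EvalResult:
    """Repeated k-fold cross-validation of the SVM on one feature table.

    Each repeat randomly splits genes into ``folds`` equal parts; each
    part is scored by a model trained on the rest, and the repeat's AUC is
    the mean over held-out folds.  The headline AUC is the mean over
    repeats.  Pass precomputed ``splits`` to compare two feature sets on
    identical partitions (paired evaluation).
    """
    X = table.features.to_numpy(dtype=float)
    y = table.labels.to_numpy(dtype=float)
    n_pos = int(y.sum())
    if n_pos < min_positives:
        raise ValueError(f"only {n_pos} positives; need >= {min_positives}")
    if n_pos == len(y):
        raise ValueError("no negatives present")
    rng = np.random.default_rng(seed)
    if splits is None:
        splits = make_splits(y, repeats, folds, rng)
    per_repeat: list[float] = []
    first_scores: np.ndarray | None = None
    for fold_idx in splits:
        fold_aucs = []
        all_scores = np.empty(len(y))
        for k, test_idx in enumerate(fold_idx):
            train_idx = np.concatenate([f for j, f in enumerate(fold_idx) if j != k])
            model = classifier_factory(seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[train_idx], y[train_idx])
            s = predict_scores(model, X[test_idx])
            all_scores[test_idx] = s
            auc, _ = roc_auc(s, y[test_idx])
            fold_aucs.append(auc)
        per_repeat.append(float(np.mean(fold_aucs)))
        if first_scores is None:
            first_scores = all_scores
    mean_auc = float(np.mean(per_repeat))
    _, roc = roc_auc(first_scores, y)
    top_k = n_pos
    return EvalResult(
        auc=mean_auc,
        per_repeat_aucs=per_repeat,
        roc=roc,
        ppv_at=ppv(first_scores, y, top_k),
        top_k=top_k,
    )
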