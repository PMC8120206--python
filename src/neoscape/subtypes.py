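"""Probability-gated three-class molecular-subtype classifier.

Signature genes are extracted per class by pairwise rank-sum tests
(BH-adjusted p < 0.05 against *both* other classes, with a higher median in
the class in both comparisons). A random forest is trained on a stratified
2/3 split of the cohort with bootstrap-resampling hyperparameter tuning
(100 resamples by default), and patients are assigned subtype I/II/III only
when the (multiregion-averaged) maximum class probability reaches the 0.4
gate; otherwise they are left UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SUBTYPE_LABELS",
    "UNCLASSIFIED",
    "SubtypeModel",
    "SubtypeCall",
    "extract_signature",
    "train_subtype_model",
    "predict_subtype",
    "assign_from_probabilities",
]

SUBTYPE_LABELS = ("I", "II", "III")
UNCLASSIFIED = "UNCLASSIFIED"


def extract_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    *,
    fdr: float = 0.05,
) -> dict[str, list[str]]:
    """Per-class signature genes from pairwise between-class rank-sum tests.

    ``expr`` is genes x samples; ``labels`` maps sample -> class. Gene g is
    in class k's signature iff, against each of the other two classes, the
    Mann-Whitney rank-sum test has BH-adjusted p < ``fdr`` (adjustment across
    genes within each pairwise comparison) and the median expression is
    higher in k. Each class needs >= 3 samples.
    """
    labels = labels.loc[expr.columns]
    classes = sorted(labels.unique())
    for k in classes:
        n = int((labels == k).sum())
        if n < 3:
            raise ValueError(f"class {k} has {n} samples; >= 3 required")
    X = expr.to_numpy(dtype=float)
    genes = list(expr.index)
    masks = {k: (labels == k).to_numpy() for k in classes}

    # significant "higher in k1 vs k2" gene sets, per ordered class pair
    higher: dict[tuple, set[str]] = {}
    for i, k1 in enumerate(classes):
        for k2 in classes[i + 1 :]:
            x1, x2 = X[:, masks[k1]], X[:, masks[k2]]
            res = stats.mannwhitneyu(x1, x2, axis=1, alternative="two-sided")
            padj = multipletests(res.pvalue, method="fdr_bh")[1]
            med1 = np.median(x1, axis=1)
            med2 = np.median(x2, axis=1)
            sig = padj < fdr
            higher[(k1, k2)] = {g for g, s, up in zip(genes, sig, med1 > med2) if s and up}
            higher[(k2, k1)] = {g for g, s, up in zip(genes, sig, med2 > med1) if s and up}

    out: dict[str, list[str]] = {}
    for k in classes:
        others = [o for o in classes if o != k]
        sel = set(genes)
        for o in others:
            sel &= higher[(k, o)]
        out[str(k)] = sorted(sel)
    return out


@dataclass
class SubtypeModel:
    """Trained subtype classifier plus its training provenance."""

    signature_genes: dict[str, list[str]]
    feature_genes: list[str]
    classifier: RandomForestClassifier
    classes: tuple[str, ...]
    train_fraction: float
    iterations: int
    seed: int
    probability_gate: float = 0.4
    validation_accuracy: float = float("nan")
    best_max_features: object = "sqrt"
    train_samples: list[str] = field(default_factory=list)
    validation_samples: list[str] = field(default_factory=list)


def _tune_max_features(
    X: np.ndarray,
    y: np.ndarray,
    iterations: int,
    rng: np.random.Generator,
    candidates: Sequence[object] = ("sqrt", 0.25, 0.5),
    n_estimators: int = 50,
) -> object:
    """Bootstrap-resampling tuning of the forest's max_features.

    Each resampling iteration draws a bootstrap sample of the training set,
    fits one forest per candidate and scores it on the out-of-bootstrap
    samples; the candidate with the highest mean accuracy wins (first wins
    ties, in candidate order).
    """
    n = len(y)
    scores = {c: [] for c in candidates}
    for _ in range(iterations):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0 or len(np.unique(y[idx])) < len(np.unique(y)):
            continue
        for cand in candidates:
            clf = RandomForestClassifier(
                n_estimators=n_estimators,
                max_features=cand,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            clf.fit(X[idx], y[idx])
            scores[cand].append(clf.score(X[oob], y[oob]))
    means = {c: (np.mean(v) if v else -1.0) for c, v in scores.items()}
    best = max(candidates, key=lambda c: means[c])
    return best


def train_subtype_model(
    expr: pd.DataFrame,
    labels: pd.Series,
    *,
    train_fraction: float = 2 / 3,
    iterations: int = 100,
    seed: int = 0,
    probability_gate: float = 0.4,
    signature: Optional[dict[str, list[str]]] = None,
    fdr: float = 0.05,
    n_estimators: int = 300,
    max_retries: int = 10,
) -> SubtypeModel:
    """Train the subtype model by the split-and-resample protocol.

    A stratified ``train_fraction`` (default 2/3) of samples trains the
    forest on the signature-gene features, with ``iterations`` bootstrap
    resamples used to tune max_features; accuracy on the held-out remainder
    is recorded. Fully seed-deterministic.
    """
    labels = labels.loc[expr.columns].astype(str)
    classes = tuple(sorted(labels.unique()))
    if len(classes) != 3:
        raise ValueError(f"expected 3 subtype classes, got {classes}")
    if signature is None:
        signature = extract_signature(expr, labels, fdr=fdr)
    feature_genes = sorted(set().union(*signature.values()))
    if not feature_genes:
        raise ValueError("signature extraction produced no genes")

    X = expr.loc[feature_genes].to_numpy(dtype=float).T
    y = labels.to_numpy()
    samples = np.array(expr.columns)

    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        split_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, X_va, y_tr, y_va, s_tr, s_va = train_test_split(
            X, y, samples,
            train_size=train_fraction,
            stratify=y,
            random_state=split_seed,
        )
        if len(np.unique(y_tr)) == len(classes):
            break
    else:
        raise RuntimeError("could not obtain a training split containing all classes")

    best = _tune_max_features(X_tr, y_tr, iterations, rng)
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=best,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    clf.fit(X_tr, y_tr)
    acc = float(clf.score(X_va, y_va))
    return SubtypeModel(
        signature_genes=signature,
        feature_genes=feature_genes,
        classifier=clf,
        classes=tuple(clf.classes_),
        train_fraction=train_fraction,
        iterations=iterations,
        seed=seed,
        probability_gate=probability_gate,
        validation_accuracy=acc,
        best_max_features=best,
        train_samples=[str(s) for s in s_tr],
        validation_samples=[str(s) for s in s_va],
    )


@dataclass(frozen=True)
class SubtypeCall:
    patient_id: str
    mean_probabilities: dict[str, float]
    label: str  # one of SUBTYPE_LABELS or UNCLASSIFIED
    contributing_regions: tuple[str, ...]


def assign_from_probabilities(
    mean_probs: dict[str, float], *, gate: float = 0.4
) -> str:
    """Gate rule on (multiregion-averaged) class probabilities.

    Assign the argmax class iff its probability reaches ``gate``; ties break
    deterministically by class order I < II < III.
    """
    best_label, best_p = None, -1.0
    for label in sorted(mean_probs):
        p = mean_probs[label]
        if p > best_p:
            best_label, best_p = label, p
    if best_p < gate:
        return UNCLASSIFIED
    return str(best_label)


def predict_subtype(
    model: SubtypeModel,
    regions: pd.DataFrame,
    patient_id: str = "",
) -> SubtypeCall:
    """Subtype call for one patient from >= 1 regional expression profiles.

    ``regions`` is genes x regions; per-region class probabilities from the
    forest are averaged across regions before the 0.4 probability gate is
    applied (patients failing the gate stay UNCLASSIFIED).
    """
    missing = [g for g in model.feature_genes if g not in regions.index]
    if missing:
        raise ValueError(f"regions are missing signature genes: {missing}")
    X = regions.loc[model.feature_genes].to_numpy(dtype=float).T
    probs = model.classifier.predict_proba(X)
    mean_p = probs.mean(axis=0)
    mean_probs = {str(c): float(p) for c, p in zip(model.classes, mean_p)}
    label = assign_from_probabilities(mean_probs, gate=model.probability_gate)
    return SubtypeCall(
        patient_id=patient_id,
        mean_probabilities=mean_probs,
        label=label,
        contributing_regions=tuple(str(c) for c in regions.columns),
    )
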