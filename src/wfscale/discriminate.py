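"""Classifier-based distinguishability of scaled vs unscaled replicates.

If rescaling left simulation outcomes unchanged, no classifier could label a
replicate as scaled or unscaled better than chance.  Held-out accuracy of a
logistic regression and a random forest, trained separately on each of the
four outcome feature sets, therefore measures how far the outcome
distributions have shifted: 50% means indistinguishable, 100% means
disjoint.  Train and test sets are balanced, so 50% is the uninformative
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .summaries import ReplicateSummary

__all__ = [
    "FEATURE_SETS",
    "CLASSIFIERS",
    "FeatureMatrix",
    "DiscriminationReport",
    "build_features",
    "train_and_score",
]

FEATURE_SETS = ("sfs", "ld", "fraction_fixed", "fixation_times")
CLASSIFIERS = ("logistic_regression", "random_forest")


@dataclass
class FeatureMatrix:
    """One row per replicate; feature layout fixed within a feature set."""

    feature_set: str
    rows: np.ndarray          # (n_replicates, n_features)
    classes: tuple
    had_empty_ld_bins: bool = False


def build_features(summaries: Sequence[ReplicateSummary], feature_set: str) -> FeatureMatrix:
    """Assemble the feature matrix for one feature set.

    sfs: per-class SFS concatenated (199 features per class for n=100);
    ld: the 50 binned mean r^2 values (all classes pooled; empty bins 0);
    fraction_fixed: one corrected fraction per class (undefined -> 0);
    fixation_times: per-class fixation-time histograms concatenated.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; valid: {FEATURE_SETS}")
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries given")
    classes = summaries[0].classes
    had_empty = False
    rows = []
    for s in summaries:
        if s.classes != classes:
            raise ValueError("summaries have inconsistent class sets")
        if feature_set == "sfs":
            vec = np.concatenate([np.asarray(s.sfs[c], dtype=np.float64) for c in classes])
        elif feature_set == "ld":
            vec = np.asarray(s.ld_bin_means, dtype=np.float64).copy()
            if np.isnan(vec).any():
                had_empty = True
                vec = np.nan_to_num(vec, nan=0.0)
        elif feature_set == "fraction_fixed":
            vec = np.array([s.fixed_fraction[c] for c in classes], dtype=np.float64)
            vec = np.nan_to_num(vec, nan=0.0)
        else:
            vec = np.concatenate([np.asarray(s.fixation_hist[c], dtype=np.float64)
                                  for c in classes])
        rows.append(vec)
    width = max(len(v) for v in rows)
    mat = np.zeros((len(rows), width))
    for i, v in enumerate(rows):
        mat[i, :len(v)] = v
    return FeatureMatrix(feature_set=feature_set, rows=mat, classes=classes,
                         had_empty_ld_bins=had_empty)


@dataclass
class DiscriminationReport:
    feature_set: str
    classifier: str
    Q: float
    baseline_Q: float
    test_accuracy: float
    n_train: int
    n_test: int
    seed: int


def _make_classifier(name: str, seed: int):
    # hyperparameters pinned (library defaults at the time of the protocol)
    if name == "logistic_regression":
        # L2 penalty (the default), C=1.0, 100-iteration cap
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0, max_iter=100, random_state=seed))
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, criterion="gini",
                                      max_depth=None, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; valid: {CLASSIFIERS}")


def train_and_score(unscaled_rows: np.ndarray, scaled_rows: np.ndarray,
                    classifier: str, seed: int,
                    feature_set: str = "unspecified",
                    Q: float = float("nan"),
                    baseline_Q: float = 1.0) -> DiscriminationReport:
    """Train one classifier to separate scaled from unscaled replicates and
    return its held-out accuracy.

    Both classes are truncated to the smaller count, then split 80/20 with
    identical class counts in both partitions, so 0.5 is the accuracy of an
    uninformative classifier.
    """
    unscaled_rows = np.asarray(unscaled_rows, dtype=np.float64)
    scaled_rows = np.asarray(scaled_rows, dtype=np.float64)
    n = min(len(unscaled_rows), len(scaled_rows))
    if n < 5:
        raise ValueError("need at least 5 replicates per class")
    rng = np.random.default_rng(seed)
    idx_u = rng.permutation(len(unscaled_rows))[:n]
    idx_s = rng.permutation(len(scaled_rows))[:n]
    n_test = max(1, int(round(0.2 * n)))
    n_train = n - n_test

    def split(rows, idx):
        return rows[idx[:n_train]], rows[idx[n_train:]]

    u_tr, u_te = split(unscaled_rows, idx_u)
    s_tr, s_te = split(scaled_rows, idx_s)
    X_tr = np.vstack([u_tr, s_tr])
    y_tr = np.concatenate([np.zeros(n_train), np.ones(n_train)])
    X_te = np.vstack([u_te, s_te])
    y_te = np.concatenate([np.zeros(n_test), np.ones(n_test)])

    clf = _make_classifier(classifier, int(rng.integers(0, 2**31 - 1)))
    clf.fit(X_tr, y_tr)
    acc = float((clf.predict(X_te) == y_te).mean())
    return DiscriminationReport(
        feature_set=feature_set, classifier=classifier, Q=Q, baseline_Q=baseline_Q,
        test_accuracy=acc, n_train=2 * n_train, n_test=2 * n_test, seed=int(seed))
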