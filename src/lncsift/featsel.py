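"""Correlation-ranked feature selection and the incremental feature selection sweep.

Features are ranked by |Pearson r| against the class label (1 = lncRNA,
0 = mRNA); redundant pairs (|r| > 0.8 by default) are resolved by keeping
the member more correlated with the label, with an exception list that
can pin features (the stop-codon SD is pinned by default: it captures
frame deviation that survives even when an ORF is never translated).
The IFS sweep then cross-validates each classifier on the top-k feature
prefix for k = 1..#features, with min-max scaling fit inside each
training fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_validate
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .seqio import DataError

logger = logging.getLogger(__name__)

DEFAULT_PINNED = ("Stop_codon_std",)

# tie-break priority when several classifiers reach the best F at the same k
CLASSIFIER_PRIORITY = ["RF", "LR", "SVM", "KNN", "DT"]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; zero-variance input gives 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise DataError("need at least 2 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero-variance input; Pearson r reported as 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CorrelationReport:
    label_corr: pd.Series
    pairwise: pd.DataFrame
    dropped: list[tuple[str, str, float]] = field(default_factory=list)


def label_correlations(m: FeatureMatrix) -> pd.Series:
    y = m.binary_labels()
    return pd.Series(
        {name: pearson_r(m.data[name].to_numpy(), y) for name in m.names}, name="label_corr"
    )


def remove_redundant(
    m: FeatureMatrix,
    threshold: float = 0.8,
    pinned: Sequence[str] = DEFAULT_PINNED,
) -> tuple[FeatureMatrix, CorrelationReport]:
    """Drop one member of every feature pair with |pairwise r| > threshold.

    Pairs are visited in descending |r|; the member with the smaller
    |label correlation| is dropped (ties drop the later column in the
    matrix's column order). Pinned features are never dropped.
    """
    if len(m.names) < 2:
        raise DataError("need at least 2 features for redundancy removal")
    label_corr = label_correlations(m)
    pairwise = m.data.corr().fillna(0.0)
    names = m.names
    order = {n: i for i, n in enumerate(names)}

    pairs = [
        (abs(pairwise.loc[a, b]), a, b)
        for i, a in enumerate(names)
        for b in names[i + 1 :]
        if abs(pairwise.loc[a, b]) > threshold
    ]
    pairs.sort(key=lambda t: (-t[0], order[t[1]], order[t[2]]))

    alive = set(names)
    dropped: list[tuple[str, str, float]] = []
    for r, a, b in pairs:
        if a not in alive or b not in alive:
            continue
        a_pin, b_pin = a in pinned, b in pinned
        if a_pin and b_pin:
            continue
        if a_pin:
            victim, keeper = b, a
        elif b_pin:
            victim, keeper = a, b
        else:
            ca, cb = abs(label_corr[a]), abs(label_corr[b])
            if ca > cb:
                victim, keeper = b, a
            elif cb > ca:
                victim, keeper = a, b
            else:  # tie: drop the later one in column order
                victim, keeper = (b, a) if order[b] > order[a] else (a, b)
        alive.discard(victim)
        dropped.append((victim, keeper, float(r)))

    kept = [n for n in names if n in alive]
    report = CorrelationReport(label_corr=label_corr, pairwise=pairwise, dropped=dropped)
    return m.select(kept), report


def rank_features(m: FeatureMatrix) -> FeatureMatrix:
    """Reorder columns by descending |label correlation| (ties by name)."""
    lc = label_correlations(m).abs()
    ranked = sorted(m.names, key=lambda n: (-lc[n], n))
    return m.select(ranked)


def make_classifier(name: str, seed: int):
    """Library-default classifiers; randomness seeded where it exists."""
    if name == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "SVM":
        return SVC(random_state=seed)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier()
    raise DataError(f"unknown classifier '{name}'; valid: {CLASSIFIER_PRIORITY}")


@dataclass
class IFSTrace:
    """Cross-validated sensitivity and F for every (classifier, k) prefix."""

    table: pd.DataFrame  # columns: classifier, k, sen, f
    best_classifier: str
    best_k: int

    @property
    def best_f(self) -> float:
        row = self.table[
            (self.table["classifier"] == self.best_classifier) & (self.table["k"] == self.best_k)
        ]
        return float(row["f"].iloc[0])


def run_ifs(
    m: FeatureMatrix,
    classifiers: Sequence[str] = ("LR", "SVM", "DT", "RF", "KNN"),
    folds: int = 10,
    seed: int = 0,
) -> IFSTrace:
    """Incremental feature selection over already-ranked features.

    For every k the top-k columns are cross-validated (stratified folds,
    min-max scaling inside each training fold) and mean sensitivity
    (recall) and F-measure recorded. Best = argmax F, ties to the
    smaller k and then the classifier priority RF>LR>SVM>KNN>DT.
    """
    y = m.binary_labels()
    if m.n < folds:
        raise DataError(f"{m.n} samples is fewer than {folds} folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    X_all = m.data.to_numpy()
    for k in range(1, len(m.names) + 1):
        X = X_all[:, :k]
        for name in classifiers:
            pipe = Pipeline(
                [("scale", MinMaxScaler(clip=True)), ("clf", make_classifier(name, seed))]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = cross_validate(pipe, X, y, cv=cv, scoring=("recall", "f1"))
            rows.append(
                {
                    "classifier": name,
                    "k": k,
                    "sen": float(np.mean(res["test_recall"])),
                    "f": float(np.mean(res["test_f1"])),
                }
            )
    table = pd.DataFrame(rows)

    prio = {c: i for i, c in enumerate(CLASSIFIER_PRIORITY)}
    best = min(
        table.itertuples(),
        key=lambda r: (-r.f, r.k, prio.get(r.classifier, len(prio))),
    )
    return IFSTrace(table=table, best_classifier=best.classifier, best_k=int(best.k))
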