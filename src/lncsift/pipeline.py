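"""End-to-end orchestration: features -> tri-nucleotide screen -> IFS -> balanced forest.

This mirrors the full training workflow on a pair of labeled transcript
sets: train the hexamer table, screen the 64 tri-nucleotides (Z test at
1% FDR), assemble the scalar + selected-tri-nucleotide matrix, remove
redundant features, rank by label correlation, run the incremental
feature-selection sweep, and train the balanced random forest on the
chosen prefix. The IFS sweep inside this convenience path defaults to
logistic regression only, which keeps an end-to-end run at desk scale;
the full five-classifier comparison remains available via
:func:`lncsift.featsel.run_ifs` or the ``ifs`` CLI subcommand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .featsel import IFSTrace, rank_features, remove_redundant, run_ifs
from .features import SCALAR_FEATURES, FeatureMatrix, extract_features, trinuc_matrix
from .hexamer import HexamerTable, train_hexamer_table
from .metrics import compute_metrics, confusion_from_labels, roc_auc
from .model import ModelBundle, predict, train_balanced_rf
from .seqio import Transcript
from .trinuc_stats import select_trinucs, trinuc_ztest

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    bundle: ModelBundle
    selected_trinucs: list[str]
    trinuc_report: pd.DataFrame
    dropped_features: list[tuple[str, str, float]]
    ifs_trace: IFSTrace
    feature_names: list[str]
    test_metrics: dict[str, float] | None = None
    test_auc: float | None = None


def build_training_matrix(
    pos: Sequence[Transcript],
    neg: Sequence[Transcript],
    hex_table: HexamerTable,
    trinucs: Sequence[str],
) -> FeatureMatrix:
    return extract_features(
        list(pos) + list(neg), hex_table=hex_table, feature_list=SCALAR_FEATURES + list(trinucs)
    )


def run_pipeline(
    train_pos: Sequence[Transcript],
    train_neg: Sequence[Transcript],
    test_pos: Sequence[Transcript] | None = None,
    test_neg: Sequence[Transcript] | None = None,
    alpha: float = 0.01,
    top_k_trinucs: int | None = 15,
    ifs_classifiers: Sequence[str] = ("LR",),
    ifs_folds: int = 10,
    n_trees: int = 500,
    seed: int = 0,
) -> PipelineResult:
    """Train the full classifier from labeled transcripts; optionally evaluate.

    ``top_k_trinucs`` caps the tri-nucleotide subset at the strongest
    summed-|Z| candidates (default 15, the animal-preset count).
    """
    hex_table = train_hexamer_table(coding=train_neg, noncoding=train_pos)

    stats = trinuc_ztest(trinuc_matrix(train_pos), trinuc_matrix(train_neg))
    selected, report = select_trinucs([stats], alpha=alpha, top_k=top_k_trinucs)
    logger.info("tri-nucleotide screen selected %d of 64", len(selected))

    m = build_training_matrix(train_pos, train_neg, hex_table, selected)
    m_red, corr_report = remove_redundant(m)
    m_ranked = rank_features(m_red)

    trace = run_ifs(m_ranked, classifiers=ifs_classifiers, folds=ifs_folds, seed=seed)
    chosen = m_ranked.names[: trace.best_k]
    logger.info("IFS chose k=%d (%s, F=%.4f)", trace.best_k, trace.best_classifier, trace.best_f)

    bundle = train_balanced_rf(
        m_ranked.select(chosen), n_trees=n_trees, seed=seed, hexamer_table=hex_table
    )

    result = PipelineResult(
        bundle=bundle,
        selected_trinucs=selected,
        trinuc_report=report,
        dropped_features=corr_report.dropped,
        ifs_trace=trace,
        feature_names=chosen,
    )

    if test_pos is not None and test_neg is not None:
        test_m = extract_features(
            list(test_pos) + list(test_neg), hex_table=hex_table, feature_list=chosen
        )
        pred = predict(bundle, test_m)
        y_true = test_m.binary_labels()
        y_hat = (pred["score"] >= bundle.threshold).to_numpy().astype(int)
        result.test_metrics = compute_metrics(confusion_from_labels(y_true, y_hat))
        _, result.test_auc = roc_auc(pred["score"].to_numpy(), y_true)
    return result
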