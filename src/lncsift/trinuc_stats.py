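"""Tri-nucleotide significance screen: two-sample Z, two-sided p, BH-FDR, consensus.

For each of the 64 tri-nucleotides the per-transcript frequencies of the
positive (lncRNA) and negative (mRNA) groups are compared with the
two-sample Z statistic

    Z = (X̄1 − X̄2) / sqrt(S1²/n1 + S2²/n2),

with S the sample standard deviation (divisor n−1). Two-sided p-values
come from the standard normal tail and are Benjamini–Hochberg adjusted.
A tri-nucleotide is selected when its adjusted p stays below alpha in
every species set; candidates are ranked by the summed |Z| across sets.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .features import TRINUCLEOTIDES
from .seqio import DataError

logger = logging.getLogger(__name__)


def p_from_z(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided standard-normal tail probability 2*(1 - Phi(|z|))."""
    return 2.0 * sp_stats.norm.sf(np.abs(z))


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, returned in the input order.

    Raw adjustment p_i * m / rank_i on the ascending sort (stable ranks
    for ties), then step-up monotonicity (cumulative minimum from the
    largest rank) and a cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise DataError("p-value vector must be 1-d and non-empty")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    raw = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def trinuc_ztest(pos_freqs: pd.DataFrame, neg_freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-tri-nucleotide two-group statistics (one row per 3-mer).

    Inputs are per-transcript 64-column frequency tables (one row per
    transcript) for the positive and negative groups. Zero-variance
    degeneracies are handled explicitly: equal means give Z=0, p=1;
    unequal means are flagged degenerate with p=0.
    """
    pos = np.asarray(pos_freqs, dtype=float)
    neg = np.asarray(neg_freqs, dtype=float)
    n1, n2 = len(pos), len(neg)
    if n1 < 2 or n2 < 2:
        raise DataError(f"need at least 2 transcripts per group (got {n1} and {n2})")
    if pos.shape[1] != 64 or neg.shape[1] != 64:
        raise DataError("frequency tables must have 64 tri-nucleotide columns")

    m1, m2 = pos.mean(axis=0), neg.mean(axis=0)
    s1, s2 = pos.std(axis=0, ddof=1), neg.std(axis=0, ddof=1)
    se = np.sqrt(s1**2 / n1 + s2**2 / n2)

    z = np.zeros(64)
    p = np.ones(64)
    degenerate = np.zeros(64, dtype=bool)
    ok = se > 0
    z[ok] = (m1[ok] - m2[ok]) / se[ok]
    p[ok] = p_from_z(z[ok])
    bad = (~ok) & (m1 != m2)
    if bad.any():
        degenerate[bad] = True
        z[bad] = np.where(m1[bad] > m2[bad], np.inf, -np.inf)
        p[bad] = 0.0

    return pd.DataFrame(
        {
            "trinuc": TRINUCLEOTIDES,
            "mean_pos": m1,
            "mean_neg": m2,
            "sd_pos": s1,
            "sd_neg": s2,
            "n_pos": n1,
            "n_neg": n2,
            "z": z,
            "p": p,
            "p_adj": fdr_adjust(p),
            "degenerate": degenerate,
        }
    )


def select_trinucs(
    stats_by_species: Sequence[pd.DataFrame],
    alpha: float = 0.01,
    top_k: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Consensus selection across species sets.

    A tri-nucleotide is a candidate iff its adjusted p is below ``alpha``
    in every set; candidates are ordered by descending summed |Z| (ties
    by name). Returns the ordered list and an audit report with the
    per-species Z and adjusted p.
    """
    if not stats_by_species:
        raise DataError("need at least one species stats set")
    report = pd.DataFrame({"trinuc": TRINUCLEOTIDES})
    sig_all = np.ones(64, dtype=bool)
    abs_z_sum = np.zeros(64)
    for i, df in enumerate(stats_by_species):
        df = df.set_index("trinuc").loc[TRINUCLEOTIDES]
        report[f"z_{i}"] = df["z"].to_numpy()
        report[f"p_adj_{i}"] = df["p_adj"].to_numpy()
        sig_all &= df["p_adj"].to_numpy() < alpha
        abs_z_sum += np.abs(df["z"].to_numpy())
    report["abs_z_sum"] = abs_z_sum
    report["selected"] = sig_all

    cand = report[report["selected"]].sort_values(
        ["abs_z_sum", "trinuc"], ascending=[False, True], kind="stable"
    )
    selected = list(cand["trinuc"])
    if top_k is not None:
        selected = selected[:top_k]
    report["selected"] = report["trinuc"].isin(selected)
    return selected, report
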