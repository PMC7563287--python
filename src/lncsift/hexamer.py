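"""In-frame hexamer usage model: train frequency tables, score by log-likelihood ratio.

A hexamer is a pair of adjacent codons, so hexamer usage captures
dependencies between neighbouring amino acids. Coding training sequences
contribute 6-mers read in frame (step 3) along their longest predicted
ORF, excluding the stop codon (a stop encodes no amino acid); non-coding
sequences contribute frame-0 6-mers of the whole sequence. The score of a
transcript is the mean natural-log ratio of coding to non-coding 6-mer
frequency along its predicted ORF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import OrfResult, _window_codes, encode, find_longest_orf
from .seqio import DataError, Transcript

logger = logging.getLogger(__name__)

ALL_HEXAMERS_N = 4096


@dataclass
class HexamerTable:
    """Paired 6-mer frequency tables for coding and non-coding training sets."""

    coding_freq: np.ndarray  # length 4096, sums to 1
    noncoding_freq: np.ndarray
    pseudocount: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._log_ratio: np.ndarray | None = None

    @property
    def log_ratio(self) -> np.ndarray:
        if self._log_ratio is None:
            self._log_ratio = np.log(self.coding_freq / self.noncoding_freq)
        return self._log_ratio

    def swapped(self) -> "HexamerTable":
        return HexamerTable(self.noncoding_freq.copy(), self.coding_freq.copy(), self.pseudocount)

    def to_frame(self) -> pd.DataFrame:
        import itertools

        names = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
        return pd.DataFrame(
            {"hexamer": names, "coding_freq": self.coding_freq, "noncoding_freq": self.noncoding_freq}
        )


def _orf_hexamer_region(t: Transcript, orf: OrfResult | None = None) -> tuple[int, int]:
    """Half-open nt span whose step-3 6-mers are counted for a transcript."""
    if orf is None:
        orf = find_longest_orf(t)
    if orf.has_start:
        end = orf.end - 3 if orf.has_stop else orf.end
        return orf.start, end
    return 0, len(t.seq)


def _inframe_hexamer_codes(t: Transcript, start: int, end: int) -> np.ndarray:
    codes = encode(t.seq)
    hexes = _window_codes(codes, 6)
    positions = np.arange(start, end - 5, 3)
    if len(positions) == 0:
        return np.empty(0, dtype=np.int64)
    w = hexes[positions]
    return w[w >= 0]  # drop N-containing windows


def train_hexamer_table(
    coding: Sequence[Transcript],
    noncoding: Sequence[Transcript],
    pseudocount: float = 1.0,
) -> HexamerTable:
    """Count in-frame 6-mers in both classes and normalize with add-pseudocount smoothing."""
    if not coding or not noncoding:
        raise DataError("both coding and non-coding training sets must be non-empty")

    def _freqs(ts: Sequence[Transcript], use_orf: bool) -> np.ndarray:
        counts = np.zeros(ALL_HEXAMERS_N)
        for t in ts:
            if use_orf:
                start, end = _orf_hexamer_region(t)
            else:
                start, end = 0, len(t.seq)
            w = _inframe_hexamer_codes(t, start, end)
            if len(w):
                counts += np.bincount(w, minlength=ALL_HEXAMERS_N)
        counts += pseudocount
        return counts / counts.sum()

    return HexamerTable(
        coding_freq=_freqs(coding, use_orf=True),
        noncoding_freq=_freqs(noncoding, use_orf=False),
        pseudocount=pseudocount,
        meta={"n_coding": len(coding), "n_noncoding": len(noncoding)},
    )


def hexamer_score(t: Transcript, table: HexamerTable, orf: OrfResult | None = None) -> float:
    """Mean ln(F(H)/F'(H)) over the step-3 6-mers of the predicted ORF.

    Falls back to frame 0 of the whole sequence when no ATG-initiated ORF
    exists; returns 0 (with a warning) when there is no scorable window.
    """
    start, end = _orf_hexamer_region(t, orf=orf)
    w = _inframe_hexamer_codes(t, start, end)
    if len(w) == 0:
        logger.warning("sequence '%s' has no scorable hexamer window; score 0", t.id)
        return 0.0
    return float(table.log_ratio[w].mean())


def save_table(table: HexamerTable, path: str | Path) -> None:
    from .seqio import write_table

    write_table(table.to_frame(), path)


def load_table(path: str | Path, pseudocount: float = 1.0) -> HexamerTable:
    df = pd.read_csv(path, sep="\t")
    if len(df) != ALL_HEXAMERS_N:
        raise DataError(f"hexamer table at {path} has {len(df)} rows, expected {ALL_HEXAMERS_N}")
    return HexamerTable(
        coding_freq=df["coding_freq"].to_numpy(),
        noncoding_freq=df["noncoding_freq"].to_numpy(),
        pseudocount=pseudocount,
    )
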