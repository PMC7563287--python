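"""Synthetic labeled transcripts with the statistical structure the classifier exploits.

Two generators emulate the contrast between the classes:

* ``simulate_mrna`` — a long codon-usage-biased ORF (ATG + biased sense
  codons + stop) flanked by UTRs drawn at the GC target; the ORF occupies
  at least ``1 - utr_fraction`` of the transcript.
* ``simulate_lncrna`` — length/GC-matched sequences built by weighted
  tri-nucleotide-chain sampling (so tests can dial exactly which 3-mers
  differ via ``trinuc_bias``); any complete ORF longer than the
  disruption threshold has its start codon knocked out.

Everything is driven by a single seed, so a parameter set fixes the
output byte-for-byte.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import NEGATIVE_LABEL, POSITIVE_LABEL, DataError, Transcript

STOPS = ("TAA", "TAG", "TGA")

# Human codon usage (frequency per thousand, Kazusa codon usage database);
# the default codon bias for mRNA-like ORFs.
HUMAN_CODON_USAGE = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}

_TRINUCS = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for one synthetic dataset."""

    n_pos: int = 1000
    n_neg: int = 1000
    length_range: tuple[int, int] = (200, 3000)
    gc_target: float = 0.5
    codon_bias: dict[str, float] | None = None
    trinuc_bias: dict[str, float] | None = None
    utr_fraction: float = 0.4
    orf_disrupt_nt: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise DataError("counts must be non-negative")
        if self.length_range[0] < 9 or self.length_range[0] > self.length_range[1]:
            raise DataError("length_range must satisfy 9 <= min <= max")
        if not 0.0 < self.gc_target < 1.0:
            raise DataError("gc_target must lie in (0, 1)")
        if not 0.0 < self.utr_fraction < 1.0:
            raise DataError("utr_fraction must lie in (0, 1)")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=_base_probs(gc))])


def _codon_sampler(codon_bias: dict[str, float] | None):
    usage = codon_bias if codon_bias is not None else HUMAN_CODON_USAGE
    sense = [c for c in usage if c not in STOPS]
    w = np.array([usage[c] for c in sense], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise DataError("codon bias weights must be non-negative with positive sum")
    return np.array(sense), w / w.sum()


def simulate_mrna(p: SynthParams) -> list[Transcript]:
    """mRNA-like transcripts: 5'UTR + ATG + biased codons + stop + 3'UTR."""
    rng = np.random.default_rng([int(p.seed), 0x6D])
    codons, cw = _codon_sampler(p.codon_bias)
    out = []
    lo, hi = p.length_range
    for i in range(p.n_neg):
        L = int(rng.integers(lo, hi + 1))
        orf_nt = max(9, int(math.ceil((1 - p.utr_fraction) * L / 3)) * 3)
        orf_nt = min(orf_nt, L // 3 * 3)
        n_internal = orf_nt // 3 - 2  # minus ATG and stop
        if n_internal < 1:
            raise DataError(f"length {L} too short for an ORF under the given constraints")
        body = "".join(rng.choice(codons, size=n_internal, p=cw))
        orf = "ATG" + body + STOPS[rng.integers(0, 3)]
        rest = L - len(orf)
        utr5 = int(rng.integers(0, rest + 1))
        seq = (
            _random_bases(rng, utr5, p.gc_target)
            + orf
            + _random_bases(rng, rest - utr5, p.gc_target)
        )
        out.append(Transcript(id=f"mrna_{p.seed}_{i:05d}", seq=seq, label=NEGATIVE_LABEL))
    return out


def _trinuc_weights(p: SynthParams) -> np.ndarray:
    probs = _base_probs(p.gc_target)
    w = np.array(
        [probs["ACGT".index(a)] * probs["ACGT".index(b)] * probs["ACGT".index(c)]
         for a, b, c in _TRINUCS]
    )
    if p.trinuc_bias:
        for tri, mult in p.trinuc_bias.items():
            if tri not in _TRINUCS or mult < 0:
                raise DataError(f"invalid trinuc_bias entry {tri!r}: {mult!r}")
            w[_TRINUCS.index(tri)] *= mult
    return w / w.sum()


def _disrupt_long_orfs(seq: str, max_nt: int) -> str:
    # Replace the start codon of any complete ORF longer than max_nt.
    # "ACC" contains no T/G pattern that could create a new ATG across
    # boundaries, so the loop terminates.
    from .features import find_longest_orf
    from .seqio import Transcript as _T

    while True:
        orf = find_longest_orf(_T(id="x", seq=seq))
        if not (orf.complete and orf.length_nt > max_nt):
            return seq
        seq = seq[: orf.start] + "ACC" + seq[orf.start + 3 :]


def simulate_lncrna(p: SynthParams) -> list[Transcript]:
    """lncRNA-like transcripts: tri-nucleotide-chain sampling, long ORFs disrupted."""
    rng = np.random.default_rng([int(p.seed), 0x4C])
    w = _trinuc_weights(p)
    tri_arr = np.array(_TRINUCS)
    out = []
    lo, hi = p.length_range
    for i in range(p.n_pos):
        L = int(rng.integers(lo, hi + 1))
        n3 = (L + 2) // 3
        seq = "".join(tri_arr[rng.choice(64, size=n3, p=w)])[:L]
        seq = _disrupt_long_orfs(seq, p.orf_disrupt_nt)
        out.append(Transcript(id=f"lnc_{p.seed}_{i:05d}", seq=seq, label=POSITIVE_LABEL))
    return out


def simulate_dataset(p: SynthParams) -> tuple[list[Transcript], list[Transcript]]:
    """(positives, negatives) under one parameter set."""
    return simulate_lncrna(p), simulate_mrna(p)


def with_seed(p: SynthParams, seed: int) -> SynthParams:
    return replace(p, seed=seed)
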