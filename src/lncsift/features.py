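"""Per-transcript scalar features and tri-nucleotide frequencies.

The scalar catalogue: sequence length, GC content, standard deviation of
stop-codon counts across the three frames, ORF integrity, CDS length /
score / percentage from a bespoke longest-ORF scorer, predicted-peptide
length and isoelectric point, Fickett TESTCODE score, and the hexamer
log-likelihood score (computed in :mod:`lncsift.hexamer`). Tri-nucleotide
frequencies are overlapping 3-mer proportions (64 values summing to 1).

N handling: N is excluded from GC and Fickett counts, 3-mer/6-mer windows
containing N are skipped, and codons containing N never match ATG or a
stop codon.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import _fickett
from .seqio import DataError, Transcript

if TYPE_CHECKING:  # pragma: no cover
    from .hexamer import HexamerTable

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")

TRINUCLEOTIDES: list[str] = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
_TRINUC_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES)}

SCALAR_FEATURES = [
    "Length",
    "GC_content",
    "Stop_codon_std",
    "ORF_in",
    "CDS_len",
    "CDS_score",
    "CDS_percent",
    "Pep_len",
    "PI",
    "Hexamer",
    "Fickett",
]

# Tri-nucleotide subsets that discriminate lncRNA from mRNA consistently
# across the animal (human/mouse/cow) and plant (A. thaliana / O. sativa /
# Z. mays) training compendia (two-sample Z screen at 1% FDR).
ANIMAL_TRINUCS = [
    "ACG", "AGC", "CAG", "CAT", "CCA", "CGG", "CGT", "GAC",
    "GAG", "GAT", "GGC", "GGG", "TAC", "TAG", "TCA",
]
PLANT_TRINUCS = [
    "AAA", "AAC", "AAT", "ACC", "ACT", "AGC", "AGG", "ATC",
    "ATG", "CAA", "CAG", "CAT", "CGA", "CTA", "GAC", "GAG",
    "GAT", "GGA", "GGG", "GTA", "TAA", "TAG", "TAT", "TTA",
]

PRESETS = {
    "animal": SCALAR_FEATURES + ANIMAL_TRINUCS,
    "plant": SCALAR_FEATURES + PLANT_TRINUCS,
    "full": SCALAR_FEATURES + TRINUCLEOTIDES,
}

# base -> code; N and anything else -> 4
_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_ATG_CODE = 14  # A*16 + T*4 + G
_STOP_CODES = frozenset((48, 50, 56))  # TAA, TAG, TGA


def encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3 N=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of all overlapping k-mers; windows containing N get code -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        out = out * 4 + np.where(col == 4, 0, col)
        bad |= col == 4
    out[bad] = -1
    return out


@dataclass(frozen=True)
class OrfResult:
    """Longest predicted ORF (0-based half-open nt coordinates, stop included)."""

    start: int
    end: int
    frame: int
    has_start: bool
    has_stop: bool

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def complete(self) -> bool:
        return self.has_start and self.has_stop


@dataclass
class FeatureMatrix:
    """Named per-transcript feature values plus optional class labels.

    ``data`` is indexed by transcript id with one column per feature;
    ``labels`` (if present) aligns with the index, coded by class tag.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    def binary_labels(self, positive: str = "lncRNA") -> np.ndarray:
        if self.labels is None:
            raise DataError("feature matrix has no labels")
        return (self.labels == positive).to_numpy(dtype=int)

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise DataError(f"unknown feature(s) {missing}; valid: {list(self.data.columns)}")
        return FeatureMatrix(self.data[list(names)].copy(), self.labels)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        if self.labels is not None:
            out.insert(len(out.columns), "label", self.labels)
        return out.reset_index(names="id")


def gc_content(t: Transcript) -> float:
    """(G+C) / (A+C+G+T); N excluded from both counts."""
    counts = np.bincount(encode(t.seq), minlength=5)
    denom = counts[:4].sum()
    if denom == 0:
        logger.warning("sequence '%s' is all-N; GC content reported as 0", t.id)
        return 0.0
    return float((counts[1] + counts[2]) / denom)


def stop_codon_counts(t: Transcript) -> tuple[int, int, int]:
    """Non-overlapping stop-codon counts in each of the three forward frames."""
    codes = encode(t.seq)
    tri = _window_codes(codes, 3)
    out = []
    for frame in range(3):
        w = tri[frame::3]
        out.append(int(np.isin(w, list(_STOP_CODES)).sum()))
    return tuple(out)  # type: ignore[return-value]


def stop_codon_sd(t: Transcript) -> float:
    """Population standard deviation (divisor 3) of the three frame counts."""
    if len(t.seq) < 3:
        logger.warning("sequence '%s' shorter than 3 nt; stop-codon SD is 0", t.id)
        return 0.0
    scc = np.array(stop_codon_counts(t), dtype=float)
    return float(np.sqrt(np.mean((scc - scc.mean()) ** 2)))


def find_longest_orf(t: Transcript) -> OrfResult:
    """Longest ORF over the three forward frames.

    Priority order: longest complete ATG..stop ORF (stop codon included);
    failing that, the longest ATG-initiated stop-free stretch; failing
    that, the longest stop-free stretch in any frame. Ties break to the
    smaller start, then the smaller frame.
    """
    L = len(t.seq)
    if L < 3:
        return OrfResult(0, 0, 0, False, False)
    codes = encode(t.seq)
    tri = _window_codes(codes, 3)
    atg_pos = np.flatnonzero(tri == _ATG_CODE)
    stop_pos = np.flatnonzero(np.isin(tri, list(_STOP_CODES)))

    # Complete ORFs: each ATG paired with the first in-frame downstream stop.
    complete: list[tuple[int, int, int]] = []  # (length, start, frame)
    open_stretch: list[tuple[int, int, int]] = []
    for frame in range(3):
        stops_f = stop_pos[stop_pos % 3 == frame]
        for a in atg_pos[atg_pos % 3 == frame]:
            idx = np.searchsorted(stops_f, a)
            if idx < len(stops_f):
                s = stops_f[idx]
                complete.append((int(s) + 3 - int(a), int(a), frame))
            else:
                length = ((L - int(a)) // 3) * 3
                if length >= 3:
                    open_stretch.append((length, int(a), frame))

    def _best(cands: list[tuple[int, int, int]]) -> tuple[int, int, int]:
        return max(cands, key=lambda c: (c[0], -c[1], -c[2]))

    if complete:
        length, start, frame = _best(complete)
        return OrfResult(start, start + length, frame, True, True)
    if open_stretch:
        length, start, frame = _best(open_stretch)
        return OrfResult(start, start + length, frame, True, False)

    # No ATG anywhere: longest stop-free codon run in any frame.
    best: tuple[int, int, int] | None = None
    for frame in range(3):
        ncod = (L - frame) // 3
        if ncod == 0:
            continue
        starts = frame + 3 * np.arange(ncod)
        is_stop = np.isin(tri[starts], list(_STOP_CODES))
        run_start = 0
        i = 0
        while i <= ncod:
            if i == ncod or is_stop[i]:
                run_len = i - run_start
                if run_len > 0:
                    cand = (3 * run_len, int(starts[run_start]), frame)
                    if best is None or (cand[0], -cand[1], -cand[2]) > (
                        best[0],
                        -best[1],
                        -best[2],
                    ):
                        best = cand
                run_start = i + 1
            i += 1
    if best is None:
        return OrfResult(0, 0, 0, False, False)
    length, start, frame = best
    return OrfResult(start, start + length, frame, False, False)


def cds_features(orf: OrfResult, t: Transcript) -> tuple[float, int, float, float]:
    """(ORF integrity, CDS length, CDS score, CDS percentage).

    The CDS score is a deterministic stand-in for an external CDS scorer:
    length plus a completeness bonus (100) plus a Kozak-context bonus (25
    when position -3 from the ATG is A/G and position +4 is G). Monotone
    in ORF length and rewards completeness.
    """
    integrity = 1.0 if orf.complete else 0.0
    cds_len = orf.length_nt
    cds_percent = cds_len / len(t.seq) if len(t.seq) else 0.0
    kozak = 0
    if orf.has_start:
        s = orf.start
        if s - 3 >= 0 and s + 3 < len(t.seq):
            if t.seq[s - 3] in "AG" and t.seq[s + 3] == "G":
                kozak = 1
    cds_score = cds_len + 100.0 * integrity + 25.0 * kozak
    return integrity, cds_len, cds_score, cds_percent


# Bjellqvist-style pKa set: N/C termini plus ionizable side chains.
_PKA_POS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_PKA_NEG = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


def peptide_charge(counts: dict[str, int], ph: float) -> float:
    """Net charge of a peptide at a given pH (Henderson–Hasselbalch sums)."""
    charge = 0.0
    for grp, pka in _PKA_POS.items():
        n = 1 if grp == "Nterm" else counts.get(grp, 0)
        charge += n / (1.0 + 10.0 ** (ph - pka))
    for grp, pka in _PKA_NEG.items():
        n = 1 if grp == "Cterm" else counts.get(grp, 0)
        charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(peptide: str) -> float:
    """pH of zero net charge, solved by bisection on [0, 14].

    Stops when |charge| < 1e-4 or the bracket is narrower than 1e-3.
    The empty peptide returns 7.0 by convention.
    """
    if not peptide:
        logger.warning("empty peptide; isoelectric point reported as 7.0")
        return 7.0
    counts = {aa: peptide.count(aa) for aa in "KRHDECY"}
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = peptide_charge(counts, mid)
        if abs(q) < 1e-4 or (hi - lo) < 1e-3:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def translate_orf(orf: OrfResult, t: Transcript) -> str:
    """Translate the ORF region (standard code, trailing stop excluded)."""
    end = orf.end - 3 if orf.has_stop else orf.end
    region = t.seq[orf.start : end]
    region = region[: len(region) // 3 * 3]
    if not region:
        return ""
    pep = str(Seq(region).translate())
    return pep.replace("*", "")


def peptide_features(orf: OrfResult, t: Transcript) -> tuple[int, float]:
    """(peptide length in residues, theoretical isoelectric point)."""
    pep = translate_orf(orf, t)
    return len(pep), isoelectric_point(pep)


def fickett_parts(t: Transcript) -> tuple[dict[str, float], dict[str, float]]:
    """Position parameters MAX(N_i)/(MIN(N_i)+1) and content proportions per base."""
    codes = encode(t.seq)
    pos_params: dict[str, float] = {}
    totals = np.zeros(4)
    per_pos = np.zeros((4, 3))
    for offset in range(3):
        c = np.bincount(codes[offset::3], minlength=5)[:4]
        per_pos[:, offset] = c
        totals += c
    for bi, base in enumerate("ACGT"):
        pos_params[base] = float(per_pos[bi].max() / (per_pos[bi].min() + 1.0))
    denom = totals.sum()
    content = {
        base: float(totals[bi] / denom) if denom else 0.0 for bi, base in enumerate("ACGT")
    }
    return pos_params, content


def fickett_score(t: Transcript) -> float:
    """Fickett TESTCODE score: weighted sum of 8 table-looked-up probabilities."""
    if len(t.seq) < 3:
        raise DataError(f"sequence '{t.id}' too short for Fickett ({len(t.seq)} nt)")
    pos_params, content = fickett_parts(t)
    score = 0.0
    for base in "ACGT":
        score += (
            _fickett.lookup(
                pos_params[base], _fickett.POSITION_THRESHOLDS, _fickett.POSITION_PROB[base]
            )
            * _fickett.POSITION_WEIGHT[base]
        )
        score += (
            _fickett.lookup(
                content[base], _fickett.CONTENT_THRESHOLDS, _fickett.CONTENT_PROB[base]
            )
            * _fickett.CONTENT_WEIGHT[base]
        )
    return score


def trinuc_frequencies(t: Transcript) -> np.ndarray:
    """Overlapping 3-mer proportions (64 values summing to 1; N windows skipped)."""
    if len(t.seq) < 3:
        raise DataError(f"sequence '{t.id}' too short for tri-nucleotide counts")
    tri = _window_codes(encode(t.seq), 3)
    valid = tri[tri >= 0]
    if len(valid) == 0:
        logger.warning("sequence '%s' has no N-free 3-mer window; zero vector", t.id)
        return np.zeros(64)
    return np.bincount(valid, minlength=64) / len(valid)


def trinuc_matrix(ts: Sequence[Transcript]) -> pd.DataFrame:
    """Per-transcript 64-column tri-nucleotide frequency table."""
    rows = np.vstack([trinuc_frequencies(t) for t in ts])
    return pd.DataFrame(rows, index=[t.id for t in ts], columns=TRINUCLEOTIDES)


def resolve_feature_list(feature_list: str | Sequence[str]) -> list[str]:
    """Expand a preset name or validate an explicit feature-name list."""
    if isinstance(feature_list, str):
        if feature_list not in PRESETS:
            raise DataError(f"unknown preset '{feature_list}'; valid: {sorted(PRESETS)}")
        return list(PRESETS[feature_list])
    vocab = set(SCALAR_FEATURES) | set(TRINUCLEOTIDES)
    unknown = [f for f in feature_list if f not in vocab]
    if unknown:
        raise DataError(
            f"unknown feature name(s) {unknown}; valid names are the scalar features "
            f"{SCALAR_FEATURES} and the 64 tri-nucleotides"
        )
    return list(feature_list)


def extract_features(
    ts: Sequence[Transcript],
    hex_table: "HexamerTable | None" = None,
    feature_list: str | Sequence[str] = "full",
) -> FeatureMatrix:
    """Build the feature matrix for a set of transcripts.

    ``feature_list`` is an explicit ordered list of names or one of the
    presets ``animal`` / ``plant`` / ``full``. The hexamer table is only
    required when the ``Hexamer`` feature is requested.
    """
    from .hexamer import hexamer_score  # local import to avoid a cycle

    names = resolve_feature_list(feature_list)
    need_hex = "Hexamer" in names
    if need_hex and hex_table is None:
        raise DataError("feature 'Hexamer' requested but no hexamer table given")
    wanted_tri = [n for n in names if n in _TRINUC_INDEX]
    need_orf = bool(
        {"ORF_in", "CDS_len", "CDS_score", "CDS_percent", "Pep_len", "PI"} & set(names)
    ) or need_hex

    rows = np.empty((len(ts), len(names)))
    for ri, t in enumerate(ts):
        vals: dict[str, float] = {}
        if "Length" in names:
            vals["Length"] = float(len(t.seq))
        if "GC_content" in names:
            vals["GC_content"] = gc_content(t)
        if "Stop_codon_std" in names:
            vals["Stop_codon_std"] = stop_codon_sd(t)
        if need_orf:
            orf = find_longest_orf(t)
            integrity, cds_len, cds_score, cds_percent = cds_features(orf, t)
            vals["ORF_in"] = integrity
            vals["CDS_len"] = float(cds_len)
            vals["CDS_score"] = cds_score
            vals["CDS_percent"] = cds_percent
            if "Pep_len" in names or "PI" in names:
                pep_len, pi = peptide_features(orf, t)
                vals["Pep_len"] = float(pep_len)
                vals["PI"] = pi
            if need_hex:
                vals["Hexamer"] = hexamer_score(t, hex_table, orf=orf)
        if "Fickett" in names:
            vals["Fickett"] = fickett_score(t)
        if wanted_tri:
            freqs = trinuc_frequencies(t)
            for tri_name in wanted_tri:
                vals[tri_name] = float(freqs[_TRINUC_INDEX[tri_name]])
        rows[ri] = [vals[n] for n in names]

    data = pd.DataFrame(rows, index=[t.id for t in ts], columns=names)
    labels = None
    if any(t.label is not None for t in ts):
        labels = pd.Series([t.label for t in ts], index=data.index, name="label")
    if not np.isfinite(rows).all():
        raise DataError("non-finite feature value produced")
    return FeatureMatrix(data, labels)
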