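"""Transcript I/O: FASTA reading/writing and tabular artifact plumbing.

Transcripts are sense-strand nucleotide sequences over {A,C,G,T,N}; RNA
input (U) is folded to the DNA alphabet at parse time so every downstream
computation works on one alphabet.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")

POSITIVE_LABEL = "lncRNA"
NEGATIVE_LABEL = "mRNA"


class DataError(ValueError):
    """Malformed or invalid input data."""


@dataclass(frozen=True)
class Transcript:
    """One transcript record: unique id, DNA-alphabet sequence, optional class label."""

    id: str
    seq: str
    label: str | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def clean_sequence(raw: str, record: str = "?") -> str:
    """Uppercase, map U->T, and reject characters outside {A,C,G,T,N}."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise DataError(
            f"record '{record}': illegal character(s) {sorted(bad)!r}; "
            "allowed alphabet is A,C,G,T,N (U is accepted and mapped to T)"
        )
    return seq


def read_fasta(path: str | Path, label: str | None = None) -> list[Transcript]:
    """Read a (possibly gzipped) multi-FASTA file into Transcript records.

    The header token before the first whitespace becomes the id; ids must be
    unique within the file. Sequences shorter than 200 nt (the conventional
    lncRNA length floor) are accepted with a warning so that prediction on
    short inputs remains possible.
    """
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for header, raw in SimpleFastaParser(handle):
            tid = header.split()[0] if header.split() else header
            if tid in seen:
                raise DataError(f"duplicate sequence id '{tid}' in {path}")
            seen.add(tid)
            seq = clean_sequence(raw, record=tid)
            if not seq:
                raise DataError(f"record '{tid}' in {path} has an empty sequence")
            if len(seq) < 200:
                logger.warning(
                    "sequence '%s' is %d nt (<200 nt lncRNA definition); kept anyway",
                    tid,
                    len(seq),
                )
            transcripts.append(Transcript(id=tid, seq=seq, label=label))
    if not transcripts:
        raise DataError(f"no records found in {path}")
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 70) -> None:
    """Write transcripts as wrapped multi-FASTA."""
    path = Path(path)
    with open(path, "wt") as out:
        for t in transcripts:
            out.write(f">{t.id}\n")
            for i in range(0, len(t.seq), width):
                out.write(t.seq[i : i + width] + "\n")


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as a UTF-8 TSV ('.' decimal separator, header row)."""
    if not isinstance(rows, pd.DataFrame):
        rows = rows.to_frame()
    if rows.empty:
        raise DataError("refusing to write an empty table")
    rows.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def as_transcripts(pairs: Sequence[tuple[str, str]], label: str | None = None) -> list[Transcript]:
    """Build Transcript records from (id, seq) pairs (used by tests and synth)."""
    return [Transcript(id=i, seq=clean_sequence(s, record=i), label=label) for i, s in pairs]
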