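"""Transcript sequence data model and FASTA I/O.

Transcripts are single-stranded RNA and are handled in the sense
orientation throughout: sequences are normalised to uppercase {A,C,G,U},
with T mapped to U and any other character (IUPAC ambiguity codes,
gaps, ...) mapped to N.  N positions never participate in k-mer or PWM
windows downstream.

Poly-adenylation tails are an artefact of library preparation rather
than genomic sequence, so terminal A-runs of at least ``min_run``
nucleotides (default 8) are removed before any motif counting.
Internal coordinates are 0-based half-open; anything written to a
report is 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

DEFAULT_POLYA_MIN_RUN = 8


class Compartment(str, Enum):
    """Cellular compartment a transcript was detected in."""

    EXOSOME = "exosome"
    CELL = "cell"


def normalize_rna(sequence: str) -> str:
    """Uppercase, map T to U, and collapse non-ACGU characters to N."""
    seq = sequence.upper().replace("T", "U")
    return "".join(c if c in RNA_ALPHABET else "N" for c in seq)


def strip_polya(sequence: str, min_run: int = DEFAULT_POLYA_MIN_RUN) -> str:
    """Remove a 3' terminal poly-A run of at least ``min_run`` nucleotides.

    The entire terminal run is removed; shorter terminal runs and
    internal A-runs are left untouched.  Idempotent.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    n = len(sequence)
    i = n
    while i > 0 and sequence[i - 1] == "A":
        i -= 1
    if n - i >= min_run:
        if i == 0:
            log.warning("sequence is a pure poly-A run; trimming leaves it empty")
        return sequence[:i]
    return sequence


def revcomp(sequence: str) -> str:
    """Reverse complement of an RNA string over {A,C,G,U,N}."""
    bad = set(sequence) - set("ACGUN")
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptRecord:
    """One RNA transcript with its compartment and cell-line labels."""

    id: str
    sequence: str
    compartment: Compartment = Compartment.EXOSOME
    cell_line: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptSet:
    """An ordered, id-unique collection of transcripts (test or control)."""

    records: list[TranscriptRecord] = field(default_factory=list)
    label: str = "test"
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate transcript id: {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def lengths(self) -> list[int]:
        return [r.length for r in self.records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


def read_fasta(
    path: str | Path,
    label: str = "test",
    compartment: Compartment = Compartment.EXOSOME,
    cell_line: str = "",
    polya_min_run: int | None = DEFAULT_POLYA_MIN_RUN,
) -> TranscriptSet:
    """Read a FASTA file into a :class:`TranscriptSet`.

    Sequences are normalised (uppercase, T->U, ambiguity codes -> N) and,
    unless ``polya_min_run`` is None, poly-A trimmed.  Duplicate ids and
    empty files are errors.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id: {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = normalize_rna(str(entry.seq))
        if polya_min_run is not None:
            trimmed = strip_polya(seq, polya_min_run)
            if len(trimmed) != len(seq):
                log.info(
                    "poly-A trim: %s lost %d nt", entry.id, len(seq) - len(trimmed)
                )
            seq = trimmed
        records.append(
            TranscriptRecord(entry.id, seq, compartment=compartment, cell_line=cell_line)
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return TranscriptSet(records, label=label, provenance=str(path))


def write_fasta(tset: TranscriptSet | Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts to a FASTA file (unwrapped lines)."""
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in tset
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)
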