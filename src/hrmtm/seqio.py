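"""Sequence ingestion, canonicalization, and elementary sequence statistics.

Amplicons analysed by high-resolution melting (HRM) are short PCR products,
typically 50-200 nt, whose melting temperature depends on base composition
and stacking order.  Everything downstream (nearest-neighbor summation, the
empirical Tm formula, calibration) consumes the canonical sequences and the
two composition statistics defined here:

* ``gc_percent`` -- percentage of G+C over the *full* sequence length, in
  percentage points (e.g. 37.18 for 29 G+C in 78 nt);
* ``stack_count`` -- the number ``n`` of nearest-neighbor stacks, one less
  than the sequence length.

These two conventions use different denominators on purpose and must not be
merged: GC content is a per-base composition, while ``n`` counts adjacent
base-pair doublets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Raised for sequences that cannot be canonicalized to {A,C,G,T}, len >= 2."""


@dataclass(frozen=True)
class SequenceRecord:
    """One amplicon: identifier, canonical A/C/G/T sequence, free-form metadata."""

    id: str
    sequence: str
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, record_id=self.id))

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(raw: str, *, record_id: str | None = None) -> str:
    """Canonicalize a raw sequence string.

    Whitespace is stripped, lowercase is uppercased and ``U`` is mapped to
    ``T`` (with a logged warning, so RNA-style input stays usable).  IUPAC
    ambiguity codes (N, R, Y, ...) and any non-nucleotide character are
    rejected; so are sequences shorter than 2 nt, which have no
    nearest-neighbor stack.

    Raises
    ------
    SequenceError
        Naming the offending character and its 1-based position, or the
        offending length.
    """
    label = f" in record {record_id!r}" if record_id else ""
    seq = "".join(raw.split()).upper()
    if "U" in seq:
        logger.warning("mapping %d 'U' base(s) to 'T'%s", seq.count("U"), label)
        seq = seq.replace("U", "T")
    for pos, base in enumerate(seq, start=1):
        if base not in _VALID_BASES:
            raise SequenceError(
                f"invalid character {base!r} at position {pos}{label}: "
                "only unambiguous A/C/G/T sequences are supported"
            )
    if len(seq) < 2:
        raise SequenceError(f"sequence{label} has length {len(seq)}; need >= 2 for one stack")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (single- or multi-record, wrapped or unwrapped) FASTA file.

    Returns one :class:`SequenceRecord` per entry, in file order.  The FASTA
    description after the first whitespace is kept as ``metadata['description']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        meta = {"description": entry.description} if entry.description != entry.id else {}
        records.append(SequenceRecord(id=entry.id, sequence=str(entry.seq), metadata=meta))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def read_fasta_lenient(path: str | Path) -> tuple[list[SequenceRecord], list[str]]:
    """Like :func:`read_fasta`, but collects per-record validation errors.

    Returns (valid records in file order, error messages for the rest).
    Used by batch front-ends where one bad record should not abort the run.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    errors: list[str] = []
    empty = True
    for entry in SeqIO.parse(str(path), "fasta"):
        empty = False
        try:
            records.append(SequenceRecord(id=entry.id, sequence=str(entry.seq)))
        except SequenceError as exc:
            errors.append(str(exc))
    if empty:
        raise SequenceError(f"no FASTA records found in {path}")
    return records, errors


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (unwrapped lines, so round-trips are byte-stable)."""
    entries = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(entries)


def gc_percent(sequence: str) -> float:
    """GC content in percentage points: 100 * (#G + #C) / full length.

    Full precision is retained; round only for display.
    """
    return 100.0 * (sequence.count("G") + sequence.count("C")) / len(sequence)


def stack_count(sequence: str) -> int:
    """Number of nearest-neighbor stacks n = length - 1."""
    if len(sequence) < 2:
        raise SequenceError(f"sequence of length {len(sequence)} has no stacks")
    return len(sequence) - 1


def reverse_complement(sequence: str) -> str:
    """Watson-Crick complement, reversed (the partner strand read 5'->3')."""
    return sequence.translate(_COMPLEMENT)[::-1]


def is_self_complementary(sequence: str) -> bool:
    """True iff the strand equals its own reverse complement (even length only)."""
    return sequence == reverse_complement(sequence)


def sequence_stats(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Per-record statistics table: id, length, n, gc_percent."""
    rows = [
        {
            "id": r.id,
            "length": len(r.sequence),
            "n": stack_count(r.sequence),
            "gc_percent": gc_percent(r.sequence),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["id", "length", "n", "gc_percent"])
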