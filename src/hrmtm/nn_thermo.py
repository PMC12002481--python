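"""Nearest-neighbor thermodynamic summation for DNA duplexes.

The nearest-neighbor (NN) model writes the enthalpy and entropy of duplex
formation as a sum over the overlapping dinucleotide "stacks" of the strand,
plus one initiation term per terminus (depending on whether the terminal
base pair is G*C or A*T) and an entropy-only symmetry correction for
self-complementary strands.  The 16 dinucleotides collapse to 10 canonical
stack classes under reverse-complement equivalence (e.g. reading TG on one
strand is the same doublet as reading CA on the partner strand, so TG uses
the CA/GT parameters).

Units are fixed throughout: delta-H in kcal/mol, delta-S in cal/(K*mol).
The unified NN parameter set of Allawi & SantaLucia (1997/1998) is built in
as the default; an alternative table may be loaded from a TSV file, which
must then supply all 13 entries (no partial overrides).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Tuple

import pandas as pd

from .seqio import SequenceRecord, gc_percent, is_self_complementary, reverse_complement, stack_count

logger = logging.getLogger(__name__)

ThermoPair = Tuple[float, float]  # (dH kcal/mol, dS cal/(K*mol))
SymmetryPolicy = Literal["auto", "always", "never"]

#: The 10 canonical stack classes, written 5'-XY-3' over its base-wise complement.
STACK_CLASS_NAMES: tuple[str, ...] = (
    "AA/TT", "AT/TA", "TA/AT", "CA/GT", "GT/CA",
    "CT/GA", "GA/CT", "CG/GC", "GC/CG", "GG/CC",
)

_DEFAULT_STACKS: dict[str, ThermoPair] = {
    "AA/TT": (-7.9, -22.2),
    "AT/TA": (-7.2, -20.4),
    "TA/AT": (-7.2, -21.3),
    "CA/GT": (-8.5, -22.7),
    "GT/CA": (-8.4, -22.4),
    "CT/GA": (-7.8, -21.0),
    "GA/CT": (-8.2, -22.2),
    "CG/GC": (-10.6, -27.2),
    "GC/CG": (-9.8, -24.4),
    "GG/CC": (-8.0, -19.9),
}
_DEFAULT_INIT_GC: ThermoPair = (0.1, -2.8)
_DEFAULT_INIT_AT: ThermoPair = (2.3, 4.1)
_DEFAULT_SYMMETRY: ThermoPair = (0.0, -1.4)

_SPECIAL_KEYS = ("init_terminal_GC", "init_terminal_AT", "symmetry_correction")


class ParameterError(ValueError):
    """Raised for malformed or incomplete nearest-neighbor parameter tables."""


def _class_key(dinucleotide: str) -> str:
    """Map a dinucleotide to its canonical stack class name."""
    complement = dinucleotide.translate(str.maketrans("ACGT", "TGCA"))
    key = f"{dinucleotide}/{complement}"
    if key in _DEFAULT_STACKS:
        return key
    rc = reverse_complement(dinucleotide)
    return f"{rc}/{rc.translate(str.maketrans('ACGT', 'TGCA'))}"


#: Canonical class for each of the 16 dinucleotides (revcomp equivalence).
DINUCLEOTIDE_CLASS: dict[str, str] = {
    a + b: _class_key(a + b) for a in "ACGT" for b in "ACGT"
}


@dataclass(frozen=True)
class NNParameterSet:
    """A complete nearest-neighbor parameter table (10 stacks + 3 special terms)."""

    stacks: Mapping[str, ThermoPair]
    init_terminal_GC: ThermoPair = _DEFAULT_INIT_GC
    init_terminal_AT: ThermoPair = _DEFAULT_INIT_AT
    symmetry_correction: ThermoPair = _DEFAULT_SYMMETRY

    def __post_init__(self) -> None:
        missing = [k for k in STACK_CLASS_NAMES if k not in self.stacks]
        if missing:
            raise ParameterError(f"parameter set is missing stack class(es): {', '.join(missing)}")
        extra = [k for k in self.stacks if k not in STACK_CLASS_NAMES]
        if extra:
            raise ParameterError(f"unknown stack class(es): {', '.join(extra)}")
        for name, (dh, ds) in self.stacks.items():
            if dh >= 0 or ds >= 0:
                logger.warning("stack %s has non-negative parameter (dH=%s, dS=%s)", name, dh, ds)

    @classmethod
    def default(cls) -> "NNParameterSet":
        return cls(stacks=dict(_DEFAULT_STACKS))


@dataclass(frozen=True)
class ThermoResult:
    """Total duplex thermodynamics plus the composition statistics of the strand."""

    dH_total: float  # kcal/mol
    dS_total: float  # cal/(K*mol)
    gc_percent: float  # percentage points
    n: int  # stack count = length - 1
    length: int  # nt
    symmetry_applied: bool
    sequence_id: str = ""


def load_parameter_set(source: str | Path | None = None) -> NNParameterSet:
    """Return the built-in default table, or a complete replacement read from TSV.

    The TSV must have columns ``name``, ``dH_kcal_per_mol``, ``dS_cal_per_K_mol``
    and one row for each of the 10 stack classes plus ``init_terminal_GC``,
    ``init_terminal_AT`` and ``symmetry_correction``.
    """
    if source is None:
        return NNParameterSet.default()
    try:
        table = pd.read_csv(source, sep="\t")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParameterError(f"cannot read parameter file {source}: {exc}") from exc
    required_cols = {"name", "dH_kcal_per_mol", "dS_cal_per_K_mol"}
    if not required_cols.issubset(table.columns):
        raise ParameterError(
            f"parameter file {source} must have columns {sorted(required_cols)}"
        )
    entries = {
        str(row["name"]): (float(row["dH_kcal_per_mol"]), float(row["dS_cal_per_K_mol"]))
        for _, row in table.iterrows()
    }
    missing = [k for k in (*STACK_CLASS_NAMES, *_SPECIAL_KEYS) if k not in entries]
    if missing:
        raise ParameterError(f"parameter file {source} is missing entries: {', '.join(missing)}")
    return NNParameterSet(
        stacks={k: entries[k] for k in STACK_CLASS_NAMES},
        init_terminal_GC=entries["init_terminal_GC"],
        init_terminal_AT=entries["init_terminal_AT"],
        symmetry_correction=entries["symmetry_correction"],
    )


def stack_lookup(dinucleotide: str, params: NNParameterSet | None = None) -> ThermoPair:
    """(dH, dS) of one dinucleotide stack via its canonical class.

    ``stack_lookup(d) == stack_lookup(reverse_complement(d))`` by construction.
    """
    params = params or NNParameterSet.default()
    try:
        return params.stacks[DINUCLEOTIDE_CLASS[dinucleotide.upper()]]
    except KeyError:
        raise ParameterError(f"invalid dinucleotide {dinucleotide!r}") from None


def duplex_thermo(
    record: SequenceRecord | str,
    params: NNParameterSet | None = None,
    symmetry_policy: SymmetryPolicy = "auto",
) -> ThermoResult:
    """Total delta-H and delta-S of the duplex formed by a strand and its complement.

    Sums the stack parameters over the n = length - 1 overlapping dinucleotides
    and always adds both terminal initiation terms (G*C terminus vs A*T
    terminus).  The entropy-only symmetry correction is applied according to
    ``symmetry_policy``:

    * ``auto`` (default) -- only for self-complementary strands, the standard
      NN convention;
    * ``always`` / ``never`` -- force it on or off.
    """
    if isinstance(record, str):
        record = SequenceRecord(id="", sequence=record)
    params = params or NNParameterSet.default()
    seq = record.sequence

    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        sdh, sds = params.stacks[DINUCLEOTIDE_CLASS[seq[i : i + 2]]]
        dh += sdh
        ds += sds
    for terminal in (seq[0], seq[-1]):
        init = params.init_terminal_GC if terminal in "GC" else params.init_terminal_AT
        dh += init[0]
        ds += init[1]

    if symmetry_policy == "auto":
        apply_symmetry = is_self_complementary(seq)
    elif symmetry_policy == "always":
        apply_symmetry = True
    elif symmetry_policy == "never":
        apply_symmetry = False
    else:
        raise ValueError(f"unknown symmetry policy {symmetry_policy!r}")
    if apply_symmetry:
        dh += params.symmetry_correction[0]
        ds += params.symmetry_correction[1]

    return ThermoResult(
        dH_total=dh,
        dS_total=ds,
        gc_percent=gc_percent(seq),
        n=stack_count(seq),
        length=len(seq),
        symmetry_applied=apply_symmetry,
        sequence_id=record.id,
    )


def thermo_table(
    records: list[SequenceRecord],
    params: NNParameterSet | None = None,
    symmetry_policy: SymmetryPolicy = "auto",
) -> pd.DataFrame:
    """Tabulate duplex_thermo over records: id, length, n, gc_percent, dH, dS, symmetry."""
    rows = []
    for r in records:
        t = duplex_thermo(r, params, symmetry_policy)
        rows.append(
            {
                "id": r.id,
                "length": t.length,
                "n": t.n,
                "gc_percent": t.gc_percent,
                "dH_total": t.dH_total,
                "dS_total": t.dS_total,
                "symmetry_applied": t.symmetry_applied,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "length", "n", "gc_percent", "dH_total", "dS_total", "symmetry_applied"],
    )
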