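"""Packaged study data and synthetic sequence generation.

The package ships, as plain-text data files, the full study dataset used to
build and validate the empirical Tm formula:

* 28 amplicon sequences (5 diatom species x 6 primer systems, with one
  primer amplifying only 3 species), as FASTA;
* measured HRM melting temperatures of the 20 training amplicons;
* the published per-amplicon thermodynamic summary (GC%, n, dH, dS);
* the published predicted/measured/difference table for the 8 validation
  amplicons;
* the default nearest-neighbor parameter table.

Published values are shipped verbatim, including internally inconsistent
rows; :func:`load_paper_dataset` recomputes GC% and n from each sequence and
flags disagreements instead of silently fixing either side.  A known case:
the UPA99/Navicula row lists GC 42.19% with n = 63 while its printed 63-nt
sequence has 26 G+C (41.27%, n = 62).

The synthetic generators (:func:`generate_sequence`,
:func:`generate_benchmark`) produce count-exact GC compositions so that
GC-dependent properties are testable without sampling noise, and benchmark
Tm values drawn as model output plus Gaussian measurement noise for
parameter-recovery experiments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .nn_thermo import NNParameterSet, SymmetryPolicy, load_parameter_set
from .seqio import SequenceRecord, gc_percent, read_fasta, stack_count
from .tm_model import TmCoefficients, predict_from_sequence

Key = tuple[str, str]  # (primer, species)

_DATA_FILES = {
    "amplicons": "amplicons_table7.fasta",
    "measured_tm": "measured_tm_table6.tsv",
    "thermo": "thermo_table8.tsv",
    "validation": "validation_table9.tsv",
    "nn_parameters": "nn_parameters_table5.tsv",
}

#: sha256 of each packaged data file; guards against silent corruption.
_CHECKSUMS = {
    "amplicons": "883705af07f87aa71d25a4816414db8ad26668b31140b1f821db71303850577b",
    "measured_tm": "a15f630755d40447e973b1337746ce17f190acb395b359cc2313b6c4c4aea065",
    "thermo": "55ebe7286011fbb577c06638bde5e29f7c1b30c238f7a34bdcaade07ad1bc12a",
    "validation": "4bf42d8257ef3a8e78f608fdee5ec674bb0789cf5296ab14c66dc51f0a5b96f7",
    "nn_parameters": "64896d069e5b0e6824021d0ba87534ae4fede789c34681491702fa504b00130e",
}

#: GC-percent slack (points) below which a printed-vs-recomputed difference is
#: attributed to the rounding rule (half-up vs half-even) rather than the data.
_GC_FLAG_TOLERANCE = 0.005


class FixtureError(RuntimeError):
    """Raised when a packaged data file is missing or corrupted."""


@dataclass(frozen=True)
class PaperDataset:
    """The bundled study dataset, keyed by (primer, species)."""

    records: Mapping[Key, SequenceRecord]
    measured_tm_table6: Mapping[Key, float]
    thermo_table8: pd.DataFrame  # primer, species, gc_percent, n, dH, dS (printed)
    table9: pd.DataFrame  # primer, species, predicted, measured, difference (printed)
    consistency: pd.DataFrame  # printed vs recomputed GC%/n per record, with flags

    @property
    def record_count(self) -> int:
        return len(self.records)


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file (by short name or file name)."""
    fname = _DATA_FILES.get(name, name)
    path = resources.files("hrmtm.data").joinpath(fname)
    with resources.as_file(path) as concrete:
        return Path(concrete)


def _verify(name: str, path: Path) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = _CHECKSUMS[name]
    if digest != expected:
        raise FixtureError(
            f"packaged data file {path.name} is corrupted "
            f"(sha256 {digest[:12]}... != expected {expected[:12]}...)"
        )


def _record_id(primer: str, species: str) -> str:
    return f"{primer}|{species.replace(' ', '_')}"


def _split_id(record_id: str) -> Key:
    primer, species = record_id.split("|", 1)
    return primer, species.replace("_", " ")


def load_default_parameters() -> NNParameterSet:
    """The packaged nearest-neighbor table (identical to the built-in default)."""
    path = data_path("nn_parameters")
    _verify("nn_parameters", path)
    return load_parameter_set(path)


def load_paper_dataset() -> PaperDataset:
    """Load the packaged study dataset and recompute per-record statistics.

    Printed values are never mutated; the ``consistency`` frame carries the
    recomputed GC% and n next to the printed ones with a boolean flag per
    row.  Loading is read-only and idempotent.
    """
    paths = {name: data_path(name) for name in _DATA_FILES}
    for name in ("amplicons", "measured_tm", "thermo", "validation"):
        _verify(name, paths[name])

    fasta_records = read_fasta(paths["amplicons"])
    records: dict[Key, SequenceRecord] = {}
    for rec in fasta_records:
        primer, species = _split_id(rec.id)
        records[(primer, species)] = SequenceRecord(
            id=rec.id, sequence=rec.sequence, metadata={"primer": primer, "species": species}
        )

    tm6 = pd.read_csv(paths["measured_tm"], sep="\t")
    measured = {
        (row.primer, row.species): float(row.tm_measured_celsius) for row in tm6.itertuples()
    }

    thermo = pd.read_csv(paths["thermo"], sep="\t")
    table9 = pd.read_csv(paths["validation"], sep="\t")

    cons_rows = []
    for row in thermo.itertuples():
        key = (row.primer, row.species)
        seq = records[key].sequence
        gc_new = gc_percent(seq)
        n_new = stack_count(seq)
        gc_mismatch = abs(gc_new - float(row.gc_percent)) > _GC_FLAG_TOLERANCE + 1e-12
        n_mismatch = n_new != int(row.n)
        cons_rows.append(
            {
                "primer": row.primer,
                "species": row.species,
                "gc_printed": float(row.gc_percent),
                "gc_recomputed": gc_new,
                "n_printed": int(row.n),
                "n_recomputed": n_new,
                "mismatch": bool(gc_mismatch or n_mismatch),
            }
        )
    consistency = pd.DataFrame(cons_rows)

    return PaperDataset(
        records=records,
        measured_tm_table6=measured,
        thermo_table8=thermo,
        table9=table9,
        consistency=consistency,
    )


def thermo_recomputation_deltas(
    dataset: PaperDataset | None = None,
    symmetry_policy: SymmetryPolicy = "auto",
) -> pd.DataFrame:
    """Printed minus recomputed dH/dS per amplicon — a diagnostic, not a test.

    The published per-amplicon totals are not exactly reproducible from the
    printed sequences (how the symmetry term was handled, and possibly which
    sequence revisions were summed, is not recorded), so the deltas are
    reported for inspection and never asserted.
    """
    from .nn_thermo import duplex_thermo

    ds = dataset or load_paper_dataset()
    rows = []
    for row in ds.thermo_table8.itertuples():
        key = (row.primer, row.species)
        t = duplex_thermo(ds.records[key], symmetry_policy=symmetry_policy)
        rows.append(
            {
                "primer": row.primer,
                "species": row.species,
                "dH_printed": float(row.dH_kcal_per_mol),
                "dH_recomputed": t.dH_total,
                "dH_delta": float(row.dH_kcal_per_mol) - t.dH_total,
                "dS_printed": float(row.dS_cal_per_K_mol),
                "dS_recomputed": t.dS_total,
                "dS_delta": float(row.dS_cal_per_K_mol) - t.dS_total,
            }
        )
    return pd.DataFrame(rows)


def generate_sequence(length: int, gc_target: float, seed: int) -> SequenceRecord:
    """A random sequence with an exact GC count: round(gc_target*length/100) bases
    are G or C (each with probability 1/2), the rest A or T, uniformly shuffled.

    Deterministic for a given (length, gc_target, seed).
    """
    if length < 2:
        raise ValueError(f"length must be >= 2, got {length}")
    if not 0.0 <= gc_target <= 100.0:
        raise ValueError(f"gc_target must be in [0, 100], got {gc_target}")
    rng = np.random.default_rng(seed)
    n_gc = int(round(gc_target * length / 100.0))
    strong = rng.choice(["G", "C"], size=n_gc)
    weak = rng.choice(["A", "T"], size=length - n_gc)
    bases = np.concatenate([strong, weak])
    rng.shuffle(bases)
    return SequenceRecord(
        id=f"synth_L{length}_GC{gc_target:g}_s{seed}",
        sequence="".join(bases),
        metadata={"synthetic": "true"},
    )


def generate_benchmark(
    n_records: int,
    length_range: tuple[int, int] = (60, 155),
    gc_range: tuple[float, float] = (34.0, 56.0),
    coefficients: TmCoefficients | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    symmetry_policy: SymmetryPolicy = "auto",
) -> list[tuple[SequenceRecord, float]]:
    """Synthetic (sequence, measured-Tm) pairs for calibration experiments.

    Lengths are uniform over ``length_range`` and GC targets uniform over
    ``gc_range``; defaults emulate the study's amplicons (60-155 nt, GC
    roughly 34-56%).  The synthetic "measured" Tm is the model prediction
    under ``coefficients`` plus Gaussian noise of sd ``noise_sd`` degC —
    i.e. ideal instrument noise with none of the systematic effects (salt,
    dye, ramp rate) a real HRM run would add.
    """
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    rng = np.random.default_rng(seed)
    out: list[tuple[SequenceRecord, float]] = []
    for _ in range(n_records):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gc_target = float(rng.uniform(*gc_range))
        child_seed = int(rng.integers(0, 2**31 - 1))
        rec = generate_sequence(length, gc_target, child_seed)
        tm = predict_from_sequence(rec, None, coefficients, symmetry_policy).tm_celsius
        out.append((rec, tm + float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else tm))
    return out
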