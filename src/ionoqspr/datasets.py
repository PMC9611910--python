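"""Dataset tables: per-ionophore sensitivities and SMILES files.

The training table is a CSV with columns ``id``, ``smiles`` and one or more
``sens_<metal>`` columns holding potentiometric sensitivities in mV per
decade. Empty sensitivity cells are missing values (the literature corpus
does not cover every ionophore/metal combination), never zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

PathLike = Union[str, Path]


@dataclass
class SensitivityRecord:
    """One ionophore: id, SMILES and measured sensitivities (mV/decade)."""

    id: str
    smiles: str
    sensitivity: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for metal, value in self.sensitivity.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite sensitivity for {self.id!r}/{metal}: {value}")


class DatasetFormatError(ValueError):
    """Input table violates the dataset CSV contract."""


def _metal_columns(columns) -> List[str]:
    return [c for c in columns if c.startswith("sens_")]


def read_dataset(path: PathLike) -> List[SensitivityRecord]:
    """Read a sensitivity CSV into records.

    Requires ``id`` and ``smiles`` columns; every ``sens_<metal>`` column
    becomes a sensitivity entry where non-empty. Duplicate ids are an error.
    """
    df = pd.read_csv(path, dtype={"id": str, "smiles": str},
                     float_precision="round_trip")
    for required in ("id", "smiles"):
        if required not in df.columns:
            raise DatasetFormatError(f"{path}: missing required column {required!r}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise DatasetFormatError(f"{path}: duplicate ids {sorted(set(dupes))}")
    metals = _metal_columns(df.columns)
    records = []
    for row in df.itertuples(index=False):
        sens = {}
        for col in metals:
            value = getattr(row, col)
            if value is not None and not (isinstance(value, float) and math.isnan(value)):
                sens[col.removeprefix("sens_")] = float(value)
        records.append(SensitivityRecord(id=str(row.id), smiles=str(row.smiles), sensitivity=sens))
    return records


def write_dataset(records: List[SensitivityRecord], path: PathLike,
                  metals: Optional[List[str]] = None) -> None:
    """Write records to the dataset CSV; missing sensitivities stay blank.

    ``metals`` fixes the column set/order; default is the sorted union of
    metals present in the records.
    """
    if metals is None:
        metals = sorted({m for r in records for m in r.sensitivity})
    rows = []
    for r in records:
        row = {"id": r.id, "smiles": r.smiles}
        for m in metals:
            row[f"sens_{m}"] = r.sensitivity.get(m)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", "smiles"] + [f"sens_{m}" for m in metals])
    df.to_csv(path, index=False)


def read_smiles_file(path: PathLike) -> List[Tuple[str, str]]:
    """Read a ``.smi`` file: one ``SMILES<whitespace>id`` per line.

    Blank lines and ``#`` comment lines are skipped; a missing id defaults
    to the 1-based line position.
    """
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else str(lineno)
        out.append((smiles, mol_id))
    return out


def load_candidate_ionophores() -> List[Tuple[str, str]]:
    """The four diphenylphosphoryl acetamide candidate ionophores.

    SMILES encoded from the published IUPAC names. Substance 2 is
    reconstructed: its printed name duplicates substance 1's
    (butane-1,4-diyl linker) while the surrounding discussion treats
    substances 1-3 as a linker-length series ending at hexane-1,6-diyl, so
    the fixture encodes substance 2 with the intermediate pentane-1,5-diyl
    linker. Treat predictions for substance 2 accordingly.
    """
    with resources.files("ionoqspr").joinpath("data/candidate_ionophores.smi").open() as fh:
        return [
            (parts[0], parts[1])
            for parts in (line.split() for line in fh)
            if parts and not parts[0].startswith("#")
        ]


def load_reference_training_set(path: PathLike) -> List[SensitivityRecord]:
    """Load a user-supplied transcription of the literature training corpus.

    The 41-ionophore corpus (structures plus Cu/Cd/Pb sensitivities) exists
    only in print; no machine-readable copy ships with this package. Once
    transcribed to the standard dataset CSV, this loader validates the
    expected shape (41 rows, all three metal columns present somewhere).
    """
    records = read_dataset(path)
    if len(records) != 41:
        raise DatasetFormatError(
            f"{path}: expected the 41-ionophore corpus, found {len(records)} rows"
        )
    present = {m for r in records for m in r.sensitivity}
    missing = {"Cu", "Cd", "Pb"} - present
    if missing:
        raise DatasetFormatError(f"{path}: no sensitivities at all for {sorted(missing)}")
    return records
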