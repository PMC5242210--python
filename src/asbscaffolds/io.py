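"""Reading activity tables (delimited text / SDF) and writing pipeline outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from asbscaffolds.curation import ActivityRecord

logger = logging.getLogger(__name__)

__all__ = ["ColumnMap", "read_activity_table", "read_sdf_structures", "records_from_frame", "write_tsv"]

#: default header names, matching common ChEMBL-style exports
DEFAULT_COLUMNS = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "target_id": "target_id",
    "organism": "organism",
    "relationship_type": "relationship_type",
    "confidence_score": "confidence_score",
    "measurement_type": "standard_type",
    "relation": "standard_relation",
    "value": "standard_value",
    "unit": "standard_units",
}


@dataclass
class ColumnMap:
    """Logical field -> header name mapping for input dialects."""

    columns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def missing(self, header: list[str]) -> list[str]:
        return [k for k, col in self.columns.items() if col not in header]


def records_from_frame(df: pd.DataFrame, colmap: ColumnMap | None = None, max_malformed_fraction: float = 0.5) -> tuple[list[ActivityRecord], int]:
    """DataFrame -> ActivityRecords; malformed rows skipped with diagnostics.

    Raises if more than ``max_malformed_fraction`` of rows are malformed.
    """
    colmap = colmap or ColumnMap()
    missing = colmap.missing(list(df.columns))
    if missing:
        raise ValueError(f"input table is missing required columns: {missing}")
    c = colmap.columns
    records: list[ActivityRecord] = []
    n_malformed = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            records.append(
                ActivityRecord(
                    compound_id=str(row[c["compound_id"]]),
                    smiles=str(row[c["smiles"]]),
                    target_id=str(row[c["target_id"]]),
                    target_organism=str(row[c["organism"]]),
                    relationship_type=str(row[c["relationship_type"]]),
                    confidence_score=int(row[c["confidence_score"]]),
                    measurement_type=str(row[c["measurement_type"]]),
                    relation=str(row[c["relation"]]),
                    value=float(row[c["value"]]),
                    unit=str(row[c["unit"]]),
                )
            )
        except (ValueError, TypeError, KeyError):
            n_malformed += 1
            logger.warning("skipping malformed row %d", i)
    if len(df) and n_malformed / len(df) > max_malformed_fraction:
        raise ValueError(f"{n_malformed}/{len(df)} rows malformed, aborting")
    return records, n_malformed


def read_activity_table(path: str | Path, sep: str = "\t", colmap: ColumnMap | None = None, max_malformed_fraction: float = 0.5) -> tuple[list[ActivityRecord], int]:
    """Delimited text with a header row -> ActivityRecords."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        logger.warning("empty activity table: %s", path)
    return records_from_frame(df, colmap, max_malformed_fraction)


def read_sdf_structures(path: str | Path, id_property: str = "compound_id") -> dict[str, str]:
    """SDF (V2000) -> {compound_id: SMILES}; unparsable entries skipped."""
    out: dict[str, str] = {}
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unparsable SDF entry %d", i)
            continue
        cid = mol.GetProp(id_property) if mol.HasProp(id_property) else (
            mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"SDF{i:05d}"
        )
        out[cid] = Chem.MolToSmiles(mol)
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
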