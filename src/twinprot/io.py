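"""TSV/JSON readers and writers for the pipeline's tabular interfaces.

All tables are tab-separated with a header row; an empty cell is a missing
value.  Protein matrices are written subjects-as-rows with a ``subject_id``
index column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import ROSTER_COLUMNS, ProteinMatrix, SimulationTruth

__all__ = [
    "read_roster",
    "write_roster",
    "read_proteins",
    "write_proteins",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth",
    "read_truth",
]


def write_roster(roster: pd.DataFrame, path) -> None:
    roster.to_csv(path, sep="\t", index=False)


def read_roster(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str, "pair_id": str, "zygosity": str}
    )
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"roster is missing columns: {missing}")
    df["pair_id"] = df["pair_id"].where(df["pair_id"].notna(), None)
    # "NA" zygosity (singletons) must survive the round trip as a string
    df["zygosity"] = df["zygosity"].fillna("NA")
    for col in ("haemolysed", "qc_fail"):
        df[col] = df[col].astype(bool)
    return df


def write_proteins(proteins: ProteinMatrix, path) -> None:
    proteins.values.to_csv(path, sep="\t", index=True, index_label="subject_id")


def read_proteins(path, transform_state: str = "raw") -> ProteinMatrix:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    return ProteinMatrix(df, transform_state=transform_state)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=True, index_label="subject_id")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def write_truth(truth: SimulationTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_truth(path) -> SimulationTruth:
    return SimulationTruth(**json.loads(Path(path).read_text()))
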