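"""Readers and writers for the delimited-text artifacts.

Patient and visit tables are comma-separated with a header row. A code
matrix is persisted as a sparse triplet file (patient_id, code, 1) next to
a JSON manifest carrying the full patient/code universes and the window,
so all-zero rows and columns survive the round trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .cohort import CodeMatrix, EventWindow

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import GroundTruth

PATIENT_COLUMNS = ["patient_id", "pair_id", "cohort_arm", "sex", "age",
                   "income_quintile", "rural", "index_date"]
VISIT_COLUMNS = ["patient_id", "visit_date", "code"]


def write_patients(patients: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = PATIENT_COLUMNS + [c for c in patients.columns if c not in PATIENT_COLUMNS]
    patients[cols].to_csv(path, index=False)
    return path


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "pair_id": str})
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: patient table missing columns {sorted(missing)}")
    df["rural"] = df["rural"].astype(bool)
    df["index_date"] = df["index_date"].astype(int)
    return df


def write_visits(visits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    visits[VISIT_COLUMNS].to_csv(path, index=False)
    return path


def read_visits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    missing = set(VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: visit table missing columns {sorted(missing)}")
    df["visit_date"] = df["visit_date"].astype(int)
    return df


def write_ground_truth(truth: "GroundTruth", path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "signal_code_ids": sorted(truth.signal_code_ids),
        "code_to_factor": dict(sorted(truth.code_to_factor.items())),
        "factor_or": dict(sorted(truth.factor_or.items())),
        "pair_rho_by_sex": [
            {"factor_a": f, "factor_b": g, "sex": s, "rho": rho}
            for (f, g, s), rho in sorted(truth.pair_rho_by_sex.items())
        ],
        "noise_code_ids": sorted(truth.noise_code_ids),
        "case_code": truth.case_code,
        "filler_code": truth.filler_code,
    }
    path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def read_ground_truth(path: str | Path) -> "GroundTruth":
    from .synthetic import GroundTruth

    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        signal_code_ids=set(doc["signal_code_ids"]),
        code_to_factor=dict(doc["code_to_factor"]),
        factor_or={k: float(v) for k, v in doc["factor_or"].items()},
        pair_rho_by_sex={(e["factor_a"], e["factor_b"], e["sex"]): float(e["rho"])
                         for e in doc["pair_rho_by_sex"]},
        noise_code_ids=set(doc["noise_code_ids"]),
        case_code=doc["case_code"],
        filler_code=doc["filler_code"],
    )


def write_code_matrix(matrix: CodeMatrix, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    triplet_path = directory / "code_matrix.csv"
    manifest_path = directory / "code_matrix.manifest.json"
    import numpy as np

    rows, cols = np.nonzero(matrix.values)
    pd.DataFrame({
        "patient_id": [matrix.patient_ids[i] for i in rows],
        "code": [matrix.codes[j] for j in cols],
        "value": 1,
    }).to_csv(triplet_path, index=False)
    manifest = {
        "patient_ids": matrix.patient_ids,
        "codes": matrix.codes,
        "window": None if matrix.window is None else {
            "days_before": matrix.window.days_before,
            "days_after": matrix.window.days_after,
        },
    }
    manifest_path.write_text(json.dumps(manifest) + "\n")
    return {"triplets": triplet_path, "manifest": manifest_path}


def read_code_matrix(directory: str | Path) -> CodeMatrix:
    directory = Path(directory)
    manifest = json.loads((directory / "code_matrix.manifest.json").read_text())
    import numpy as np

    patient_ids = list(manifest["patient_ids"])
    codes = list(manifest["codes"])
    values = np.zeros((len(patient_ids), len(codes)), dtype=np.uint8)
    trip = pd.read_csv(directory / "code_matrix.csv", dtype={"patient_id": str, "code": str})
    row_of = {p: i for i, p in enumerate(patient_ids)}
    col_of = {c: j for j, c in enumerate(codes)}
    values[[row_of[p] for p in trip["patient_id"]],
           [col_of[c] for c in trip["code"]]] = 1
    window = None
    if manifest["window"] is not None:
        window = EventWindow(**manifest["window"])
    return CodeMatrix(patient_ids, codes, values, window)
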