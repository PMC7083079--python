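"""OGTT patient records and their delimited-text serialization.

File format: CSV with header ``patient_id,time_min,glucose_mg_dl,insulin_uU_ml``,
one row per measurement, five rows per patient under the standard protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RECORD_COLUMNS = ("patient_id", "time_min", "glucose_mg_dl", "insulin_uU_ml")


class RecordValidationError(ValueError):
    """Raised with a collected, row-addressed report of malformed records."""


@dataclass(frozen=True)
class OGTTRecord:
    """One patient's measured OGTT: times, glycemia and insulinemia vectors."""

    patient_id: str
    times: np.ndarray
    G_exp: np.ndarray
    I_exp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.G_exp, dtype=float)
        i = np.asarray(self.I_exp, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "G_exp", g)
        object.__setattr__(self, "I_exp", i)
        if not (t.ndim == 1 and t.shape == g.shape == i.shape):
            raise RecordValidationError(
                f"patient {self.patient_id}: times/G/I must be equal-length vectors"
            )
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise RecordValidationError(
                f"patient {self.patient_id}: times must strictly increase from 0"
            )
        if np.any(~np.isfinite(g)) or np.any(~np.isfinite(i)) or np.any(g <= 0) or np.any(i <= 0):
            raise RecordValidationError(
                f"patient {self.patient_id}: measurements must be finite and positive"
            )

    @property
    def n_points(self) -> int:
        return self.times.size

    @property
    def basal_glycemia(self) -> float:
        return float(self.G_exp[0])

    @property
    def basal_insulinemia(self) -> float:
        return float(self.I_exp[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "time_min": self.times,
                "glucose_mg_dl": self.G_exp,
                "insulin_uU_ml": self.I_exp,
            }
        )


def write_records(records: list[OGTTRecord], path) -> None:
    pd.concat([r.to_frame() for r in records], ignore_index=True).to_csv(
        path, index=False
    )


def read_records(path, expected_points: int | None = 5) -> list[OGTTRecord]:
    """Read and validate an OGTT record file.

    Row-level problems (missing cells, non-positive values, bad times) are
    collected into one report naming patient, row and column, rather than
    aborting at the first failure.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RecordValidationError(f"{path}: missing columns {missing_cols}")

    errors: list[str] = []
    for col in ("time_min", "glucose_mg_dl", "insulin_uU_ml"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        for row in bad:
            errors.append(
                f"patient {df.loc[row, 'patient_id']!r}, file row {row + 2}, "
                f"column {col}: missing or non-numeric value"
            )
    if errors:
        raise RecordValidationError(f"{path}:\n  " + "\n  ".join(errors))

    records: list[OGTTRecord] = []
    for pid, sub in df.groupby("patient_id", sort=False):
        sub = sub.sort_values("time_min")
        if expected_points is not None and len(sub) != expected_points:
            errors.append(
                f"patient {pid!r}: expected {expected_points} measurement rows, "
                f"found {len(sub)}"
            )
            continue
        try:
            records.append(
                OGTTRecord(
                    patient_id=str(pid),
                    times=sub["time_min"].to_numpy(float),
                    G_exp=sub["glucose_mg_dl"].to_numpy(float),
                    I_exp=sub["insulin_uU_ml"].to_numpy(float),
                )
            )
        except RecordValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise RecordValidationError(f"{path}:\n  " + "\n  ".join(errors))
    return records
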