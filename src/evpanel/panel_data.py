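"""Data model and I/O for multiplex EV-protein panel measurements.

Concentrations from bead-based multiplex immunoassays are left-censored at a
biomarker-specific lower limit of detection (LLoD).  Missing values and
explicit below-LLoD results are treated identically: both are imputed to the
LLoD, and an imputation mask records exactly which cells were replaced.
Concentrations are stored as positive floats in pg/mL; any log transform is a
classifier concern, not a storage concern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PanelSchema",
    "PatientRecord",
    "CohortDataset",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "impute_llod",
    "imputation_fraction",
]

#: sentinel accepted in measurement CSV cells for a below-LLoD / missing result
BELOW_LLOD_TOKENS = {"", "NA", "nan", "NaN", "<LLoD", "<LLOD", "BLQ"}

STAGES = ("I", "II", "none")


class CohortParseError(ValueError):
    """Structured parse/validation error naming the offending row or column."""


@dataclass(frozen=True)
class PanelSchema:
    """Ordered biomarker names with per-biomarker LLoD (pg/mL, strictly > 0)."""

    biomarkers: tuple[str, ...]
    llod: Mapping[str, float]

    def __init__(self, biomarkers: Sequence[str], llod: Mapping[str, float]):
        biomarkers = tuple(biomarkers)
        if len(set(biomarkers)) != len(biomarkers):
            raise ValueError("biomarker names must be unique")
        missing = [b for b in biomarkers if b not in llod]
        if missing:
            raise ValueError(f"LLoD missing for biomarkers: {missing}")
        llod = {b: float(llod[b]) for b in biomarkers}
        bad = [b for b, v in llod.items() if not v > 0]
        if bad:
            raise ValueError(f"LLoD must be strictly positive, violated by: {bad}")
        object.__setattr__(self, "biomarkers", biomarkers)
        object.__setattr__(self, "llod", llod)

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    def llod_vector(self) -> np.ndarray:
        return np.array([self.llod[b] for b in self.biomarkers])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({b: self.llod[b] for b in self.biomarkers}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelSchema":
        mapping = yaml.safe_load(Path(path).read_text())
        return cls(list(mapping), mapping)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({b: self.llod[b] for b in self.biomarkers}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelSchema":
        mapping = json.loads(Path(path).read_text())
        return cls(list(mapping), mapping)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: opaque id, case/control label, stage, free-text condition.

    ``label`` is 1 for a case, 0 for a control.  Stage is one of ``I``/``II``
    for cases and ``none`` for controls.
    """

    patient_id: str
    label: int
    stage: str = "none"
    noted_condition: str = "none"

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r} for {self.patient_id}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r} for {self.patient_id}")
        if self.stage in ("I", "II") and self.label != 1:
            raise ValueError(f"patient {self.patient_id}: staged patients must be cases")
        if self.label == 0 and self.stage != "none":
            raise ValueError(f"patient {self.patient_id}: controls must have stage 'none'")


@dataclass
class CohortDataset:
    """Patients x biomarkers concentration matrix with LLoD imputation mask.

    Invariants: values strictly positive; wherever ``imputed_mask`` is True the
    value equals that biomarker's LLoD exactly; shapes agree with
    ``len(patients) x schema.n_biomarkers``.
    """

    schema: PanelSchema
    patients: list[PatientRecord]
    values: np.ndarray
    imputed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros_like(self.values, dtype=bool)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        n, p = len(self.patients), self.schema.n_biomarkers
        if self.values.shape != (n, p):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {p})")
        if self.imputed_mask.shape != (n, p):
            raise ValueError("imputed_mask shape mismatch")
        if not np.all(self.values > 0):
            raise ValueError("concentrations must be strictly positive")
        llod = self.schema.llod_vector()
        if not np.allclose(self.values[self.imputed_mask], np.broadcast_to(llod, self.values.shape)[self.imputed_mask]):
            raise ValueError("imputed cells must equal the biomarker LLoD exactly")
        ids = [p_.patient_id for p_ in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients])

    @property
    def stages(self) -> np.ndarray:
        return np.array([p.stage for p in self.patients])

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def biomarker_index(self, name: str) -> int:
        try:
            return self.schema.biomarkers.index(name)
        except ValueError:
            raise KeyError(f"unknown biomarker {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.biomarker_index(name)]

    def subset_biomarkers(self, names: Sequence[str]) -> "CohortDataset":
        idx = [self.biomarker_index(n) for n in names]
        schema = PanelSchema(list(names), {n: self.schema.llod[n] for n in names})
        return CohortDataset(schema, list(self.patients), self.values[:, idx].copy(), self.imputed_mask[:, idx].copy())

    def subset_patients(self, indices: Sequence[int]) -> "CohortDataset":
        indices = np.asarray(indices)
        return CohortDataset(
            self.schema,
            [self.patients[i] for i in indices],
            self.values[indices].copy(),
            self.imputed_mask[indices].copy(),
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(patients table, measurements table) in the on-disk CSV layout."""
        pat = pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "label": ["case" if p.label else "control" for p in self.patients],
                "stage": [p.stage for p in self.patients],
                "noted_condition": [p.noted_condition for p in self.patients],
            }
        )
        meas = pd.DataFrame(self.values, columns=list(self.schema.biomarkers))
        # imputed cells round-trip as the below-LLoD token
        meas = meas.astype(object)
        rows, cols = np.nonzero(self.imputed_mask)
        for r, c in zip(rows, cols):
            meas.iat[r, c] = "<LLoD"
        meas.insert(0, "patient_id", self.patient_ids)
        return pat, meas


def impute_llod(raw_values: np.ndarray, schema: PanelSchema) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing/below-LLoD entries with the biomarker LLoD.

    ``raw_values`` is a patients x biomarkers float matrix where NaN marks a
    missing or below-detection cell.  Returns ``(values, imputed_mask)``; the
    mask marks exactly the replaced cells.  Idempotent.
    """
    raw = np.asarray(raw_values, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != schema.n_biomarkers:
        raise ValueError(f"expected shape (*, {schema.n_biomarkers}), got {raw.shape}")
    if np.any(raw[~np.isnan(raw)] < 0):
        raise ValueError("negative concentrations are physically impossible")
    mask = np.isnan(raw)
    values = raw.copy()
    llod = schema.llod_vector()
    values[mask] = np.broadcast_to(llod, raw.shape)[mask]
    # zeros are below any positive LLoD: treat as below-detection as well
    zero = values == 0
    values[zero] = np.broadcast_to(llod, raw.shape)[zero]
    mask = mask | zero
    return values, mask


def imputation_fraction(dataset: CohortDataset, biomarker: str) -> float:
    """Fraction of patients whose value for ``biomarker`` was imputed to LLoD."""
    j = dataset.biomarker_index(biomarker)
    return float(dataset.imputed_mask[:, j].mean())


def _parse_patients(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "label", "stage", "noted_condition"}
    if not required.issubset(df.columns):
        raise CohortParseError(f"patients CSV missing columns: {sorted(required - set(df.columns))}")
    records = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pid = row["patient_id"].strip()
        if not pid:
            raise CohortParseError(f"patients CSV row {i}: missing patient id")
        if pid in seen:
            raise CohortParseError(f"duplicate patient_id {pid!r}")
        seen.add(pid)
        label_txt = row["label"].strip().lower()
        if label_txt in ("case", "1"):
            label = 1
        elif label_txt in ("control", "0"):
            label = 0
        else:
            raise CohortParseError(f"patients CSV row {i} ({pid}): bad label {row['label']!r}")
        stage = row["stage"].strip() or "none"
        try:
            records.append(PatientRecord(pid, label, stage, row["noted_condition"].strip() or "none"))
        except ValueError as e:
            raise CohortParseError(str(e)) from None
    return records


def read_cohort(patients_path: str | Path, measurements_path: str | Path, schema: PanelSchema) -> CohortDataset:
    """Read the two-CSV cohort layout and return a validated dataset.

    Measurement cells holding a below-LLoD token (``<LLoD``, ``NA``, empty, ...)
    are imputed to the biomarker's LLoD with the mask set.
    """
    patients = _parse_patients(patients_path)
    meas = pd.read_csv(measurements_path, dtype=str, keep_default_na=False)
    if "patient_id" not in meas.columns:
        raise CohortParseError("measurements CSV missing patient_id column")
    extra = [c for c in meas.columns if c != "patient_id" and c not in schema.biomarkers]
    if extra:
        raise CohortParseError(f"measurements CSV has unknown biomarker columns: {extra}")
    missing = [b for b in schema.biomarkers if b not in meas.columns]
    if missing:
        raise CohortParseError(f"measurements CSV missing biomarker columns: {missing}")
    meas = meas.set_index("patient_id")
    if meas.index.duplicated().any():
        dup = meas.index[meas.index.duplicated()][0]
        raise CohortParseError(f"duplicate patient_id {dup!r} in measurements CSV")
    ids = [p.patient_id for p in patients]
    absent = [i for i in ids if i not in meas.index]
    if absent:
        raise CohortParseError(f"measurements missing for patients: {absent}")
    raw = np.empty((len(ids), schema.n_biomarkers))
    for r, pid in enumerate(ids):
        for c, b in enumerate(schema.biomarkers):
            cell = str(meas.at[pid, b]).strip()
            if cell in BELOW_LLOD_TOKENS:
                raw[r, c] = np.nan
                continue
            try:
                raw[r, c] = float(cell)
            except ValueError:
                raise CohortParseError(f"non-numeric concentration {cell!r} at patient {pid}, biomarker {b}") from None
    try:
        values, mask = impute_llod(raw, schema)
    except ValueError as e:
        raise CohortParseError(str(e)) from None
    return CohortDataset(schema, patients, values, mask)


def write_cohort(dataset: CohortDataset, patients_path: str | Path, measurements_path: str | Path) -> None:
    """Write the two-CSV layout; read_cohort on the output round-trips exactly."""
    pat, meas = dataset.to_frames()
    pat.to_csv(patients_path, index=False)
    meas.to_csv(measurements_path, index=False)
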