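"""Domain types and I/O for pleural-effusion biomarker cohorts.

A *cohort* is a set of patients, each with a diagnostic label
(mesothelioma / other cancer / benign) and up to seven soluble-marker
concentrations measured in the effusion supernatant.  Assay readings of
exactly 0 mean "below the detection limit" and are kept as zeros with a
below-detection flag; a missing reading (insufficient material) is stored
as absent (NaN in the tabular form).

All modelling downstream works on the log10 scale; zeros are substituted
with 0.1 before taking the logarithm (:func:`log_transform`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import CohortValidationError, DegenerateDataError

__all__ = [
    "Diagnosis",
    "MARKERS",
    "MARKER_UNITS",
    "DEFAULT_SCHEMA",
    "DEFAULT_ALIASES",
    "Sample",
    "Cohort",
    "PairedRetest",
    "read_cohort",
    "write_cohort",
    "load_aliases",
    "log_transform",
    "retest_reliability",
]


class Diagnosis(str, enum.Enum):
    """Diagnostic group of an effusion."""

    MESOTHELIOMA = "mesothelioma"
    OTHER_CANCER = "other_cancer"
    BENIGN = "benign"


#: Canonical marker short names, in reporting order.
MARKERS: tuple[str, ...] = ("ha", "nerc", "cerc", "opn", "sdc1", "sdc2", "trx")

#: Unit metadata; units are carried as strings and never converted.
MARKER_UNITS: dict[str, str] = {
    "ha": "ug UA/mL",            # hyaluronan, as hyaluronan-derived uronic acid
    "nerc": "ng/mL",             # N-ERC/mesothelin (megakaryocyte potentiating factor)
    "cerc": "nM",                # C-ERC/mesothelin, MESOMARK-type assay units
    "opn": "ng/mL",              # osteopontin
    "sdc1": "assay units",       # syndecan-1
    "sdc2": "assay units",       # syndecan-2
    "trx": "assay units",        # thioredoxin
}

#: Default CSV column name per marker.
DEFAULT_SCHEMA: dict[str, str] = {
    "ha": "ha_ug_ua_ml",
    "nerc": "nerc_ng_ml",
    "cerc": "cerc",
    "opn": "opn",
    "sdc1": "sdc1",
    "sdc2": "sdc2",
    "trx": "trx",
}

#: Case-insensitive diagnosis aliases accepted out of the box.
DEFAULT_ALIASES: dict[str, Diagnosis] = {
    "mesothelioma": Diagnosis.MESOTHELIOMA,
    "mm": Diagnosis.MESOTHELIOMA,
    "malignant mesothelioma": Diagnosis.MESOTHELIOMA,
    "other_cancer": Diagnosis.OTHER_CANCER,
    "other cancer": Diagnosis.OTHER_CANCER,
    "metastatic": Diagnosis.OTHER_CANCER,
    "benign": Diagnosis.BENIGN,
}


@dataclass(frozen=True)
class Sample:
    """One patient's effusion measurement record.

    ``markers`` holds non-negative concentrations; a marker that was not
    measured is simply absent from the mapping.  ``below_detection[m]``
    is True exactly when ``markers[m] == 0``.
    """

    patient_id: str
    diagnosis: Diagnosis
    markers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, value in self.markers.items():
            if not math.isfinite(value) or value < 0:
                raise CohortValidationError(
                    f"sample {self.patient_id!r}: marker {name!r} has invalid "
                    f"concentration {value!r} (must be finite and >= 0)"
                )

    @property
    def below_detection(self) -> dict[str, bool]:
        return {m: v == 0 for m, v in self.markers.items()}

    @property
    def is_mesothelioma(self) -> bool:
        return self.diagnosis is Diagnosis.MESOTHELIOMA


class Cohort:
    """A named, ordered collection of :class:`Sample` with unique patient ids.

    Internally backed by a DataFrame with columns ``patient_id``,
    ``diagnosis`` and one float column per marker (NaN = not measured).
    """

    def __init__(self, name: str, data: pd.DataFrame):
        required = {"patient_id", "diagnosis"}
        missing = required - set(data.columns)
        if missing:
            raise CohortValidationError(f"cohort {name!r}: missing columns {sorted(missing)}")
        data = data.reset_index(drop=True).copy()
        data["patient_id"] = data["patient_id"].astype(str)
        dup = data["patient_id"].duplicated()
        if dup.any():
            ids = data.loc[dup, "patient_id"].tolist()
            raise CohortValidationError(f"cohort {name!r}: duplicate patient_id(s) {ids}")
        data["diagnosis"] = data["diagnosis"].map(
            lambda d: d if isinstance(d, Diagnosis) else Diagnosis(str(d))
        )
        for m in _marker_columns(data):
            col = pd.to_numeric(data[m], errors="coerce")
            neg = col < 0
            if neg.any():
                row = int(np.flatnonzero(neg.to_numpy())[0])
                raise CohortValidationError(
                    f"cohort {name!r}: negative concentration in column {m!r}, "
                    f"row {row} (patient_id={data.at[row, 'patient_id']!r})"
                )
            data[m] = col.astype(float)
        self.name = name
        self.data = data

    # -- construction -------------------------------------------------
    @classmethod
    def from_samples(cls, name: str, samples: Iterable[Sample]) -> "Cohort":
        rows = []
        for s in samples:
            row: dict = {"patient_id": s.patient_id, "diagnosis": s.diagnosis}
            row.update(s.markers)
            rows.append(row)
        frame = pd.DataFrame(rows)
        return cls(name, frame)

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    @property
    def samples(self) -> list[Sample]:
        out = []
        marker_cols = self.marker_names
        for _, row in self.data.iterrows():
            markers = {
                m: float(row[m]) for m in marker_cols if pd.notna(row[m])
            }
            out.append(Sample(row["patient_id"], row["diagnosis"], markers))
        return out

    @property
    def marker_names(self) -> list[str]:
        return _marker_columns(self.data)

    # -- modelling views ----------------------------------------------
    def outcome(self) -> np.ndarray:
        """Binary outcome: mesothelioma = 1, other cancer or benign = 0."""
        return (self.data["diagnosis"] == Diagnosis.MESOTHELIOMA).to_numpy(int)

    def group_counts(self) -> dict[Diagnosis, int]:
        counts = self.data["diagnosis"].value_counts()
        return {d: int(counts.get(d, 0)) for d in Diagnosis}

    def marker_frame(self, markers: Sequence[str], dropna: bool = True) -> pd.DataFrame:
        """Concentrations for ``markers`` plus an ``outcome`` column.

        With ``dropna`` (default) samples lacking any requested marker are
        removed, mirroring the per-marker N of the source assays.
        """
        for m in markers:
            if m not in self.data.columns:
                raise KeyError(f"marker {m!r} not present in cohort {self.name!r}")
        frame = self.data[["patient_id", *markers]].copy()
        frame["outcome"] = self.outcome()
        if dropna:
            frame = frame.dropna(subset=list(markers)).reset_index(drop=True)
        return frame


def _marker_columns(data: pd.DataFrame) -> list[str]:
    return [c for c in data.columns if c not in ("patient_id", "diagnosis")]


# ---------------------------------------------------------------------------
# CSV ingestion / emission
# ---------------------------------------------------------------------------

def load_aliases(path: str | Path) -> dict[str, Diagnosis]:
    """Load a plain key-value alias file mapping raw labels to diagnoses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {str(k).lower(): Diagnosis(str(v)) for k, v in raw.items()}


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    aliases: Mapping[str, Diagnosis] | None = None,
    name: str | None = None,
) -> Cohort:
    """Read a cohort from CSV.

    Parameters
    ----------
    path
        CSV with a header row; must contain ``patient_id`` and ``diagnosis``
        columns plus numeric (or blank) marker columns.
    schema
        marker-name -> column-name mapping; defaults to :data:`DEFAULT_SCHEMA`.
        Markers whose column is absent from the file are skipped.
    aliases
        raw diagnosis string (case-insensitive) -> :class:`Diagnosis`.
        Merged on top of :data:`DEFAULT_ALIASES`.

    Blank marker cells become absent markers; 0 cells are kept as 0 with the
    below-detection flag implied.  Negative values, unknown diagnosis labels
    and duplicate patient ids are rejected with the offending row named.
    """
    path = Path(path)
    schema = dict(schema or DEFAULT_SCHEMA)
    alias_map = {k.lower(): v for k, v in DEFAULT_ALIASES.items()}
    if aliases:
        alias_map.update({k.lower(): Diagnosis(v) for k, v in aliases.items()})

    raw = pd.read_csv(path)
    for col in ("patient_id", "diagnosis"):
        if col not in raw.columns:
            raise CohortValidationError(f"{path.name}: required column {col!r} missing")

    out = pd.DataFrame({"patient_id": raw["patient_id"].astype(str)})

    labels = raw["diagnosis"].astype(str).str.strip().str.lower()
    unknown = ~labels.isin(alias_map)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise CohortValidationError(
            f"{path.name}: unknown diagnosis {raw['diagnosis'].iloc[row]!r} at row {row} "
            f"(no alias configured)"
        )
    out["diagnosis"] = labels.map(alias_map)

    for marker, column in schema.items():
        if column not in raw.columns:
            continue
        values = pd.to_numeric(raw[column], errors="coerce")
        bad = values.isna() & raw[column].notna() & (raw[column].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"{path.name}: non-numeric value {raw[column].iloc[row]!r} in column "
                f"{column!r}, row {row}"
            )
        neg = values < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise CohortValidationError(
                f"{path.name}: negative concentration {values.iloc[row]} in column "
                f"{column!r}, row {row}"
            )
        out[marker] = values

    return Cohort(name or path.stem, out)


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> None:
    """Emit a cohort in the CSV schema accepted by :func:`read_cohort`."""
    schema = dict(schema or DEFAULT_SCHEMA)
    frame = cohort.data.copy()
    frame["diagnosis"] = frame["diagnosis"].map(lambda d: d.value)
    rename = {m: schema[m] for m in cohort.marker_names if m in schema}
    frame = frame.rename(columns=rename)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Log transformation with the 0 -> 0.1 substitution
# ---------------------------------------------------------------------------

#: Value substituted for below-detection zeros before taking log10.
ZERO_SUBSTITUTE = 0.1


def log_transform(value):
    """log10 of a concentration, with below-detection zeros set to 0.1 first.

    Accepts scalars or arrays.  ``log_transform(0) == -1.0`` by the
    substitution rule; the images of 0 and 0.1 therefore coincide.
    Negative input is rejected.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentrations must be non-negative")
    out = np.log10(np.where(arr == 0, ZERO_SUBSTITUTE, arr))
    if np.isscalar(value) or arr.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Retest reliability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedRetest:
    """Two measurements of the same marker from two effusions of one patient."""

    marker: str
    first: float
    second: float

    def __post_init__(self):
        if self.first < 0 or self.second < 0:
            raise CohortValidationError(
                f"paired retest for {self.marker!r}: concentrations must be >= 0"
            )


def retest_reliability(pairs: Sequence[PairedRetest]) -> dict[str, float]:
    """Spearman rank correlation between first and repeat measurements.

    Returns both ``rho`` and ``rho_squared`` (the squared rank correlation,
    the scale on which retest reliability of effusion markers is usually
    quoted).  Requires at least 3 pairs of the same marker; ties are handled
    with midranks.
    """
    if len(pairs) < 3:
        raise DegenerateDataError("retest reliability needs at least 3 pairs")
    markers = {p.marker for p in pairs}
    if len(markers) != 1:
        raise CohortValidationError(f"pairs mix markers: {sorted(markers)}")
    first = np.array([p.first for p in pairs], float)
    second = np.array([p.second for p in pairs], float)
    if np.all(first == first[0]) or np.all(second == second[0]):
        raise DegenerateDataError(
            "rank correlation undefined: a coordinate has zero rank variance"
        )
    rho = float(stats.spearmanr(first, second).statistic)
    return {"rho": rho, "rho_squared": rho * rho}
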