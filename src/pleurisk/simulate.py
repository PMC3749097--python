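"""Seeded synthetic effusion cohorts.

Each diagnostic group is modelled as a multivariate lognormal: marker
vectors are drawn from a multivariate normal on the log10 scale
(group-specific means/SDs plus a pairwise correlation structure) and
exponentiated back to concentrations.  Concentrations below a marker's
detection limit are censored to 0, which downstream code reads as the
below-detection flag — the same zero-inflation mechanism the assays
produce.

:func:`default_cohort_spec` packages group sizes matching the two source
referral-centre datasets (46/49/95 and 48/166/161) together with synthetic
log-scale locations.  The locations are package constants chosen to
reproduce the qualitative geometry of the real data — mesothelioma crosses
the 120 ug UA/mL hyaluronan gate in roughly half of cases and the
1050 ng/mL N-ERC gate in roughly 38%, non-mesothelioma essentially never
crosses either gate, hyaluronan and N-ERC share a log-scale R-squared of
about 0.35, and the remaining markers carry little or no group signal.
They are synthetic stand-ins, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, Diagnosis, MARKERS
from .errors import CohortValidationError

__all__ = ["GroupSpec", "CohortSpec", "generate_cohort", "default_cohort_spec"]


@dataclass
class GroupSpec:
    """Distributional description of one diagnostic group.

    All location/scale parameters live on the log10 scale; detection
    limits are on the raw concentration scale.
    """

    diagnosis: Diagnosis
    n: int
    log_mean: dict[str, float]
    log_sd: dict[str, float]
    detection_limit: dict[str, float] = field(default_factory=dict)
    #: pairwise correlation of log-values, keyed by (marker, marker)
    log_correlation: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        self.diagnosis = Diagnosis(self.diagnosis)
        if self.n < 1:
            raise CohortValidationError(f"group {self.diagnosis.value}: n must be >= 1")
        for m, sd in self.log_sd.items():
            if sd <= 0:
                raise CohortValidationError(
                    f"group {self.diagnosis.value}: log_sd[{m!r}] must be > 0"
                )
        for m, dl in self.detection_limit.items():
            if dl < 0:
                raise CohortValidationError(
                    f"group {self.diagnosis.value}: detection_limit[{m!r}] must be >= 0"
                )

    @property
    def markers(self) -> list[str]:
        # canonical order first so generation is invariant to mapping order
        known = [m for m in MARKERS if m in self.log_mean]
        extra = [m for m in self.log_mean if m not in MARKERS]
        return known + sorted(extra)

    def covariance(self) -> np.ndarray:
        """Log-scale covariance matrix; rejects non-PSD correlation input."""
        names = self.markers
        k = len(names)
        corr = np.eye(k)
        for (a, b), r in self.log_correlation.items():
            if a in names and b in names:
                i, j = names.index(a), names.index(b)
                corr[i, j] = corr[j, i] = r
        eig = np.linalg.eigvalsh(corr)
        if eig.min() < -1e-10:
            raise CohortValidationError(
                f"group {self.diagnosis.value}: correlation matrix is not "
                f"positive semi-definite (min eigenvalue {eig.min():.3g})"
            )
        sd = np.array([self.log_sd[m] for m in names])
        return corr * np.outer(sd, sd)


@dataclass
class CohortSpec:
    """A full synthetic-cohort recipe: one :class:`GroupSpec` per diagnosis."""

    name: str
    groups: list[GroupSpec]
    seed: int = 0

    def __post_init__(self):
        diagnoses = [g.diagnosis for g in self.groups]
        if len(set(diagnoses)) != len(diagnoses):
            raise CohortValidationError("group diagnoses must be distinct")

    # -- plain key-value (de)serialization ----------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "seed": self.seed,
            "groups": [
                {
                    "diagnosis": g.diagnosis.value,
                    "n": g.n,
                    "log_mean": dict(g.log_mean),
                    "log_sd": dict(g.log_sd),
                    "detection_limit": dict(g.detection_limit),
                    "log_correlation": {
                        f"{a}:{b}": r for (a, b), r in g.log_correlation.items()
                    },
                }
                for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortSpec":
        groups = [
            GroupSpec(
                diagnosis=Diagnosis(g["diagnosis"]),
                n=int(g["n"]),
                log_mean={k: float(v) for k, v in g["log_mean"].items()},
                log_sd={k: float(v) for k, v in g["log_sd"].items()},
                detection_limit={k: float(v) for k, v in g.get("detection_limit", {}).items()},
                log_correlation={
                    tuple(k.split(":")): float(v)
                    for k, v in g.get("log_correlation", {}).items()
                },
            )
            for g in raw["groups"]
        ]
        return cls(name=raw["name"], groups=groups, seed=int(raw.get("seed", 0)))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Draw a synthetic :class:`Cohort` from ``spec``.

    One seed controls the whole cohort; the stream is split deterministically
    per group, in group order, so regenerating with the same spec and seed
    yields an identical cohort.
    """
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    streams = root.spawn(len(spec.groups))
    frames = []
    offset = 0
    for g, ss in zip(spec.groups, streams):
        rng = np.random.default_rng(ss)
        names = g.markers
        mean = np.array([g.log_mean[m] for m in names])
        cov = g.covariance()
        logs = rng.multivariate_normal(mean, cov, size=g.n, method="cholesky")
        conc = 10.0 ** logs
        for j, m in enumerate(names):
            dl = g.detection_limit.get(m, 0.0)
            conc[conc[:, j] < dl, j] = 0.0
        frame = pd.DataFrame(conc, columns=names)
        frame.insert(0, "diagnosis", g.diagnosis)
        frame.insert(
            0,
            "patient_id",
            [f"{spec.name}-{g.diagnosis.value[:4]}-{offset + i:04d}" for i in range(g.n)],
        )
        offset += g.n
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    return Cohort(spec.name, data)


# ---------------------------------------------------------------------------
# Default synthetic study conditions
# ---------------------------------------------------------------------------

# Log10-scale locations/SDs per (marker, group). Synthetic stand-ins chosen
# once so that the generated cohorts show the qualitative structure of the
# source datasets (gate crossing rates, marker ranking, HA-N-ERC coupling);
# see docs/methods.md for the calibration rationale.
_MESO = Diagnosis.MESOTHELIOMA
_OTHER = Diagnosis.OTHER_CANCER
_BENIGN = Diagnosis.BENIGN

# C-ERC/mesothelin is generated as a fixed linear function of log N-ERC plus
# noise, shared across groups (the two fragments come from one precursor):
# cerc_log = -0.215 + 0.675 * nerc_log + eps (eps sd 0.298).  It is marginally
# informative but conditionally null given N-ERC — it can never add to a
# model that already contains N-ERC, mirroring its fate in the source data.
# The means/sds/correlations below are the implied per-group moments.
_LOG_MEAN: dict[str, dict[Diagnosis, float]] = {
    #         benign  other   meso
    "ha":   {_BENIGN: 0.90, _OTHER: 1.00, _MESO: 2.08},
    "nerc": {_BENIGN: 1.80, _OTHER: 1.95, _MESO: 2.95},
    "cerc": {_BENIGN: 1.000, _OTHER: 1.101, _MESO: 1.776},
    "opn":  {_BENIGN: 2.55, _OTHER: 2.55, _MESO: 2.55},
    "sdc1": {_BENIGN: 1.25, _OTHER: 1.25, _MESO: 1.25},
    "sdc2": {_BENIGN: 0.30, _OTHER: 0.30, _MESO: 0.30},
    "trx":  {_BENIGN: 1.50, _OTHER: 1.50, _MESO: 1.50},
}

_LOG_SD: dict[str, dict[Diagnosis, float]] = {
    "ha":   {_BENIGN: 0.30, _OTHER: 0.30, _MESO: 0.55},
    "nerc": {_BENIGN: 0.35, _OTHER: 0.35, _MESO: 0.40},
    "cerc": {_BENIGN: 0.38, _OTHER: 0.38, _MESO: 0.40},
    "opn":  {_BENIGN: 0.50, _OTHER: 0.50, _MESO: 0.50},
    "sdc1": {_BENIGN: 0.45, _OTHER: 0.45, _MESO: 0.45},
    "sdc2": {_BENIGN: 0.60, _OTHER: 0.60, _MESO: 0.60},
    "trx":  {_BENIGN: 0.50, _OTHER: 0.50, _MESO: 0.50},
}

#: Raw-scale detection limits; sdc2's limit sits near its median, giving the
#: large below-detection fraction seen for syndecan-2 in real effusions.
_DETECTION_LIMIT: dict[str, float] = {
    "ha": 1.0,
    "nerc": 10.0,
    "cerc": 1.0,
    "opn": 30.0,
    "sdc1": 3.0,
    "sdc2": 1.5,
    "trx": 5.0,
}

#: Log-scale correlations: HA-N-ERC R^2 ~ 0.35 (rho ~ 0.59); the C-ERC
#: correlations are the moments implied by the shared linear link to N-ERC
#: (they differ by group only because the N-ERC spread does).
_LOG_CORRELATION: dict[Diagnosis, dict[tuple[str, str], float]] = {
    _MESO: {
        ("ha", "nerc"): 0.59,
        ("nerc", "cerc"): 0.672,
        ("ha", "cerc"): 0.396,
    },
    _OTHER: {
        ("ha", "nerc"): 0.59,
        ("nerc", "cerc"): 0.622,
        ("ha", "cerc"): 0.367,
    },
    _BENIGN: {
        ("ha", "nerc"): 0.59,
        ("nerc", "cerc"): 0.622,
        ("ha", "cerc"): 0.367,
    },
}

_GROUP_SIZES: dict[str, dict[Diagnosis, int]] = {
    "generation": {_MESO: 46, _OTHER: 49, _BENIGN: 95},
    "validation": {_MESO: 48, _OTHER: 166, _BENIGN: 161},
}


def default_cohort_spec(
    dataset: Literal["generation", "validation"] = "generation",
    seed: int = 0,
) -> CohortSpec:
    """Packaged synthetic study conditions for either dataset.

    ``generation`` sizes the groups 46/49/95 (mesothelioma / other cancer /
    benign) and ``validation`` 48/166/161, matching the two source referral
    centres; the distributional constants are shared synthetic stand-ins.
    """
    if dataset not in _GROUP_SIZES:
        raise ValueError("dataset must be 'generation' or 'validation'")
    sizes = _GROUP_SIZES[dataset]
    groups = [
        GroupSpec(
            diagnosis=diag,
            n=sizes[diag],
            log_mean={m: _LOG_MEAN[m][diag] for m in MARKERS},
            log_sd={m: _LOG_SD[m][diag] for m in MARKERS},
            detection_limit=dict(_DETECTION_LIMIT),
            log_correlation=dict(_LOG_CORRELATION[diag]),
        )
        for diag in (_MESO, _OTHER, _BENIGN)
    ]
    return CohortSpec(name=f"synthetic-{dataset}", groups=groups, seed=seed)
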