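"""Cohort data model for MRI-derived molar tissue volumes.

A cohort is a set of participants (id, sex, chronological age in decimal
years) each contributing up to twelve molars, identified by their two-digit
FDI code.  Each tooth carries three tissue volumes in ml obtained from
T2-intensity segmentation: hard tooth tissue (dentine, enamel, cementum),
low-signal soft tissue, and high-signal soft tissue.  The modelling response
is the natural logarithm of the tissue ratio

    y = ln((low_soft + high_soft) / (hard + low_soft + high_soft)),

which falls roughly linearly with age as the pulp chamber mineralises.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VALID_FDI_MOLARS",
    "Sex",
    "MolarClass",
    "Participant",
    "ToothRecord",
    "Cohort",
    "SegmentationThresholds",
    "InvalidRecordError",
    "CohortLoadError",
    "response_from_volumes",
    "volumes_from_intensities",
    "read_cohort",
    "write_cohort",
]

#: The twelve permanent molars in FDI (two-digit) notation.
VALID_FDI_MOLARS = frozenset({16, 17, 18, 26, 27, 28, 36, 37, 38, 46, 47, 48})


class InvalidRecordError(ValueError):
    """A tooth record violates a structural invariant (volumes, codes, ids)."""


class CohortLoadError(ValueError):
    """A cohort file failed validation; carries per-row diagnostics."""

    def __init__(self, row_errors: list[str]):
        self.row_errors = list(row_errors)
        super().__init__(
            "cohort file failed validation:\n  " + "\n  ".join(self.row_errors)
        )


class Sex(enum.Enum):
    """Participant sex; female is the reference level throughout."""

    F = "F"
    M = "M"

    @classmethod
    def parse(cls, value: "Sex | str") -> "Sex":
        if isinstance(value, Sex):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise ValueError(f"sex must be F or M, got {value!r}") from None


class MolarClass(enum.IntEnum):
    """Molar position family shared across quadrants (1st/2nd/3rd molar)."""

    FIRST = 1
    SECOND = 2
    THIRD = 3

    @classmethod
    def from_fdi(cls, tooth: int) -> "MolarClass":
        if tooth not in VALID_FDI_MOLARS:
            raise ValueError(f"not a valid FDI molar code: {tooth}")
        return cls(tooth % 10 - 5)

    @property
    def label(self) -> str:
        return {1: "1st", 2: "2nd", 3: "3rd"}[int(self)]


#: Canonical class ordering used for vectors/matrices everywhere.
CLASS_ORDER: tuple[MolarClass, ...] = (
    MolarClass.FIRST,
    MolarClass.SECOND,
    MolarClass.THIRD,
)


def response_from_volumes(
    hard_ml: float, low_soft_ml: float, high_soft_ml: float
) -> float:
    """Log tissue ratio ``ln((low+high soft)/total)`` from volumes in ml.

    The response is scale invariant: only the soft fraction of the total
    tooth volume matters.  Raises :class:`InvalidRecordError` when the total
    volume is zero, and when the soft volume is zero (the log is undefined;
    such records must be excluded, not mapped to ``-inf``).
    """
    vols = (hard_ml, low_soft_ml, high_soft_ml)
    if any(v < 0 or not math.isfinite(v) for v in vols):
        raise InvalidRecordError(f"volumes must be finite and >= 0, got {vols}")
    total = hard_ml + low_soft_ml + high_soft_ml
    if total == 0:
        raise InvalidRecordError("total tooth volume is zero")
    soft = low_soft_ml + high_soft_ml
    if soft == 0:
        raise InvalidRecordError(
            "soft tissue volume is zero: log tissue ratio undefined"
        )
    return math.log(soft / total)


@dataclass(frozen=True)
class SegmentationThresholds:
    """T2 intensity cut-offs for the three tissue classes plus voxel size.

    Voxels with intensity in [0, hard_max] are hard tissue, in
    (hard_max, low_soft_max] low-signal soft tissue, and above low_soft_max
    high-signal soft tissue.  Defaults follow the segmentation protocol:
    0–63 hard, 64–100 low soft, >= 101 high soft, on 0.37 mm iso-voxels.
    """

    hard_max: int = 63
    low_soft_max: int = 100
    voxel_edge_mm: float = 0.37

    def __post_init__(self) -> None:
        if not (0 <= self.hard_max < self.low_soft_max):
            raise ValueError("need 0 <= hard_max < low_soft_max")
        if self.voxel_edge_mm <= 0:
            raise ValueError("voxel_edge_mm must be > 0")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_edge_mm**3 / 1000.0  # mm^3 -> ml


def volumes_from_intensities(
    intensity_histogram: Mapping[int, int],
    thresholds: SegmentationThresholds | None = None,
) -> tuple[float, float, float]:
    """Convert a voxel intensity histogram into (hard, low soft, high soft) ml.

    ``intensity_histogram`` maps integer intensity -> voxel count.  Class
    counts are multiplied by the voxel volume; voxels are conserved.
    """
    thr = thresholds if thresholds is not None else SegmentationThresholds()
    counts = [0, 0, 0]
    for intensity, count in intensity_histogram.items():
        if intensity < 0 or int(intensity) != intensity:
            raise ValueError(f"intensity must be a nonnegative integer: {intensity!r}")
        if count < 0:
            raise ValueError(f"voxel count must be >= 0: {count!r}")
        if intensity <= thr.hard_max:
            counts[0] += count
        elif intensity <= thr.low_soft_max:
            counts[1] += count
        else:
            counts[2] += count
    v = thr.voxel_volume_ml
    return counts[0] * v, counts[1] * v, counts[2] * v


@dataclass(frozen=True)
class Participant:
    id: str
    sex: Sex
    age: float  # chronological age, decimal years

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if not (self.age > 0 and math.isfinite(self.age)):
            raise ValueError(f"age must be finite and > 0, got {self.age}")


@dataclass(frozen=True)
class ToothRecord:
    """One tooth's tissue volumes and derived log tissue ratio."""

    participant_id: str
    tooth: int
    hard_ml: float
    low_soft_ml: float
    high_soft_ml: float
    y: float = field(init=False)

    def __post_init__(self) -> None:
        if self.tooth not in VALID_FDI_MOLARS:
            raise InvalidRecordError(f"invalid FDI molar code: {self.tooth}")
        object.__setattr__(
            self,
            "y",
            response_from_volumes(self.hard_ml, self.low_soft_ml, self.high_soft_ml),
        )

    @property
    def molar_class(self) -> MolarClass:
        return MolarClass.from_fdi(self.tooth)


@dataclass
class Cohort:
    """Participants plus their tooth records; incomplete tooth sets are legal."""

    participants: list[Participant]
    records: list[ToothRecord]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidRecordError(f"duplicate participant ids: {dupes}")
        known = set(ids)
        seen: set[tuple[str, int]] = set()
        for r in self.records:
            if r.participant_id not in known:
                raise InvalidRecordError(
                    f"record references unknown participant {r.participant_id!r}"
                )
            key = (r.participant_id, r.tooth)
            if key in seen:
                raise InvalidRecordError(f"duplicate (participant, tooth): {key}")
            seen.add(key)
        self._by_id = {p.id: p for p in self.participants}

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def participant(self, pid: str) -> Participant:
        return self._by_id[pid]

    def records_for(
        self, tooth: int | None = None, sex: Sex | str | None = None
    ) -> list[ToothRecord]:
        sex = Sex.parse(sex) if sex is not None else None
        out = []
        for r in self.records:
            if tooth is not None and r.tooth != tooth:
                continue
            if sex is not None and self._by_id[r.participant_id].sex is not sex:
                continue
            out.append(r)
        return out

    def tooth_arrays(
        self, tooth: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(age, male indicator, y) arrays for one tooth across the cohort."""
        recs = self.records_for(tooth)
        age = np.array([self._by_id[r.participant_id].age for r in recs])
        male = np.array(
            [1.0 if self._by_id[r.participant_id].sex is Sex.M else 0.0 for r in recs]
        )
        y = np.array([r.y for r in recs])
        return age, male, y

    def observations_by_participant(
        self, tooth_by_class: Mapping[MolarClass, int]
    ) -> list[tuple[Participant, dict[MolarClass, float]]]:
        """Each participant's observed subset of the mapped teeth.

        Participants holding none of the mapped teeth are omitted (they carry
        no information about the mapped combination).
        """
        tooth_to_class = {t: c for c, t in tooth_by_class.items()}
        by_pid: dict[str, dict[MolarClass, float]] = {}
        for r in self.records:
            cls = tooth_to_class.get(r.tooth)
            if cls is not None:
                by_pid.setdefault(r.participant_id, {})[cls] = r.y
        return [(self._by_id[pid], obs) for pid, obs in by_pid.items()]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": r.participant_id,
                "sex": self._by_id[r.participant_id].sex.value,
                "age": self._by_id[r.participant_id].age,
                "tooth": r.tooth,
                "hard_ml": r.hard_ml,
                "low_soft_ml": r.low_soft_ml,
                "high_soft_ml": r.high_soft_ml,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=["id", "sex", "age", "tooth", "hard_ml", "low_soft_ml", "high_soft_ml"],
        )


REQUIRED_COLUMNS = ("id", "sex", "age", "tooth", "hard_ml", "low_soft_ml", "high_soft_ml")


def read_cohort(path: str | Path, delimiter: str | None = None) -> Cohort:
    """Read a cohort table (comma default, tab accepted) and validate it.

    Expected header: ``id,sex,age,tooth,hard_ml,low_soft_ml,high_soft_ml``.
    Rows with zero soft-tissue volume are excluded with a warning (their log
    ratio is undefined); all other invariant violations are collected and
    raised together as :class:`CohortLoadError` with row numbers.
    """
    path = Path(path)
    if delimiter is None:
        header = path.open("r", encoding="utf-8").readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, dtype={"id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortLoadError([f"missing required column(s): {', '.join(missing)}"])

    errors: list[str] = []
    skipped: list[int] = []
    participants: dict[str, Participant] = {}
    records: list[ToothRecord] = []
    seen: set[tuple[str, int]] = set()
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, counting the header line
        try:
            pid = str(row["id"])
            sex = Sex.parse(row["sex"])
            age = float(row["age"])
            tooth = int(row["tooth"])
            for col in ("hard_ml", "low_soft_ml", "high_soft_ml"):
                float(row[col])
        except (ValueError, TypeError) as exc:
            errors.append(f"row {rowno}: {exc}")
            continue
        if tooth not in VALID_FDI_MOLARS:
            errors.append(f"row {rowno}: invalid FDI molar code {tooth}")
            continue
        if (pid, tooth) in seen:
            errors.append(f"row {rowno}: duplicate (participant, tooth) ({pid}, {tooth})")
            continue
        prev = participants.get(pid)
        if prev is not None and (prev.sex is not sex or prev.age != age):
            errors.append(f"row {rowno}: participant {pid} has inconsistent sex/age")
            continue
        soft = float(row["low_soft_ml"]) + float(row["high_soft_ml"])
        if soft == 0 and float(row["hard_ml"]) + soft > 0:
            skipped.append(rowno)
            continue
        try:
            rec = ToothRecord(
                participant_id=pid,
                tooth=tooth,
                hard_ml=float(row["hard_ml"]),
                low_soft_ml=float(row["low_soft_ml"]),
                high_soft_ml=float(row["high_soft_ml"]),
            )
        except InvalidRecordError as exc:
            errors.append(f"row {rowno}: {exc}")
            continue
        if prev is None:
            try:
                participants[pid] = Participant(pid, sex, age)
            except ValueError as exc:
                errors.append(f"row {rowno}: {exc}")
                continue
        seen.add((pid, tooth))
        records.append(rec)
    if errors:
        raise CohortLoadError(errors)
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} record(s) with zero soft-tissue volume "
            f"(log tissue ratio undefined): rows {skipped}",
            stacklevel=2,
        )
    return Cohort(list(participants.values()), records)


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    cohort.to_frame().to_csv(path, sep=delimiter, index=False)
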