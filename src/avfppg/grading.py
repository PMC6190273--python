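"""Degree-of-stenosis (DOS) computation and the three-class severity partition.

The degree of stenosis of an arteriovenous fistula is graded from two
diameters read off B-mode ultrasound or angiography: the lesion diameter
``d`` at the narrowest point and the normal vessel diameter ``D`` in the
flow direction.  The fractional DOS is

    DOS = 1 - (d / D)**2

so DOS = 0 means no narrowing and DOS = 1 means total occlusion.  Clinical
practice bins DOS into three severity classes: class 1 (mild, DOS <= 30%),
class 2 (moderate, 30% < DOS <= 50%, may reduce dialysis efficiency) and
class 3 (severe, DOS > 50%, usually needs surgical revision).  The printed
band edges overlap at 30% and 50%; this module resolves them half-open,
closed on the milder class, so the mapping is a total function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "SubjectMeta",
    "dos",
    "dos_to_class",
    "diameter_for_dos",
    "read_manifest",
    "write_manifest",
    "check_manifest_consistency",
]

#: Upper DOS bound (fraction) of class 1 and class 2 respectively.
CLASS_EDGES = (0.30, 0.50)


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject clinical metadata.

    ``d`` and ``D`` share an arbitrary length unit (only their ratio
    matters); ``dos`` is stored as a fraction in ``(-inf, 1]``, never as a
    percent.
    """

    subject_id: str
    d: float
    D: float
    dos: float
    age: float
    gender: str  # "male" | "female"
    true_class: int  # 1 | 2 | 3

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"normal diameter D must be > 0, got {self.D}")
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be 'male' or 'female', got {self.gender!r}")
        if self.true_class not in (1, 2, 3):
            raise ValueError(f"true_class must be 1, 2 or 3, got {self.true_class}")

    @property
    def consistent(self) -> bool:
        """True when the stored DOS matches 1 - (d/D)^2 to 1e-6 and the
        stored class matches the partition of the stored DOS."""
        return (
            abs(self.dos - dos(self.d, self.D)) < 1e-6
            and dos_to_class(self.dos) == self.true_class
        )


def dos(d: float, D: float) -> float:
    """Fractional degree of stenosis ``1 - d**2 / D**2``.

    Parameters
    ----------
    d : lesion (stenosed) diameter, >= 0.
    D : normal vessel diameter, > 0.

    Returns 1.0 at total occlusion (d = 0) and 0.0 for an unnarrowed
    vessel (d = D).  A lesion diameter larger than the normal diameter is
    physically implausible; the (negative) value is still returned but a
    warning is emitted.
    """
    if D <= 0:
        raise ValueError(f"normal diameter D must be > 0, got {D}")
    if d < 0:
        raise ValueError(f"lesion diameter d must be >= 0, got {d}")
    value = 1.0 - (d * d) / (D * D)
    if value < 0:
        warnings.warn(
            f"d = {d} exceeds D = {D}: negative DOS {value:.6f} is implausible",
            stacklevel=2,
        )
    return value


def dos_to_class(dos_value: float, edges: tuple[float, float] = CLASS_EDGES) -> int:
    """Map a fractional DOS to severity class 1, 2 or 3.

    Bands are half-open, closed on the milder class: ``[-inf, e1] -> 1``,
    ``(e1, e2] -> 2``, ``(e2, inf) -> 3`` with default edges (0.30, 0.50).
    Negative DOS (implausible diameters) maps to class 1 with a warning.
    """
    e1, e2 = edges
    if not e1 < e2:
        raise ValueError(f"class edges must be increasing, got {edges}")
    if dos_value != dos_value:  # NaN
        raise ValueError("DOS is NaN")
    if dos_value < 0:
        warnings.warn(f"negative DOS {dos_value:.6f} mapped to class 1", stacklevel=2)
        return 1
    if dos_value <= e1:
        return 1
    if dos_value <= e2:
        return 2
    return 3


def diameter_for_dos(dos_value: float, D: float = 1.0) -> float:
    """Lesion diameter giving the requested DOS: ``d = D * sqrt(1 - DOS)``."""
    if not 0.0 <= dos_value <= 1.0:
        raise ValueError(f"DOS fraction must be in [0, 1], got {dos_value}")
    if D <= 0:
        raise ValueError(f"normal diameter D must be > 0, got {D}")
    return D * (1.0 - dos_value) ** 0.5


MANIFEST_COLUMNS = ["subject_id", "d", "D", "dos", "age", "gender", "class"]


def write_manifest(subjects: Iterable[SubjectMeta], path: str | Path) -> None:
    """Write a cohort manifest CSV (subject_id, d, D, dos, age, gender, class)."""
    rows = [
        (s.subject_id, s.d, s.D, s.dos, s.age, s.gender, s.true_class)
        for s in subjects
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[SubjectMeta]:
    """Read a cohort manifest CSV written by :func:`write_manifest`."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    return [
        SubjectMeta(
            subject_id=str(r["subject_id"]),
            d=float(r["d"]),
            D=float(r["D"]),
            dos=float(r["dos"]),
            age=float(r["age"]),
            gender=str(r["gender"]),
            true_class=int(r["class"]),
        )
        for _, r in df.iterrows()
    ]


def check_manifest_consistency(subjects: Iterable[SubjectMeta]) -> pd.DataFrame:
    """Report, per subject, whether the recorded DOS and class agree with the
    DOS formula and the class partition.

    Published clinical tables sometimes carry transcription errors; this
    utility flags rows whose DOS does not equal 1 - (d/D)^2 or whose class
    does not match the partition of the recorded DOS, without altering them.
    """
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in subjects:
            formula_dos = dos(s.d, s.D)
            records.append(
                {
                    "subject_id": s.subject_id,
                    "recorded_dos": s.dos,
                    "formula_dos": formula_dos,
                    "dos_consistent": abs(s.dos - formula_dos) < 1e-6,
                    "recorded_class": s.true_class,
                    "partition_class": dos_to_class(s.dos),
                    "class_consistent": dos_to_class(s.dos) == s.true_class,
                }
            )
    return pd.DataFrame.from_records(records)
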