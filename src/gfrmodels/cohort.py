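"""Patient and cohort containers with delimited-text I/O.

A cohort is an ordered collection of adult diabetic patients, each carrying
demographics (sex, age), serum creatinine, optional laboratory covariates
(BMI, HbA1c, UACR) and an optional measured ("standard") GFR.  Records are
tagged with a split label so that model development, internal validation
(model selection) and external validation (final comparison) stay separated.

Serum creatinine is stored internally in mg/dL only; files reporting
creatinine in µmol/L are converted on read using the standard clinical
factor of 88.4 µmol/L per mg/dL.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError

__all__ = [
    "PatientRecord",
    "Cohort",
    "SPLIT_LABELS",
    "UMOL_PER_MGDL",
    "read_cohort",
    "write_cohort",
    "split_cohort",
]

#: µmol/L of creatinine per mg/dL — the standard clinical conversion factor.
UMOL_PER_MGDL = 88.4

SPLIT_LABELS = ("development", "internal", "external", "unassigned")

_MANDATORY_COLUMNS = ("sex", "age", "scr_mg_dl")
_OPTIONAL_COLUMNS = ("bmi", "hba1c", "uacr_mg_g", "sgfr")
_SEX_TOKENS = {"f": "female", "female": "female", "m": "male", "male": "male"}


@dataclass(frozen=True)
class PatientRecord:
    """One diabetic subject.

    Units: age in years, scr in mg/dL, bmi in kg/m², hba1c in percent,
    uacr in mg/g, sgfr in mL/min/1.73 m².  Optional fields are ``None``
    when absent; they are never imputed.
    """

    id: str
    sex: str  # "female" | "male"
    age: float
    scr: float
    bmi: Optional[float] = None
    hba1c: Optional[float] = None
    uacr: Optional[float] = None
    sgfr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(
                f"record {self.id!r}: sex must be 'female' or 'male', got {self.sex!r}"
            )
        if not np.isfinite(self.age) or self.age < 18:
            raise ValidationError(
                f"record {self.id!r}: age {self.age} violates the adult (>= 18 years) "
                "inclusion requirement"
            )
        if not np.isfinite(self.scr) or self.scr <= 0:
            raise ValidationError(f"record {self.id!r}: scr must be > 0, got {self.scr}")
        for name, value, lower_ok in (
            ("bmi", self.bmi, False),
            ("hba1c", self.hba1c, False),
            ("uacr", self.uacr, True),
            ("sgfr", self.sgfr, False),
        ):
            if value is None:
                continue
            if not np.isfinite(value) or (value < 0 if lower_ok else value <= 0):
                bound = ">= 0" if lower_ok else "> 0"
                raise ValidationError(
                    f"record {self.id!r}: field {name} must be {bound}, got {value}"
                )

    @property
    def female(self) -> bool:
        return self.sex == "female"

    def get(self, name: str) -> Optional[float]:
        """Return a covariate by canonical name (age/scr/bmi/hba1c/uacr/sgfr)."""
        return getattr(self, name)


@dataclass
class Cohort:
    """Ordered records plus a parallel split label per record."""

    records: list[PatientRecord]
    split: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.split:
            self.split = ["unassigned"] * len(self.records)
        if len(self.split) != len(self.records):
            raise ValidationError("split labels must be parallel to records")
        for label in self.split:
            if label not in SPLIT_LABELS:
                raise ValidationError(f"unknown split label {label!r}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def subset(self, label: str) -> list[PatientRecord]:
        """Records carrying a given split label."""
        return [r for r, s in zip(self.records, self.split) if s == label]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _coerce_sex(token: object, row_id: str) -> str:
    key = str(token).strip().lower()
    if key not in _SEX_TOKENS:
        raise ValidationError(
            f"record {row_id!r}: unrecognized sex token {token!r} (expected F/M)"
        )
    return _SEX_TOKENS[key]


def read_cohort(path, scr_unit: str = "mg/dL") -> Cohort:
    """Read a comma- or tab-delimited cohort file.

    The header must name at least ``sex``, ``age`` and ``scr_mg_dl`` (the
    creatinine column keeps that name even when the values are µmol/L and
    ``scr_unit="umol/L"`` is passed; conversion divides by 88.4).  Optional
    columns: ``bmi``, ``hba1c``, ``uacr_mg_g``, ``sgfr``, ``id``, ``split``.
    """
    if scr_unit not in ("mg/dL", "umol/L", "µmol/L"):
        raise ValidationError(f"unknown creatinine unit {scr_unit!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"mandatory column {col!r} missing from {path}")

    records: list[PatientRecord] = []
    split: list[str] = []
    for i, row in df.iterrows():
        row_id = str(row["id"]) if "id" in df.columns and not pd.isna(row["id"]) else str(i)
        scr = float(row["scr_mg_dl"])
        if scr_unit != "mg/dL":
            scr /= UMOL_PER_MGDL

        def _opt(col: str) -> Optional[float]:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        records.append(
            PatientRecord(
                id=row_id,
                sex=_coerce_sex(row["sex"], row_id),
                age=float(row["age"]),
                scr=scr,
                bmi=_opt("bmi"),
                hba1c=_opt("hba1c"),
                uacr=_opt("uacr_mg_g"),
                sgfr=_opt("sgfr"),
            )
        )
        label = "unassigned"
        if "split" in df.columns and not pd.isna(row["split"]):
            label = str(row["split"]).strip().lower()
        split.append(label)
    return Cohort(records=records, split=split)


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    """Write a cohort in the canonical delimited format (round-trip safe).

    Numbers are written with ``repr`` so finite decimal inputs survive a
    write/read cycle bit-identically.
    """
    header = ["id", "sex", "age", "scr_mg_dl", "bmi", "hba1c", "uacr_mg_g", "sgfr", "split"]
    buf = io.StringIO()
    buf.write(sep.join(header) + "\n")
    for rec, label in zip(cohort.records, cohort.split):
        cells = [
            rec.id,
            "F" if rec.female else "M",
            repr(rec.age),
            repr(rec.scr),
            "" if rec.bmi is None else repr(rec.bmi),
            "" if rec.hba1c is None else repr(rec.hba1c),
            "" if rec.uacr is None else repr(rec.uacr),
            "" if rec.sgfr is None else repr(rec.sgfr),
            label,
        ]
        buf.write(sep.join(cells) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def split_cohort(cohort: Cohort, dev_fraction: float = 2.0 / 3.0, seed: int = 0) -> Cohort:
    """Randomly assign development / internal labels.

    Records labelled ``external`` are never touched; records labelled
    ``unassigned``, ``development`` or ``internal`` are pooled and
    re-randomized.  The development count is ``round(n * dev_fraction)``
    (half-up); the remainder goes to internal validation.  With 414 eligible
    records and dev_fraction 2/3 this yields the 276/138 split used for
    equation development versus model selection.
    """
    if not 0 < dev_fraction < 1:
        raise ValidationError(f"dev_fraction must be in (0, 1), got {dev_fraction}")
    eligible = [i for i, s in enumerate(cohort.split) if s != "external"]
    n = len(eligible)
    if n < 2:
        raise InsufficientDataError(
            f"need at least 2 non-external records to split, have {n}"
        )
    n_dev = int(np.floor(n * dev_fraction + 0.5))
    n_dev = min(max(n_dev, 1), n - 1)  # both arms non-empty
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    dev_positions = {eligible[j] for j in order[:n_dev]}
    new_split = list(cohort.split)
    for i in eligible:
        new_split[i] = "development" if i in dev_positions else "internal"
    return Cohort(records=list(cohort.records), split=new_split)
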