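"""The per-subject measurement record shared across the pipeline."""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

#: Regression predictors of spleen volume, in report order: age, spleen
#: length, then the single-slice L1/abdominal metrics.
PREDICTORS = (
    "age",
    "spleen_length",
    "l1_ap",
    "l1_tv",
    "l1_area",
    "abd_ap",
    "abd_tv",
    "abd_circumference",
    "canal_area",
)

#: Human-readable variable labels used in report tables.
VARIABLE_LABELS = {
    "age": "Age",
    "spleen_length": "Spleen length (cm)",
    "spleen_volume": "Spleen volume (cm3)",
    "l1_ap": "L1 AP diameter (cm)",
    "l1_tv": "L1 transverse diameter (cm)",
    "l1_area": "L1 transverse area (cm2)",
    "abd_ap": "Abdomen AP diameter (cm)",
    "abd_tv": "Abdomen transverse diameter (cm)",
    "abd_circumference": "Abdomen circumference (cm)",
    "canal_area": "Spinal canal area (cm2)",
}

VOLUME_CLASSES = ("normal", "high", "unset")

CSV_COLUMNS = [
    "subject_id",
    "sex",
    "rater_id",
    "age",
    "spleen_volume",
    "spleen_ce",
    "n_slices",
    "spleen_length",
    "l1_ap",
    "l1_tv",
    "l1_area",
    "abd_ap",
    "abd_tv",
    "abd_circumference",
    "canal_area",
    "volume_class",
    "notes",
]

_NUMERIC_FIELDS = (
    "age",
    "spleen_volume",
    "spleen_ce",
    "n_slices",
    "spleen_length",
    "l1_ap",
    "l1_tv",
    "l1_area",
    "abd_ap",
    "abd_tv",
    "abd_circumference",
    "canal_area",
)


def _clean(value) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


@dataclass
class SubjectRecord:
    """One subject's measurements from one rater; missing values are None.

    All linear measures are cm, areas cm², volumes cm³, age years; the
    coefficient of error is dimensionless and may be undefined (e.g. a spleen
    covered by fewer than three slices).
    """

    subject_id: str
    sex: str = ""
    rater_id: str = "r1"
    age: Optional[float] = None
    spleen_volume: Optional[float] = None
    spleen_ce: Optional[float] = None
    n_slices: Optional[float] = None
    spleen_length: Optional[float] = None
    l1_ap: Optional[float] = None
    l1_tv: Optional[float] = None
    l1_area: Optional[float] = None
    abd_ap: Optional[float] = None
    abd_tv: Optional[float] = None
    abd_circumference: Optional[float] = None
    canal_area: Optional[float] = None
    volume_class: str = "unset"
    notes: str = ""

    def __post_init__(self) -> None:
        for name in _NUMERIC_FIELDS:
            setattr(self, name, _clean(getattr(self, name)))
        for name in _NUMERIC_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.volume_class not in VOLUME_CLASSES:
            raise ValueError(f"volume_class must be one of {VOLUME_CLASSES}")

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in CSV_COLUMNS}

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectRecord":
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                kwargs[f.name] = d[f.name]
        for key in ("subject_id", "sex", "rater_id", "volume_class", "notes"):
            v = kwargs.get(key)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                kwargs[key] = "" if key not in ("volume_class",) else "unset"
            else:
                kwargs[key] = str(v)
        if not kwargs.get("rater_id"):
            kwargs["rater_id"] = "r1"
        return cls(**kwargs)
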