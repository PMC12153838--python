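"""The 22-feature RAPS schema, scoring constraints, deficit flags and grades.

RAPS (Rose / Antler / Pedicle / Skull) is a binary morphological scoring
system for cervid antler-pedicle pathology: 3 rose, 6 antler, 7 pedicle and
6 skull features, each scored 0/1 separately per side, and each carrying a
severity grade I-IV reflecting its pathomorphological background.

Scoring constraints
-------------------
* R1 (short rose-grain discontinuity) and R2 (rose deformity) are mutually
  exclusive on a side; co-presence is a validation error, never silently fixed.
* A2 and A3 are side-comparison features: if present on either side they are
  scored 1 on both sides.
* A2.1 and A3.1 are derived, not visual: present when the brow-tine (bottom
  20%) or main-beam (bottom 5%) length falls strictly below the control
  register quantile of the animal's age and side.

Grade-table variants
--------------------
The published grade rows assign the skull fistula and the cortical-plate
separation inconsistently between their two labels (S4/S5).  The default
``"resolved"`` table follows the feature-prevalence text (S4 -> III,
S5 -> IV); the ``"literal"`` table swaps them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import ConstraintViolation, SchemaError
from .registry import ControlRegister, Metric, Side, TrophyRecord


class Region(str, Enum):
    ROSE = "ROSE"
    ANTLER = "ANTLER"
    PEDICLE = "PEDICLE"
    SKULL = "SKULL"


class Grade(IntEnum):
    I = 1
    II = 2
    III = 3
    IV = 4


class Mode(str, Enum):
    VISUAL = "VISUAL"
    DERIVED = "DERIVED"
    BILATERAL = "BILATERAL"


@dataclass(frozen=True)
class RapsFeature:
    code: str
    region: Region
    grade: Grade
    mode: Mode
    description: str


_R, _A, _P, _S = Region.ROSE, Region.ANTLER, Region.PEDICLE, Region.SKULL
_V, _D, _B = Mode.VISUAL, Mode.DERIVED, Mode.BILATERAL

#: The 22 features with the default ("resolved") grade assignment.
FEATURES: Tuple[RapsFeature, ...] = (
    RapsFeature("R1", _R, Grade.I, _V, "Rose grain discontinuity between 5 mm and 1 cm"),
    RapsFeature("R2", _R, Grade.II, _V, "Rose deformity, also visible on cast antlers"),
    RapsFeature("R3", _R, Grade.III, _V, "Loss of rose granularity over more than 1 cm"),
    RapsFeature("A1", _A, Grade.I, _V, "Supernumerary tine originating from the rose"),
    RapsFeature("A2", _A, Grade.II, _B, "Visible left-right brow tine length asymmetry"),
    RapsFeature("A2.1", _A, Grade.II, _D, "Brow tine below the register bottom-20% quantile"),
    RapsFeature("A3", _A, Grade.III, _B, "Visible left-right main beam length asymmetry"),
    RapsFeature("A3.1", _A, Grade.III, _D, "Main beam below the register bottom-5% quantile"),
    RapsFeature("A4", _A, Grade.IV, _V, "Absence of antler or only an aberrant antler beam"),
    RapsFeature("P1", _P, Grade.I, _V, "Pitting on the proximal pedicle surface"),
    RapsFeature("P2", _P, Grade.II, _V, "Pedicle ellipticity: axis difference above 4 mm"),
    RapsFeature("P3", _P, Grade.II, _V, "Pedicle shortening beyond the physiological extent"),
    RapsFeature("P4", _P, Grade.II, _V, "Pedicle widening beyond the normal extent"),
    RapsFeature("P5", _P, Grade.III, _V, "Pedicle fistula"),
    RapsFeature("P6", _P, Grade.III, _V, "Free casting plane without protruding antler bone"),
    RapsFeature("P7", _P, Grade.IV, _V, "Casting plane mostly at or below the skull plane"),
    RapsFeature("S1", _S, Grade.I, _V, "Pitting extending onto the skull surface"),
    RapsFeature("S2", _S, Grade.II, _V, "Spongy remodelling of skull bones"),
    RapsFeature("S3", _S, Grade.IV, _V, "Discohesion along the interosseous suture"),
    RapsFeature("S4", _S, Grade.III, _V, "Fistula mouth opening on the skull, distant from the pedicle"),
    RapsFeature("S5", _S, Grade.IV, _V, "Separation of the cortical bone plates"),
    RapsFeature("S6", _S, Grade.II, _V, "Pedicle centre shifted, mostly towards the brow ridge"),
)

FEATURE_CODES: Tuple[str, ...] = tuple(f.code for f in FEATURES)
_BY_CODE: Dict[str, RapsFeature] = {f.code: f for f in FEATURES}

#: Side-comparison features mirrored to both sides when present on either.
BILATERAL_CODES = ("A2", "A3")
#: Register-relative features derived from lengths rather than inspection.
DERIVED_CODES = ("A2.1", "A3.1")

GRADE_TABLES: Dict[str, Dict[str, Grade]] = {
    "resolved": {f.code: f.grade for f in FEATURES},
    # published table rows read literally: S4 graded IV, S5 III
    "literal": {
        **{f.code: f.grade for f in FEATURES},
        "S4": Grade.IV,
        "S5": Grade.III,
    },
}


def feature_info(code: str) -> RapsFeature:
    try:
        return _BY_CODE[code]
    except KeyError:
        raise SchemaError(f"unknown RAPS code {code!r}") from None


def feature_grade(code: str, table: str = "resolved") -> Grade:
    """Severity grade of a feature code under the chosen grade-table variant."""
    feature_info(code)  # total mapping: unknown codes raise
    try:
        return GRADE_TABLES[table][code]
    except KeyError:
        raise SchemaError(f"unknown grade table {table!r}") from None


def schema_as_json(path=None) -> str:
    """JSON export of the feature schema with grades (both table variants)."""
    payload = [
        {
            "code": f.code,
            "region": f.region.value,
            "grade": f.grade.name,
            "grade_literal": GRADE_TABLES["literal"][f.code].name,
            "mode": f.mode.value,
            "description": f.description,
        }
        for f in FEATURES
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Assessments


@dataclass
class RapsAssessment:
    """Per-trophy, per-side binary scoring of the 22 features.

    ``values[(code, side)]`` is 1 (present), 0 (absent) or None (missing).
    Missing entries are never imputed; downstream prevalence denominators
    exclude them.
    """

    trophy_id: str
    values: Dict[Tuple[str, Side], Optional[int]] = field(default_factory=dict)

    def get(self, code: str, side: Side) -> Optional[int]:
        feature_info(code)
        return self.values.get((code, side))

    def set(self, code: str, side: Side, value: Optional[int]) -> None:
        feature_info(code)
        if value not in (0, 1, None):
            raise ValueError(f"assessment value must be 0, 1 or missing, got {value!r}")
        self.values[(code, side)] = value

    def present_codes(self) -> set:
        """Codes scored present on at least one side."""
        return {code for (code, _), v in self.values.items() if v == 1}

    def is_complete(self) -> bool:
        return all(self.values.get((c, s)) in (0, 1) for c in FEATURE_CODES for s in Side)


def apply_scoring_constraints(assessment: RapsAssessment) -> RapsAssessment:
    """Enforce the scoring constraints, returning a new assessment.

    Mirrors A2/A3 to both sides when present on either; raises
    :class:`ConstraintViolation` when R1 and R2 are both present on a side.
    """
    for side in Side:
        if assessment.get("R1", side) == 1 and assessment.get("R2", side) == 1:
            raise ConstraintViolation(
                f"trophy {assessment.trophy_id}, side {side.value}: "
                "R1 and R2 are mutually exclusive"
            )
    out = RapsAssessment(assessment.trophy_id, dict(assessment.values))
    for code in BILATERAL_CODES:
        if any(assessment.get(code, s) == 1 for s in Side):
            for s in Side:
                out.set(code, s, 1)
    return out


def derive_deficit_flags(
    record: TrophyRecord,
    register: ControlRegister,
    q_brow: float = 0.20,
    q_beam: float = 0.05,
    min_stratum: int = 10,
) -> Dict[Side, Dict[str, Optional[int]]]:
    """Derive the register-relative flags A2.1 (brow) and A3.1 (beam).

    A flag is 1 iff the corresponding length is strictly below the control
    stratum quantile for the record's age and side; a missing length yields a
    missing flag.  The default 20%/5% split reflects that register brow-tine
    distributions are skewed, so a less stringent brow threshold is used.
    """
    flags: Dict[Side, Dict[str, Optional[int]]] = {}
    for side in Side:
        m = record.side(side)
        side_flags: Dict[str, Optional[int]] = {}
        for code, metric, length, q in (
            ("A2.1", Metric.BROW, m.brow_tine_len, q_brow),
            ("A3.1", Metric.BEAM, m.main_beam_len, q_beam),
        ):
            if length is None:
                side_flags[code] = None
            else:
                threshold = register.quantile(
                    record.age_years, side, metric, q, min_stratum=min_stratum
                )
                side_flags[code] = int(length < threshold)
        flags[side] = side_flags
    return flags


def trophy_grade(assessment: RapsAssessment, table: str = "resolved") -> Optional[Grade]:
    """Trophy-level severity: the maximum grade among features present on
    either side, or None when no feature is present."""
    present = assessment.present_codes()
    if not present:
        return None
    return max(feature_grade(code, table=table) for code in present)


# ---------------------------------------------------------------------------
# Assessment I/O (long format: trophy_id, side, feature, value)


def assessments_to_long(assessments: Sequence[RapsAssessment]) -> pd.DataFrame:
    rows = []
    for a in assessments:
        for code in FEATURE_CODES:
            for side in Side:
                v = a.values.get((code, side))
                rows.append(
                    {
                        "trophy_id": a.trophy_id,
                        "side": side.value,
                        "feature": code,
                        "value": "" if v is None else v,
                    }
                )
    return pd.DataFrame(rows)


def write_assessments(assessments: Sequence[RapsAssessment], path) -> None:
    assessments_to_long(assessments).to_csv(path, index=False)


def read_assessments(path) -> list:
    df = pd.read_csv(path, dtype={"trophy_id": str, "side": str, "feature": str})
    required = {"trophy_id", "side", "feature", "value"}
    if not required.issubset(df.columns):
        raise SchemaError(f"assessment file must have columns {sorted(required)}")
    out: Dict[str, RapsAssessment] = {}
    for row in df.itertuples(index=False):
        a = out.setdefault(row.trophy_id, RapsAssessment(row.trophy_id))
        value = None if pd.isna(row.value) else int(row.value)
        a.set(row.feature, Side(row.side), value)
    return list(out.values())
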