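"""Trophy-register I/O, validation, and the age-stratified control register.

A trophy register is a delimited table with one row per trophy: species, age,
per-side brow-tine and main-beam lengths (cm), per-side pedicle axes (mm), a
cohort label and optional free-text register marks.  The control register
built from the trophy-register control group (TRCG) supports the empirical
quantile lookups that drive the register-relative deficit flags A2.1/A3.1.

Quantile definition
-------------------
``stratum_quantile`` returns the empirical inverse CDF: the smallest observed
value whose cumulative frequency reaches ``q``.  A record is considered
deficient only when its length falls *strictly below* that value, so flagging
a stratum against itself can never mark more than a fraction ``q`` of it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyRegisterError,
    RowValidationError,
    SchemaError,
    UnresolvableStratumError,
)


class Species(str, Enum):
    """The three free-ranging cervid species covered by the register."""

    DD = "DD"  # Dama dama, fallow deer
    CC = "CC"  # Capreolus capreolus, roe deer
    CE = "CE"  # Cervus elaphus, red deer


class Cohort(str, Enum):
    ABERRANT = "ABERRANT"
    MCG = "MCG"    # morphology control group (healthy trophies, fully assessed)
    TRCG = "TRCG"  # trophy-register control group (length sheets only)


class Side(str, Enum):
    LEFT = "L"
    RIGHT = "R"


class Metric(str, Enum):
    BROW = "brow"  # brow tine length, cm
    BEAM = "beam"  # main beam length, cm


#: Register marks that exclude a sheet from the control group.
DEFAULT_EXCLUSION_FLAGS = frozenset({"deformed", "injured pedicle", "diseased pedicle"})


@dataclass(frozen=True)
class SideMeasurements:
    """Per-side measurements: tine/beam lengths in cm, pedicle axes in mm."""

    brow_tine_len: Optional[float] = None
    main_beam_len: Optional[float] = None
    pedicle_D: Optional[float] = None
    pedicle_d: Optional[float] = None


@dataclass(frozen=True)
class TrophyRecord:
    trophy_id: str
    species: Species
    age_years: int
    cohort: Cohort
    left: SideMeasurements = field(default_factory=SideMeasurements)
    right: SideMeasurements = field(default_factory=SideMeasurements)
    harvest_age_years: Optional[int] = None
    marks: frozenset = field(default_factory=frozenset)

    def side(self, side: Side) -> SideMeasurements:
        return self.left if side is Side.LEFT else self.right

    def validation_problems(self, strict_axis_order: bool = True) -> list:
        """Return a list of human-readable invariant violations (empty if valid)."""
        problems = []
        if not (1 <= self.age_years <= 20):
            problems.append(f"age {self.age_years} outside [1, 20]")
        if self.harvest_age_years is not None and self.harvest_age_years < 1:
            problems.append("harvest age must be positive")
        for s in Side:
            m = self.side(s)
            for name in ("brow_tine_len", "main_beam_len", "pedicle_D", "pedicle_d"):
                v = getattr(m, name)
                if v is not None and not (v > 0):
                    problems.append(f"{name} ({s.value}) must be strictly positive")
            if (
                strict_axis_order
                and m.pedicle_D is not None
                and m.pedicle_d is not None
                and m.pedicle_d > m.pedicle_D
            ):
                problems.append(f"axis order ({s.value}): pedicle d > D")
        return problems


# ---------------------------------------------------------------------------
# CSV schema

_MEASUREMENTS = ("brow_tine_len", "main_beam_len", "pedicle_D", "pedicle_d")
_MANDATORY = ("trophy_id", "species", "age_years", "cohort")
_OPTIONAL = ("harvest_age_years", "marks") + tuple(
    f"{m}_{s.value.lower()}" for m in _MEASUREMENTS for s in Side
)

#: native unit per measurement; declared units in the schema are converted to it
_NATIVE_UNITS = {
    "brow_tine_len": "cm",
    "main_beam_len": "cm",
    "pedicle_D": "mm",
    "pedicle_d": "mm",
}
_TO_CM = {"cm": 1.0, "mm": 0.1, "m": 100.0}
_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


@dataclass(frozen=True)
class RegisterSchema:
    """Column-name map (logical name -> file header), declared units, dialect."""

    columns: Mapping[str, str] = field(default_factory=dict)
    units: Mapping[str, str] = field(default_factory=dict)
    strict_axis_order: bool = True
    exclusion_flags: frozenset = DEFAULT_EXCLUSION_FLAGS

    def column(self, logical: str) -> str:
        return self.columns.get(logical, logical)

    def factor(self, measurement: str) -> float:
        declared = self.units.get(measurement, _NATIVE_UNITS[measurement])
        table = _TO_CM if _NATIVE_UNITS[measurement] == "cm" else _TO_MM
        try:
            return table[declared]
        except KeyError:
            raise SchemaError(f"unknown unit {declared!r} for {measurement}") from None

    @classmethod
    def from_json(cls, path) -> "RegisterSchema":
        raw = json.loads(Path(path).read_text())
        return cls(
            columns=raw.get("columns", {}),
            units=raw.get("units", {}),
            strict_axis_order=raw.get("strict_axis_order", True),
            exclusion_flags=frozenset(raw.get("exclusion_flags", DEFAULT_EXCLUSION_FLAGS)),
        )


@dataclass(frozen=True)
class RejectedRow:
    row: int  # 1-based data-row number (header not counted)
    reason: str


@dataclass
class ReadResult:
    records: list
    rejects: list

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _parse_float(value, what: str):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric {what}: {value!r}") from None


def read_register(path, schema: Optional[RegisterSchema] = None) -> ReadResult:
    """Read and validate a register CSV.

    Rows failing validation are reported in ``ReadResult.rejects`` with their
    1-based data-row number and a reason; valid rows are never dropped.
    In lenient mode (``schema.strict_axis_order=False``) inverted pedicle axes
    are swapped instead of rejected.
    """
    schema = schema or RegisterSchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for logical in _MANDATORY:
        if schema.column(logical) not in df.columns:
            raise SchemaError(f"missing mandatory column {schema.column(logical)!r}")

    records, rejects = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            records.append(_parse_row(row, schema))
        except (ValueError, RowValidationError) as exc:
            reason = exc.reason if isinstance(exc, RowValidationError) else str(exc)
            rejects.append(RejectedRow(row=i, reason=reason))
    return ReadResult(records=records, rejects=rejects)


def _parse_row(row: Mapping[str, str], schema: RegisterSchema) -> TrophyRecord:
    def get(logical):
        return row.get(schema.column(logical), "")

    species_code = get("species").strip()
    try:
        species = Species(species_code)
    except ValueError:
        raise ValueError(f"unknown species code {species_code!r}") from None
    try:
        cohort = Cohort(get("cohort").strip())
    except ValueError:
        raise ValueError(f"unknown cohort label {get('cohort')!r}") from None

    age = _parse_float(get("age_years"), "age")
    if age is None:
        raise ValueError("missing age")
    harvest = _parse_float(get("harvest_age_years"), "harvest age")

    sides = {}
    for s in Side:
        kwargs = {}
        for m in _MEASUREMENTS:
            logical = f"{m}_{s.value.lower()}"
            v = _parse_float(get(logical), logical)
            kwargs[m] = None if v is None else v * schema.factor(m)
        if (
            not schema.strict_axis_order
            and kwargs["pedicle_D"] is not None
            and kwargs["pedicle_d"] is not None
            and kwargs["pedicle_d"] > kwargs["pedicle_D"]
        ):
            kwargs["pedicle_D"], kwargs["pedicle_d"] = kwargs["pedicle_d"], kwargs["pedicle_D"]
        sides[s] = SideMeasurements(**kwargs)

    marks = frozenset(m.strip() for m in get("marks").split(";") if m.strip())
    record = TrophyRecord(
        trophy_id=get("trophy_id"),
        species=species,
        age_years=int(age),
        cohort=cohort,
        left=sides[Side.LEFT],
        right=sides[Side.RIGHT],
        harvest_age_years=None if harvest is None else int(harvest),
        marks=marks,
    )
    problems = record.validation_problems(strict_axis_order=schema.strict_axis_order)
    if problems:
        raise ValueError("; ".join(problems))
    return record


def write_register(records: Iterable[TrophyRecord], path, schema: Optional[RegisterSchema] = None) -> None:
    """Write records as a register CSV readable by :func:`read_register`."""
    schema = schema or RegisterSchema()
    rows = []
    for r in records:
        row = {
            schema.column("trophy_id"): r.trophy_id,
            schema.column("species"): r.species.value,
            schema.column("age_years"): r.age_years,
            schema.column("cohort"): r.cohort.value,
            schema.column("harvest_age_years"): "" if r.harvest_age_years is None else r.harvest_age_years,
            schema.column("marks"): ";".join(sorted(r.marks)),
        }
        for s in Side:
            m = r.side(s)
            for name in _MEASUREMENTS:
                v = getattr(m, name)
                col = schema.column(f"{name}_{s.value.lower()}")
                row[col] = "" if v is None else repr(v / schema.factor(name))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_register(
    records: Sequence[TrophyRecord],
    exclusion_flags: Iterable[str] = DEFAULT_EXCLUSION_FLAGS,
):
    """Partition records into (kept, excluded) by register marks.

    A record bearing *any* exclusion flag is excluded; the two lists always
    partition the input.
    """
    flags = frozenset(exclusion_flags)
    kept, excluded = [], []
    for r in records:
        (excluded if r.marks & flags else kept).append(r)
    return kept, excluded


# ---------------------------------------------------------------------------
# Control register


class ControlRegister:
    """Age- and side-stratified empirical length distributions from TRCG sheets.

    One stratum per (age, side, metric); each stratum holds the sorted vector
    of observed lengths.  Lookups on thin strata pool with the nearest ages
    (age +/- 1, +/- 2, ...) until ``min_stratum`` observations are reached.
    """

    def __init__(self, strata: Mapping[tuple, np.ndarray]):
        self.strata = {k: np.sort(np.asarray(v, dtype=float)) for k, v in strata.items() if len(v)}
        if not self.strata:
            raise EmptyRegisterError("control register has no observations")

    @classmethod
    def from_records(cls, records: Sequence[TrophyRecord]) -> "ControlRegister":
        if not records:
            raise EmptyRegisterError("cannot build a control register from zero records")
        bad = [r.trophy_id for r in records if r.cohort is not Cohort.TRCG]
        if bad:
            raise ValueError(f"non-TRCG records in control build: {bad[:5]}")
        strata: dict = {}
        for r in records:
            for s in Side:
                m = r.side(s)
                for metric, value in ((Metric.BROW, m.brow_tine_len), (Metric.BEAM, m.main_beam_len)):
                    if value is not None:
                        strata.setdefault((r.age_years, s, metric), []).append(value)
        return cls(strata)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def counts(self) -> dict:
        return {k: len(v) for k, v in self.strata.items()}

    def _pooled(self, age: int, side: Side, metric: Metric, min_stratum: int) -> np.ndarray:
        ages = sorted({a for (a, s, m) in self.strata if s is side and m is metric})
        if not ages:
            raise UnresolvableStratumError(f"no observations for ({side.value}, {metric.value})")
        max_width = max(abs(a - age) for a in ages)
        for width in range(0, max_width + 1):
            pooled = [
                self.strata[(a, side, metric)]
                for a in ages
                if abs(a - age) <= width and (a, side, metric) in self.strata
            ]
            values = np.concatenate(pooled) if pooled else np.empty(0)
            if len(values) >= min_stratum or (width == max_width and len(values)):
                return np.sort(values)
        raise UnresolvableStratumError(
            f"stratum (age={age}, {side.value}, {metric.value}) unresolvable"
        )

    def quantile(self, age: int, side: Side, metric: Metric, q: float, min_stratum: int = 10) -> float:
        """Empirical inverse-CDF quantile of the (possibly pooled) stratum."""
        if not (0 < q < 1):
            raise ValueError(f"q must be in (0, 1), got {q}")
        values = self._pooled(age, side, metric, min_stratum)
        k = math.ceil(q * len(values))
        return float(values[max(k, 1) - 1])


def build_control(records: Sequence[TrophyRecord]) -> ControlRegister:
    """Build the stratified control register from TRCG records."""
    return ControlRegister.from_records(records)


def stratum_quantile(
    register: ControlRegister,
    age: int,
    side: Side,
    metric: Metric,
    q: float,
    min_stratum: int = 10,
) -> float:
    """Smallest observed value in the stratum with cumulative frequency >= q."""
    return register.quantile(age, side, metric, q, min_stratum=min_stratum)
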