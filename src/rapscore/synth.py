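"""Synthetic trophy registers, cohorts and pedicle geometry.

The generator emulates the three data layers the analysis pipeline consumes:

* a trophy-register control group (TRCG): ~2924 evaluation sheets with age
  and per-side brow-tine/main-beam lengths, of which a small number carry
  exclusion marks ("deformed", "injured pedicle", "diseased pedicle");
* a healthy morphology control group (MCG, 24 trophies) and an aberrant
  cohort (50 trophies), each with a complete 22-feature x 2-side assessment
  matrix, lengths coherent with the derived flags, and pedicle axis pairs
  coherent with the P2 deformity flag;
* standalone pedicle geometry samples for the two measurement groups
  (66 healthy and 28 abnormal antlers).

Correlated-feature model
------------------------
Each trophy draws one latent severity score ``z ~ N(0, 1)``; its severity
grade I-IV is the mixture-quantile cut of ``z``.  Feature ``f`` on a side is
present iff ``rho*z + sqrt(1-rho^2)*eps > Phi^-1(1 - p_f)`` with independent
noise ``eps``, a Gaussian-copula construction whose marginal prevalence is
exactly ``p_f`` for any coupling strength ``rho``.  Structural constraints
are enforced by construction, preserving the marginals:

* R1, R2 and P2 share one per-side uniform: R2 occupies the top ``p_R2``
  window, R1 the adjacent disjoint window (mutual exclusivity), and P2 the
  top ``p_P2`` window — since ``p_P2 >= p_R2``, R2 implies P2 (the rose
  deformity is not independent of the pedicle deformity).  Configurations
  with ``p_P2 < p_R2`` are rejected with an error naming both features.
* A2 and A3 reuse a single trophy-level noise term for both sides, so they
  are bilateral whenever present.

Lengths are log-normal per (age, side, metric) with age-increasing location
(right-skewed, as register length distributions are); for trophies whose
A2.1/A3.1 entries are set, lengths are drawn from the corresponding tail of
the distribution so the derived flags reproduce the matrix.  Pedicle axis
differences are log-normal with dispersions solved from the group means and
the published 4 mm threshold-crossing rates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .cohort import FeatureMatrix
from .errors import ConfigurationError
from .morphometrics import PedicleGeometry
from .raps import BILATERAL_CODES, FEATURE_CODES
from .registry import Cohort, Metric, Side, SideMeasurements, Species, TrophyRecord

#: Marginal per-(trophy, side) prevalences in the aberrant cohort.  The three
#: features without a published rate (R1, A1, P7) share the residual that
#: makes the 22-feature sum 9.89, i.e. an expected 44.95% positive slots.
DEFAULT_PREVALENCE: Dict[str, float] = {
    "R1": 0.16, "R2": 0.48, "R3": 0.53,
    "A1": 0.16, "A2": 0.76, "A2.1": 0.76, "A3": 0.69, "A3.1": 0.92, "A4": 0.40,
    "P1": 0.80, "P2": 0.60, "P3": 0.61, "P4": 0.63, "P5": 0.16, "P6": 0.29, "P7": 0.16,
    "S1": 0.64, "S2": 0.30, "S3": 0.20, "S4": 0.10, "S5": 0.23, "S6": 0.31,
}


@dataclass(frozen=True)
class GeometryParams:
    """Log-normal axis-difference model plus the major-axis distribution.

    ``sigma_log_diff`` defaults are solved analytically from the published
    group means and 4 mm threshold-crossing rates (19.7% of healthy antlers
    above, 10.7% of abnormal antlers below).
    """

    mean_diff: float       # mm, E[D - d]
    sigma_log_diff: float  # log-scale dispersion of D - d
    mean_D: float          # mm
    sd_D: float            # mm

    def __post_init__(self):
        if self.mean_diff <= 0 or self.sigma_log_diff < 0 or self.mean_D <= 0 or self.sd_D < 0:
            raise ConfigurationError("geometry parameters must be positive (dispersions >= 0)")


@dataclass(frozen=True)
class AgeModel:
    mean: float
    sd: float
    lo: int
    hi: int


@dataclass(frozen=True)
class LengthModel:
    """Log-normal length family with saturating, age-increasing location."""

    brow_base: float = 10.0   # cm at age 0
    brow_slope: float = 1.2   # cm per year up to the cap
    beam_base: float = 30.0
    beam_slope: float = 4.5
    age_cap: int = 10
    sigma_brow: float = 0.25  # log-scale dispersions
    sigma_beam: float = 0.18

    def mu(self, age: int, metric: Metric) -> float:
        if metric is Metric.BROW:
            mean = self.brow_base + self.brow_slope * min(age, self.age_cap)
            return float(np.log(mean) - self.sigma_brow ** 2 / 2)
        mean = self.beam_base + self.beam_slope * min(age, self.age_cap)
        return float(np.log(mean) - self.sigma_beam ** 2 / 2)

    def sigma(self, metric: Metric) -> float:
        return self.sigma_brow if metric is Metric.BROW else self.sigma_beam


@dataclass
class SimulationConfig:
    """Every distributional parameter plus the seed.

    The defaults are the published study conditions: cohort sizes 24/50,
    register size 2924 with 12 marked sheets, mean ages 9 vs 7.74 years,
    the printed per-feature prevalences, a 1.52% control anomaly rate, and
    pedicle axis-difference means 3.12 vs 10.78 mm.
    """

    seed: int = 0
    n_register: int = 2924
    n_register_flagged: int = 12
    n_control: int = 24
    n_aberrant: int = 50
    control_age: AgeModel = field(default_factory=lambda: AgeModel(9.0, 2.0, 4, 14))
    aberrant_age: AgeModel = field(default_factory=lambda: AgeModel(7.74, 2.0, 2, 14))
    lengths: LengthModel = field(default_factory=LengthModel)
    prevalence: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    control_anomaly_rate: float = 0.0152
    coupling: float = 0.4
    grade_mixture: Tuple[float, float, float, float] = (0.15, 0.30, 0.35, 0.20)
    q_brow: float = 0.20
    q_beam: float = 0.05
    healthy_geometry: GeometryParams = field(
        default_factory=lambda: GeometryParams(3.12, 0.3731, 44.0, 4.0)
    )
    abnormal_geometry: GeometryParams = field(
        default_factory=lambda: GeometryParams(10.78, 0.6356, 64.4, 8.0)
    )
    n_geometry_healthy: int = 66
    n_geometry_abnormal: int = 28
    species: Species = Species.DD

    def validate(self) -> None:
        if self.n_register <= 0 or self.n_control <= 0 or self.n_aberrant <= 0:
            raise ConfigurationError("cohort sizes must be positive")
        if not (0 <= self.n_register_flagged <= self.n_register):
            raise ConfigurationError("flagged register count out of range")
        missing = set(FEATURE_CODES) - set(self.prevalence)
        if missing:
            raise ConfigurationError(f"prevalence vector missing features: {sorted(missing)}")
        for code, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"prevalence of {code} outside [0, 1]: {p}")
        if not (0.0 <= self.control_anomaly_rate <= 1.0):
            raise ConfigurationError("control anomaly rate outside [0, 1]")
        if not (0.0 <= self.coupling < 1.0):
            raise ConfigurationError("coupling must lie in [0, 1)")
        if abs(sum(self.grade_mixture) - 1.0) > 1e-9 or any(w < 0 for w in self.grade_mixture):
            raise ConfigurationError("grade mixture must be a probability vector")
        if self.prevalence["P2"] < self.prevalence["R2"]:
            raise ConfigurationError(
                "infeasible prevalence vector: R2 implies P2, so prevalence(P2) "
                f"({self.prevalence['P2']}) must be >= prevalence(R2) ({self.prevalence['R2']})"
            )
        if self.prevalence["R1"] + self.prevalence["R2"] > 1.0:
            raise ConfigurationError(
                "infeasible prevalence vector: R1 and R2 are mutually exclusive, "
                "so their prevalences cannot sum above 1"
            )

    def to_json(self, path=None) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, Species):
                return o.value
            raise TypeError(type(o))

        text = json.dumps(dataclasses.asdict(self), default=default, indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        from pathlib import Path

        raw = json.loads(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        for key, sub in (("control_age", AgeModel), ("aberrant_age", AgeModel),
                         ("lengths", LengthModel),
                         ("healthy_geometry", GeometryParams),
                         ("abnormal_geometry", GeometryParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "grade_mixture" in kwargs:
            kwargs["grade_mixture"] = tuple(kwargs["grade_mixture"])
        if "species" in kwargs:
            kwargs["species"] = Species(kwargs["species"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Core samplers.  One seeded Generator instance drives every draw in the
# fixed order documented below, so identical (seed, config) pairs yield
# bit-identical tables.


def _clamp_u(u: np.ndarray) -> np.ndarray:
    return np.clip(u, 1e-12, 1.0 - 1e-12)


def _sample_features(
    rng: np.random.Generator,
    n: int,
    prev: Dict[str, float],
    coupling: float,
    grade_mixture: Tuple[float, ...],
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Draw an n x 44 presence matrix plus the latent severity grades (1-4).

    Draw order: latent z; one per-side uniform for the {R1, R2, P2} block
    (left then right); one trophy-level noise term per bilateral feature;
    then per-(feature, side) noise for the remaining features in schema
    order, left before right.
    """
    z = rng.standard_normal(n)
    cut = ndtri(np.cumsum(grade_mixture[:-1]))
    grades = np.searchsorted(cut, z) + 1
    s = float(np.sqrt(1.0 - coupling ** 2))
    cols: Dict[str, np.ndarray] = {}

    p_r1, p_r2, p_p2 = prev["R1"], prev["R2"], prev["P2"]
    for side in Side:
        u = _clamp_u(ndtr(coupling * z + s * rng.standard_normal(n)))
        r2 = u > 1.0 - p_r2
        r1 = (u > 1.0 - p_r2 - p_r1) & ~r2
        cols[f"R1_{side.value}"] = r1
        cols[f"R2_{side.value}"] = r2
        cols[f"P2_{side.value}"] = u > 1.0 - p_p2

    for code in BILATERAL_CODES:
        x = coupling * z + s * rng.standard_normal(n)
        present = x > ndtri(1.0 - prev[code]) if prev[code] > 0 else np.zeros(n, bool)
        cols[f"{code}_{Side.LEFT.value}"] = present
        cols[f"{code}_{Side.RIGHT.value}"] = present

    handled = {"R1", "R2", "P2", *BILATERAL_CODES}
    for code in FEATURE_CODES:
        if code in handled:
            continue
        for side in Side:
            x = coupling * z + s * rng.standard_normal(n)
            present = x > ndtri(1.0 - prev[code]) if prev[code] > 0 else np.zeros(n, bool)
            cols[f"{code}_{side.value}"] = present

    order = [f"{c}_{s_.value}" for c in FEATURE_CODES for s_ in Side]
    df = pd.DataFrame({k: cols[k].astype(float) for k in order})
    return df, grades


def _sample_ages(rng: np.random.Generator, n: int, model: AgeModel) -> np.ndarray:
    ages = np.rint(rng.normal(model.mean, model.sd, size=n)).astype(int)
    return np.clip(ages, model.lo, model.hi)


def _tail_length(
    rng: np.random.Generator, mu: float, sigma: float, q: float, below: bool
) -> float:
    """Log-normal draw conditioned strictly below (or at/above) its q-quantile."""
    u = rng.uniform(0.0, q) if below else rng.uniform(q, 1.0)
    return float(np.exp(mu + sigma * ndtri(_clamp_u(np.array([u]))[0])))


def _length(rng: np.random.Generator, mu: float, sigma: float) -> float:
    return float(np.exp(mu + sigma * rng.standard_normal()))


def _axis_pair(
    rng: np.random.Generator, params: GeometryParams, p2: Optional[bool] = None, threshold: float = 4.0
) -> Tuple[float, float]:
    """Draw (D, d) with log-normal D - d; optionally conditioned on the flag."""
    sigma = params.sigma_log_diff
    mu = float(np.log(params.mean_diff) - sigma ** 2 / 2)
    if p2 is None or sigma == 0.0:
        diff = float(np.exp(mu + sigma * rng.standard_normal()))
    else:
        p_below = float(ndtr((np.log(threshold) - mu) / sigma))
        u = rng.uniform(p_below, 1.0) if p2 else rng.uniform(0.0, p_below)
        diff = float(np.exp(mu + sigma * ndtri(_clamp_u(np.array([u]))[0])))
    D = params.mean_D + params.sd_D * rng.standard_normal()
    D = max(D, diff + 1.0)  # keep the minor axis strictly positive
    return D, D - diff


# ---------------------------------------------------------------------------
# Public generators


def gen_register(config: SimulationConfig) -> List[TrophyRecord]:
    """Generate the raw trophy-register sheets (TRCG cohort, lengths only).

    Exactly ``n_register_flagged`` random sheets carry an exclusion mark, so
    filtering reproduces the register-cleaning step.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ages = _sample_ages(rng, config.n_register, config.control_age)
    flagged = set(rng.choice(config.n_register, size=config.n_register_flagged, replace=False).tolist())
    mark_cycle = sorted({"deformed", "injured pedicle", "diseased pedicle"})
    records = []
    for i in range(config.n_register):
        sides = {}
        for side in Side:
            brow = _length(rng, config.lengths.mu(ages[i], Metric.BROW), config.lengths.sigma(Metric.BROW))
            beam = _length(rng, config.lengths.mu(ages[i], Metric.BEAM), config.lengths.sigma(Metric.BEAM))
            sides[side] = SideMeasurements(brow_tine_len=brow, main_beam_len=beam)
        marks = frozenset({mark_cycle[i % 3]}) if i in flagged else frozenset()
        records.append(
            TrophyRecord(
                trophy_id=f"TR{i:05d}",
                species=config.species,
                age_years=int(ages[i]),
                cohort=Cohort.TRCG,
                left=sides[Side.LEFT],
                right=sides[Side.RIGHT],
                harvest_age_years=int(ages[i]),
                marks=marks,
            )
        )
    return records


def _gen_cohort(
    config: SimulationConfig,
    n: int,
    prev: Dict[str, float],
    coupling: float,
    age_model: AgeModel,
    geometry: GeometryParams,
    cohort: Cohort,
    prefix: str,
    seed_offset: int,
) -> Tuple[List[TrophyRecord], FeatureMatrix]:
    rng = np.random.default_rng((config.seed, seed_offset))
    features, _grades = _sample_features(rng, n, prev, coupling, config.grade_mixture)
    ages = _sample_ages(rng, n, age_model)

    records = []
    ids = [f"{prefix}{i:04d}" for i in range(n)]
    for i in range(n):
        sides = {}
        for side in Side:
            sv = side.value
            brow_flag = bool(features.at[i, f"A2.1_{sv}"])
            beam_flag = bool(features.at[i, f"A3.1_{sv}"])
            brow = _tail_length(
                rng, config.lengths.mu(ages[i], Metric.BROW), config.lengths.sigma(Metric.BROW),
                config.q_brow, below=brow_flag,
            )
            beam = _tail_length(
                rng, config.lengths.mu(ages[i], Metric.BEAM), config.lengths.sigma(Metric.BEAM),
                config.q_beam, below=beam_flag,
            )
            D, d = _axis_pair(rng, geometry, p2=bool(features.at[i, f"P2_{sv}"]))
            sides[side] = SideMeasurements(
                brow_tine_len=brow, main_beam_len=beam, pedicle_D=D, pedicle_d=d
            )
        records.append(
            TrophyRecord(
                trophy_id=ids[i],
                species=config.species,
                age_years=int(ages[i]),
                cohort=cohort,
                left=sides[Side.LEFT],
                right=sides[Side.RIGHT],
                harvest_age_years=int(ages[i]),
            )
        )
    matrix = FeatureMatrix(features.set_axis(ids, axis=0), label=cohort.value)
    return records, matrix


def gen_control(config: SimulationConfig) -> Tuple[List[TrophyRecord], FeatureMatrix]:
    """Healthy morphology-control cohort: sparse anomalies, near-circular pedicles."""
    config.validate()
    prev = {code: config.control_anomaly_rate for code in FEATURE_CODES}
    return _gen_cohort(
        config, config.n_control, prev, 0.0, config.control_age,
        config.healthy_geometry, Cohort.MCG, "MC", seed_offset=1,
    )


def gen_aberrant(config: SimulationConfig) -> Tuple[List[TrophyRecord], FeatureMatrix]:
    """Aberrant cohort at the configured marginal prevalences and coupling."""
    config.validate()
    return _gen_cohort(
        config, config.n_aberrant, config.prevalence, config.coupling,
        config.aberrant_age, config.abnormal_geometry, Cohort.ABERRANT, "AB", seed_offset=2,
    )


def gen_geometry(config: SimulationConfig, cohort: str) -> List[PedicleGeometry]:
    """Standalone pedicle axis pairs for the ellipticity measurement groups."""
    config.validate()
    if cohort == "healthy":
        params, n, offset = config.healthy_geometry, config.n_geometry_healthy, 3
    elif cohort == "abnormal":
        params, n, offset = config.abnormal_geometry, config.n_geometry_abnormal, 4
    else:
        raise ValueError(f"cohort must be 'healthy' or 'abnormal', got {cohort!r}")
    rng = np.random.default_rng((config.seed, offset))
    out = []
    for _ in range(n):
        D, d = _axis_pair(rng, params)
        out.append(PedicleGeometry(D=D, d=d))
    return out


def gen_harvest_ages(config: SimulationConfig, cohort: str, n: Optional[int] = None) -> np.ndarray:
    """Harvest-age sample for one cohort (ages only; for survival studies).

    ``cohort`` is "control" (register age distribution, default size
    ``n_register - n_register_flagged``) or "aberrant".
    """
    config.validate()
    if cohort == "control":
        model, default_n, offset = config.control_age, config.n_register - config.n_register_flagged, 5
    elif cohort == "aberrant":
        model, default_n, offset = config.aberrant_age, config.n_aberrant, 6
    else:
        raise ValueError(f"cohort must be 'control' or 'aberrant', got {cohort!r}")
    rng = np.random.default_rng((config.seed, offset))
    return _sample_ages(rng, n or default_n, model)


@dataclass
class SimulatedStudy:
    register: List[TrophyRecord]
    control_records: List[TrophyRecord]
    control_matrix: FeatureMatrix
    aberrant_records: List[TrophyRecord]
    aberrant_matrix: FeatureMatrix
    geometry_healthy: List[PedicleGeometry]
    geometry_abnormal: List[PedicleGeometry]


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Generate every layer of a synthetic study in one call."""
    control_records, control_matrix = gen_control(config)
    aberrant_records, aberrant_matrix = gen_aberrant(config)
    return SimulatedStudy(
        register=gen_register(config),
        control_records=control_records,
        control_matrix=control_matrix,
        aberrant_records=aberrant_records,
        aberrant_matrix=aberrant_matrix,
        geometry_healthy=gen_geometry(config, "healthy"),
        geometry_abnormal=gen_geometry(config, "abnormal"),
    )
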