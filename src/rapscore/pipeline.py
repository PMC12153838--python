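"""End-to-end analysis pipeline and the machine/human-readable report.

``run_pipeline`` takes a single JSON config (or an equivalent dict) that
either names input CSVs or contains a ``simulate`` block, runs every
analysis stage, and returns an :class:`AnalysisReport`.  Stages are
independent: a failing stage is recorded in the report and the remaining
stages still run; a stage whose inputs are absent is marked ``"not run"``.

Every number in the rendered Markdown report is taken from the same nested
dict that ``to_json`` serialises, so the two artefacts cannot diverge.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    FeatureMatrix,
    SideAggregation,
    cooccurrence,
    incidence_ratio,
    length_comparisons,
    overall_fisher,
    per_feature_tests,
    prevalence,
    significant_count,
    survival_compare,
)
from .morphometrics import PedicleGeometry, compare_geometry_groups, read_geometry
from .raps import FEATURE_CODES, RapsAssessment, Side, trophy_grade
from .registry import Cohort, Metric, filter_register, read_register
from .synth import SimulationConfig, simulate_all


@dataclass
class StageResult:
    name: str
    status: str  # "ok" | "failed" | "not run"
    error: Optional[str] = None


@dataclass
class AnalysisReport:
    data: Dict = field(default_factory=dict)
    stages: List[StageResult] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(s.status != "failed" for s in self.stages)

    def to_json(self, path=None, include_timestamp: bool = False) -> str:
        payload = dict(self.data)
        payload["stages"] = [
            {"name": s.name, "status": s.status, "error": s.error} for s in self.stages
        ]
        if include_timestamp:
            payload.setdefault("provenance", {})
            payload["provenance"] = {
                **payload["provenance"],
                "generated_at": datetime.now(timezone.utc).isoformat(),
            }
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self, path=None) -> str:
        lines = ["# RAPS analysis report", ""]
        for s in self.stages:
            suffix = f" ({s.error})" if s.error else ""
            lines.append(f"- stage `{s.name}`: {s.status}{suffix}")
        lines.append("")
        for section, content in self.data.items():
            lines.append(f"## {section}")
            lines.append("")
            lines.append("```json")
            lines.append(json.dumps(content, indent=2, default=_jsonable))
            lines.append("```")
            lines.append("")
        text = "\n".join(lines)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return json.loads(o.to_json(orient="index"))
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def _matrix_to_assessments(matrix: FeatureMatrix) -> List[RapsAssessment]:
    out = []
    for trophy_id, row in matrix.df.iterrows():
        a = RapsAssessment(str(trophy_id))
        for code in FEATURE_CODES:
            for side in Side:
                v = row[f"{code}_{side.value}"]
                a.values[(code, side)] = None if pd.isna(v) else int(v)
        out.append(a)
    return out


DEFAULT_ANALYSIS = {
    "alpha": 0.05,
    "aggregation": "ANY_SIDE",
    "eccentricity": "standard",
    "grade_table": "resolved",
    "species_case_counts": {"DD": 50, "CC": 5, "CE": 3},
    "species_densities": None,
    "reference_species": "CC",
}


def run_pipeline(config) -> AnalysisReport:
    """Run all analysis stages from a JSON config path or a config dict."""
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    analysis = {**DEFAULT_ANALYSIS, **config.get("analysis", {})}
    aggregation = SideAggregation(analysis["aggregation"])
    report = AnalysisReport()

    # ---- inputs -----------------------------------------------------------
    inputs = _load_inputs(config, report)

    report.data["provenance"] = {
        "package_version": __version__,
        "seed": config.get("simulate", {}).get("seed"),
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    report.data["inputs"] = {
        "n_register_raw": inputs.get("n_register_raw"),
        "n_register_kept": None if inputs.get("register") is None else len(inputs["register"]),
        "n_register_excluded": inputs.get("n_register_excluded"),
        "n_control": None if inputs.get("control_matrix") is None else inputs["control_matrix"].n_trophies,
        "n_aberrant": None if inputs.get("aberrant_matrix") is None else inputs["aberrant_matrix"].n_trophies,
    }

    # ---- stages -----------------------------------------------------------
    def stage(name, needs, fn):
        if any(inputs.get(k) is None for k in needs):
            report.stages.append(StageResult(name, "not run"))
            return
        try:
            report.data[name] = fn()
            report.stages.append(StageResult(name, "ok"))
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            report.stages.append(StageResult(name, "failed", f"{type(exc).__name__}: {exc}"))

    def _prevalence():
        out = {}
        for key in ("control_matrix", "aberrant_matrix"):
            summary = prevalence(inputs[key], aggregation)
            out[summary.label or key] = {
                "n_trophies": summary.n_trophies,
                "slot_count": summary.slot_count,
                "positive_count": summary.positive_count,
                "positive_pct": 100.0 * summary.positive_fraction,
                "per_feature": {
                    code: round(float(summary.per_feature.loc[code, "prevalence"]), 4)
                    for code in summary.per_feature.index
                },
            }
        return out

    stage("prevalence", ["control_matrix", "aberrant_matrix"], _prevalence)

    def _grades():
        counts: Dict[str, int] = {"NONE": 0, "I": 0, "II": 0, "III": 0, "IV": 0}
        for a in _matrix_to_assessments(inputs["aberrant_matrix"]):
            g = trophy_grade(a, table=analysis["grade_table"])
            counts[g.name if g is not None else "NONE"] += 1
        return counts

    stage("grade_distribution", ["aberrant_matrix"], _grades)

    def _fisher():
        m, a = inputs["control_matrix"], inputs["aberrant_matrix"]
        p = overall_fisher(m.positive_count, m.slot_count, a.positive_count, a.slot_count)
        return {
            "table": [[m.positive_count, m.slot_count - m.positive_count],
                      [a.positive_count, a.slot_count - a.positive_count]],
            "p_value": p,
            "significant": p < analysis["alpha"],
        }

    stage("overall_fisher", ["control_matrix", "aberrant_matrix"], _fisher)

    def _per_feature():
        tests = per_feature_tests(
            inputs["control_matrix"], inputs["aberrant_matrix"],
            aggregation=aggregation, alpha=analysis["alpha"],
        )
        return {
            "significant_count": significant_count(tests),
            "testable_count": int(tests["testable"].sum()),
            "p_values": {c: (None if pd.isna(p) else float(p)) for c, p in tests["p_value"].items()},
        }

    stage("per_feature_tests", ["control_matrix", "aberrant_matrix"], _per_feature)

    def _cooccurrence():
        cooc = cooccurrence(inputs["aberrant_matrix"], aggregation)
        pairs = [
            {"a": a, "b": b, "count": int(cooc.loc[a, b])}
            for i, a in enumerate(FEATURE_CODES)
            for b in FEATURE_CODES[i + 1:]
            if cooc.loc[a, b] > 0
        ]
        pairs.sort(key=lambda r: -r["count"])
        return {
            "diagonal": {c: int(cooc.loc[c, c]) for c in FEATURE_CODES},
            "top_pairs": pairs[:15],
            "matrix": cooc,
        }

    stage("cooccurrence", ["aberrant_matrix"], _cooccurrence)

    def _lengths():
        groups = {}
        for label, records in (("TRCG", inputs["register"]), ("aberrant", inputs["aberrant_records"])):
            for metric, attr in ((Metric.BROW, "brow_tine_len"), (Metric.BEAM, "main_beam_len")):
                values = [
                    getattr(r.side(s), attr)
                    for r in records
                    for s in Side
                    if getattr(r.side(s), attr) is not None
                ]
                if values:
                    groups[f"{label}_{metric.value}"] = values
        out = {}
        for metric in Metric:
            pair = {k: v for k, v in groups.items() if k.endswith(metric.value)}
            if len(pair) == 2:
                table = length_comparisons(pair)
                out[metric.value] = {
                    "p_raw": float(table["p_raw"].iloc[0]),
                    "p_holm": float(table["p_holm"].iloc[0]),
                }
        return out

    stage("length_comparisons", ["register", "aberrant_records"], _lengths)

    def _survival():
        trcg_ages = [r.harvest_age_years or r.age_years for r in inputs["register"]]
        ab_ages = [r.harvest_age_years or r.age_years for r in inputs["aberrant_records"]]
        res = survival_compare(trcg_ages, ab_ages, labels=("TRCG", "aberrant"))
        return {
            "logrank_statistic": res.statistic,
            "p_value": res.p_value,
            "mean_age": res.mean_age,
        }

    stage("survival", ["register", "aberrant_records"], _survival)

    def _morphometry():
        res = compare_geometry_groups(
            inputs["geometry_healthy"], inputs["geometry_abnormal"],
            definition=analysis["eccentricity"],
        )
        flag_rate = lambda gs: 100.0 * float(np.mean([g.flag() for g in gs]))  # noqa: E731
        return {
            "n_healthy": res.n_healthy,
            "n_abnormal": res.n_abnormal,
            "mean_axis_diff_mm": {"healthy": res.mean_diff_healthy, "abnormal": res.mean_diff_abnormal},
            "p_focal_distance": res.p_focal_distance,
            "p_eccentricity": res.p_eccentricity,
            "flagged_pct": {
                "healthy": flag_rate(inputs["geometry_healthy"]),
                "abnormal": flag_rate(inputs["geometry_abnormal"]),
            },
        }

    stage("morphometry", ["geometry_healthy", "geometry_abnormal"], _morphometry)

    def _incidence():
        table = incidence_ratio(
            analysis["species_case_counts"],
            densities=analysis["species_densities"],
            reference=analysis["reference_species"],
        )
        return {"reference": analysis["reference_species"], "ratios": table}

    stage("incidence_ratios", ["species_case_counts"], _incidence)

    return report


def _load_inputs(config: dict, report: AnalysisReport) -> dict:
    inputs: dict = {"species_case_counts": True}
    if "simulate" in config:
        sim_cfg = SimulationConfig.from_dict(config["simulate"])
        study = simulate_all(sim_cfg)
        raw = study.register
        kept, excluded = filter_register(raw)
        inputs.update(
            n_register_raw=len(raw),
            n_register_excluded=len(excluded),
            register=kept,
            control_records=study.control_records,
            control_matrix=study.control_matrix,
            aberrant_records=study.aberrant_records,
            aberrant_matrix=study.aberrant_matrix,
            geometry_healthy=study.geometry_healthy,
            geometry_abnormal=study.geometry_abnormal,
        )
        report.stages.append(StageResult("simulate", "ok"))
        return inputs

    files = config.get("inputs", {})

    def load(name, fn):
        path = files.get(name)
        if path is None:
            return None
        try:
            return fn(path)
        except Exception as exc:  # noqa: BLE001
            report.stages.append(StageResult(f"load:{name}", "failed", str(exc)))
            return None

    raw = load("register_csv", lambda p: read_register(p).records)
    if raw is not None:
        kept, excluded = filter_register(raw)
        inputs.update(n_register_raw=len(raw), n_register_excluded=len(excluded), register=kept)
    inputs["control_matrix"] = load("control_features_csv", lambda p: FeatureMatrix.from_csv(p, label="MCG"))
    inputs["aberrant_matrix"] = load("aberrant_features_csv", lambda p: FeatureMatrix.from_csv(p, label="ABERRANT"))
    inputs["aberrant_records"] = load("aberrant_register_csv", lambda p: read_register(p).records)

    def load_geometry(name):
        df = load(name, read_geometry)
        if df is None:
            return None
        return [PedicleGeometry(D, d) for D, d in zip(df["D_mm"], df["d_mm"])]

    inputs["geometry_healthy"] = load_geometry("geometry_healthy_csv")
    inputs["geometry_abnormal"] = load_geometry("geometry_abnormal_csv")
    return inputs
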