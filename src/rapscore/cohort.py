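"""Cohort-level statistics over RAPS feature matrices.

The central container is :class:`FeatureMatrix`: one row per trophy, one
column per (feature, side) — 44 columns for the full 22-feature schema —
with entries 1 (present), 0 (absent) or NaN (missing).  Missing entries are
excluded from every denominator and are never imputed.

Side aggregation: ``BY_SIDE`` treats each (trophy, side) as the counting
unit; ``ANY_SIDE`` scores a trophy positive when either side is.  The
bilateral side-comparison features (A2, A3) are by construction present on
both sides whenever present, which inflates BY_SIDE co-occurrence counts; a
``bilateral_once`` switch counts them once per trophy instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import holm_adjust, two_sample_rank_test
from .errors import SchemaError
from .raps import BILATERAL_CODES, FEATURE_CODES, RapsAssessment, Side


class SideAggregation(str, Enum):
    BY_SIDE = "BY_SIDE"
    ANY_SIDE = "ANY_SIDE"


def _columns() -> list:
    return [f"{code}_{side.value}" for code in FEATURE_CODES for side in Side]


class FeatureMatrix:
    """Trophies x (feature, side) binary matrix with a cohort label."""

    def __init__(self, df: pd.DataFrame, label: str = ""):
        missing = set(_columns()) - set(df.columns)
        if missing:
            raise SchemaError(f"feature matrix missing columns: {sorted(missing)[:4]}...")
        self.df = df.loc[:, _columns()].astype(float)
        bad = ~(self.df.isna() | self.df.isin([0.0, 1.0]))
        if bad.to_numpy().any():
            raise ValueError("feature matrix entries must be 0, 1 or missing")
        self.label = label

    @classmethod
    def from_assessments(cls, assessments: Sequence[RapsAssessment], label: str = "") -> "FeatureMatrix":
        rows = {}
        for a in assessments:
            rows[a.trophy_id] = {
                f"{code}_{side.value}": (np.nan if a.values.get((code, side)) is None
                                         else float(a.values[(code, side)]))
                for code in FEATURE_CODES
                for side in Side
            }
        return cls(pd.DataFrame.from_dict(rows, orient="index"), label=label)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_trophies(self) -> int:
        return len(self.df)

    @property
    def slot_count(self) -> int:
        """Number of observed (non-missing) feature slots."""
        return int(self.df.notna().to_numpy().sum())

    @property
    def positive_count(self) -> int:
        return int((self.df == 1.0).to_numpy().sum())

    def is_complete(self) -> bool:
        return not self.df.isna().to_numpy().any()

    def feature_units(self, code: str, aggregation: SideAggregation) -> pd.Series:
        """Per-unit presence for one feature under the chosen aggregation.

        ANY_SIDE: one unit per trophy — 1 if any side is 1, 0 if some side is
        observed 0 and none is 1, NaN if nothing is observed.  BY_SIDE: one
        unit per (trophy, side).
        """
        if code not in FEATURE_CODES:
            raise SchemaError(f"unknown RAPS code {code!r}")
        cols = [f"{code}_{s.value}" for s in Side]
        block = self.df[cols]
        if aggregation is SideAggregation.BY_SIDE:
            return pd.concat([block[c] for c in cols], ignore_index=True)
        return block.max(axis=1, skipna=True)  # all-NaN rows stay NaN

    def to_csv(self, path) -> None:
        self.df.rename_axis("trophy_id").to_csv(path)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "FeatureMatrix":
        return cls(pd.read_csv(path, index_col="trophy_id"), label=label)


@dataclass
class CohortSummary:
    """Prevalence summary of one cohort's feature matrix."""

    label: str
    n_trophies: int
    slot_count: int
    positive_count: int
    per_feature: pd.DataFrame  # index feature; prevalence + denominators

    @property
    def positive_fraction(self) -> float:
        return self.positive_count / self.slot_count


def prevalence(matrix: FeatureMatrix, aggregation: SideAggregation = SideAggregation.ANY_SIDE) -> CohortSummary:
    """Per-feature prevalence with missing entries excluded from denominators."""
    if matrix.n_trophies == 0:
        raise ValueError("cannot summarise an empty feature matrix")
    rows = []
    for code in FEATURE_CODES:
        units = matrix.feature_units(code, aggregation)
        n = int(units.notna().sum())
        k = int((units == 1.0).sum())
        rows.append(
            {"feature": code, "n_units": n, "n_positive": k,
             "prevalence": (k / n) if n else np.nan}
        )
    per_feature = pd.DataFrame(rows).set_index("feature")
    return CohortSummary(
        label=matrix.label,
        n_trophies=matrix.n_trophies,
        slot_count=matrix.slot_count,
        positive_count=matrix.positive_count,
        per_feature=per_feature,
    )


def overall_fisher(mcg_positives: int, mcg_total: int, ab_positives: int, ab_total: int) -> float:
    """Two-sided Fisher exact p for pooled anomalous-slot counts.

    The 2x2 table is (positives, total - positives) per group.  Delegates to
    the log-space hypergeometric implementation in scipy, which is stable for
    register-scale counts.
    """
    for k, n, name in ((mcg_positives, mcg_total, "control"), (ab_positives, ab_total, "aberrant")):
        if not (0 <= k <= n):
            raise ValueError(f"inconsistent {name} counts: {k} positives of {n}")
    table = [[mcg_positives, mcg_total - mcg_positives],
             [ab_positives, ab_total - ab_positives]]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def per_feature_tests(
    mcg: FeatureMatrix,
    ab: FeatureMatrix,
    aggregation: SideAggregation = SideAggregation.ANY_SIDE,
    alpha: float = 0.05,
    yates: bool = False,
) -> pd.DataFrame:
    """Pearson chi-square group-discrimination test per feature.

    One side-aggregated 2x2 table (group x presence) per feature.  Features
    with a zero margin are reported as untestable (``testable=False``,
    p-value NaN) rather than as spurious p-values.  No continuity correction
    by default; set ``yates=True`` for the corrected variant.
    """
    rows = []
    for code in FEATURE_CODES:
        units_m = mcg.feature_units(code, aggregation).dropna()
        units_a = ab.feature_units(code, aggregation).dropna()
        table = np.array(
            [
                [(units_m == 1).sum(), (units_m == 0).sum()],
                [(units_a == 1).sum(), (units_a == 0).sum()],
            ],
            dtype=float,
        )
        testable = bool(np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0))
        if testable:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        else:
            chi2, p = np.nan, np.nan
        rows.append(
            {
                "feature": code,
                "mcg_positive": int(table[0, 0]),
                "mcg_n": int(table[0].sum()),
                "ab_positive": int(table[1, 0]),
                "ab_n": int(table[1].sum()),
                "chi2": chi2,
                "p_value": p,
                "testable": testable,
                "significant": bool(testable and p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def significant_count(tests: pd.DataFrame) -> int:
    return int(tests["significant"].sum())


def cooccurrence(
    matrix: FeatureMatrix,
    aggregation: SideAggregation = SideAggregation.ANY_SIDE,
    bilateral_once: bool = False,
) -> pd.DataFrame:
    """Symmetric feature x feature co-occurrence count matrix.

    Entry (i, j) is the number of units where both features are present;
    the diagonal holds per-feature presence counts.  Missing entries count
    as absent.  With ``bilateral_once`` (BY_SIDE only), the bilateral
    features A2/A3 are counted on the left side only, so their mirrored
    copies do not double every pairing.
    """
    units = {}
    for code in FEATURE_CODES:
        u = matrix.feature_units(code, aggregation).fillna(0.0).to_numpy()
        if (
            bilateral_once
            and aggregation is SideAggregation.BY_SIDE
            and code in BILATERAL_CODES
        ):
            u = u.copy()
            u[matrix.n_trophies:] = 0.0  # BY_SIDE stacks L then R
        units[code] = u
    B = np.column_stack([units[c] for c in FEATURE_CODES])
    counts = (B.T @ B).astype(int)
    return pd.DataFrame(counts, index=FEATURE_CODES, columns=FEATURE_CODES)


def cooccurrence_graph(cooc: pd.DataFrame, min_count: int = 1):
    """networkx graph: node weight = presence count, edge weight = co-occurrences."""
    import networkx as nx

    g = nx.Graph()
    for code in cooc.index:
        g.add_node(code, count=int(cooc.loc[code, code]))
    for a, b in combinations(cooc.index, 2):
        w = int(cooc.loc[a, b])
        if w >= min_count:
            g.add_edge(a, b, weight=w)
    return g


def length_comparisons(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All pairwise two-sample Wilcoxon tests with Holm step-down adjustment.

    The multiplicity family is exactly the set of pairwise comparisons
    requested in one call; raw p-values are always emitted alongside the
    adjusted ones so users can re-adjust under a different family.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups to compare")
    for lab in labels:
        if len(groups[lab]) == 0:
            raise ValueError(f"group {lab!r} is empty")
    pairs = list(combinations(labels, 2))
    raw = [two_sample_rank_test(groups[a], groups[b]) for a, b in pairs]
    adjusted = holm_adjust(raw)
    return pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "n_a": [len(groups[a]) for a, _ in pairs],
            "n_b": [len(groups[b]) for _, b in pairs],
            "p_raw": raw,
            "p_holm": adjusted,
        }
    )


@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves and the two-group log-rank test."""

    km_curves: Dict[str, pd.DataFrame]  # label -> columns (time, survival)
    statistic: float
    p_value: float
    mean_age: Dict[str, float]


def survival_compare(
    ages_a: Sequence[float],
    ages_b: Sequence[float],
    events_a: Optional[Sequence[int]] = None,
    events_b: Optional[Sequence[int]] = None,
    labels: Tuple[str, str] = ("a", "b"),
) -> SurvivalComparison:
    """Product-limit estimates plus the 1-df log-rank chi-square.

    Harvest age is the event time; with no censoring indicators supplied,
    every observation is an event (the register records harvested animals).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    ages_a = np.asarray(ages_a, dtype=float)
    ages_b = np.asarray(ages_b, dtype=float)
    if np.any(ages_a <= 0) or np.any(ages_b <= 0):
        raise ValueError("all ages must be positive")
    events_a = np.ones_like(ages_a) if events_a is None else np.asarray(events_a)
    events_b = np.ones_like(ages_b) if events_b is None else np.asarray(events_b)
    if events_a.sum() == 0 or events_b.sum() == 0:
        raise ValueError("each group must contain at least one event")

    curves = {}
    for label, ages, events in ((labels[0], ages_a, events_a), (labels[1], ages_b, events_b)):
        kmf = KaplanMeierFitter()
        kmf.fit(ages, event_observed=events)
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = logrank_test(ages_a, ages_b, event_observed_A=events_a, event_observed_B=events_b)
    return SurvivalComparison(
        km_curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        mean_age={labels[0]: float(ages_a.mean()), labels[1]: float(ages_b.mean())},
    )


def incidence_ratio(
    case_counts: Mapping[str, int],
    densities: Optional[Mapping[str, float]] = None,
    reference: str = "CC",
) -> pd.DataFrame:
    """Raw and density-adjusted per-species incidence ratios.

    Raw ratio = count / count(reference).  With population densities supplied
    (cases per unit density), adjusted ratio = (count/density) relative to the
    reference.  Densities are inputs, not constants: regional density tables
    are management data, not part of the scoring system.
    """
    if reference not in case_counts:
        raise ValueError(f"reference species {reference!r} not among counts")
    ref_count = case_counts[reference]
    if ref_count <= 0:
        raise ValueError("reference species must have a positive case count")
    if densities is not None:
        for sp, dens in densities.items():
            if dens <= 0:
                raise ValueError(f"density for {sp} must be positive")
    rows = []
    for sp, count in case_counts.items():
        if count < 0:
            raise ValueError(f"negative case count for {sp}")
        row = {"species": sp, "cases": count, "raw_ratio": count / ref_count}
        if densities is not None:
            if sp not in densities or reference not in densities:
                raise ValueError("densities must cover every species incl. the reference")
            row["adjusted_ratio"] = (count / densities[sp]) / (ref_count / densities[reference])
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
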