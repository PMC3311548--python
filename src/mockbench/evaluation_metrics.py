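"""Representation and reproducibility scoring plus rank-based comparisons.

Representation: Euclidean distance of each replicate's observed proportions
to the expected proportions (accurate methods sit near zero).
Reproducibility: distance of each replicate to the method's grand (pooled)
proportions.  Methods are compared pairwise with Wilcoxon rank-sum tests on
representation distances and Fligner-Killeen variance tests on the
reproducibility deviations, Bonferroni-adjusted over all pairs.

Distances are computed on fractions (0-1); plotting in percent only rescales
axes by 100.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats

from .community_model import ProportionVector
from .count_processing import CountTable, grand_proportions, observed_proportions
from .yield_analysis import YieldTable

__all__ = [
    "EvaluationReport",
    "MethodComparison",
    "euclidean_distance",
    "representation_scores",
    "reproducibility_scores",
    "wilcoxon_rank_sum",
    "fligner_killeen",
    "spearman_correlation",
    "bonferroni_adjust",
    "compare_methods",
]


def euclidean_distance(p: ProportionVector, q: ProportionVector) -> float:
    """Plain Euclidean distance between two compositions on shared taxa."""
    p.check_taxa(q)
    return float(np.linalg.norm(p.values - q.values))


def representation_scores(
    table: CountTable, expected: ProportionVector
) -> np.ndarray:
    """Per-replicate distance from observed to expected proportions."""
    expected.check_taxa(table.taxa)
    return np.array(
        [euclidean_distance(obs, expected) for obs in observed_proportions(table)]
    )


def reproducibility_scores(table: CountTable) -> np.ndarray:
    """Per-replicate distance from observed to the pooled grand proportions."""
    if table.n_replicates < 2:
        raise ValueError("reproducibility scoring requires at least 2 replicates")
    baseline = grand_proportions(table)
    return np.array(
        [euclidean_distance(obs, baseline) for obs in observed_proportions(table)]
    )


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> dict:
    """Two-sided Wilcoxon rank-sum test.

    ``mode`` is ``exact``, ``normal`` or ``auto``.  Exact enumeration needs a
    tie-free pooled sample of at most 20 values; otherwise the tie- and
    continuity-corrected normal approximation is used (requested exact falls
    back rather than failing).  The statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in {"exact", "normal", "auto"}:
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = mode in {"exact", "auto"} and not has_ties and pooled.size <= 20
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    rank_sum = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return {
        "statistic": rank_sum,
        "p_two_sided": float(min(res.pvalue, 1.0)),
        "mode": "exact" if use_exact else "normal",
    }


def fligner_killeen(groups) -> dict:
    """Fligner-Killeen homogeneity-of-variance test across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    if all(np.ptp(g) == 0 for g in groups):
        return {"statistic": 0.0, "p": 1.0}
    stat, p = stats.fligner(*groups)
    if not math.isfinite(stat):
        return {"statistic": 0.0, "p": 1.0}
    return {"statistic": float(stat), "p": float(p)}


def spearman_correlation(x, y) -> dict:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """min(1, m * p) with family size ``m`` (defaults to len(p_values))."""
    ps = [float(p) for p in p_values]
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps) if m is None else m
    return [min(1.0, m * p) for p in ps]


@dataclass
class EvaluationReport:
    """Per-method distance profiles plus the block-agreement tests."""

    method: str
    representation_distances: np.ndarray
    reproducibility_distances: np.ndarray
    experimenter_test: dict | None = None
    day_test: dict | None = None
    yield_correlation: dict | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "representation_distances": [float(d) for d in self.representation_distances],
            "reproducibility_distances": [float(d) for d in self.reproducibility_distances],
            "experimenter_test": self.experimenter_test,
            "day_test": self.day_test,
            "yield_correlation": self.yield_correlation,
        }


@dataclass
class MethodComparison:
    """Full cross-method evaluation: reports plus all pairwise tests."""

    reports: dict[str, EvaluationReport]
    representation_pairwise: dict[str, dict] = field(default_factory=dict)
    reproducibility_pairwise: dict[str, dict] = field(default_factory=dict)
    cross_method_correlation: dict | None = None

    @staticmethod
    def pair_key(a: str, b: str) -> str:
        return " vs ".join(sorted((a, b)))

    def to_dict(self) -> dict:
        return {
            "reports": {m: r.to_dict() for m, r in self.reports.items()},
            "representation_pairwise": self.representation_pairwise,
            "reproducibility_pairwise": self.reproducibility_pairwise,
            "cross_method_correlation": self.cross_method_correlation,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "MethodComparison":
        reports = {
            m: EvaluationReport(
                method=r["method"],
                representation_distances=np.array(r["representation_distances"]),
                reproducibility_distances=np.array(r["reproducibility_distances"]),
                experimenter_test=r.get("experimenter_test"),
                day_test=r.get("day_test"),
                yield_correlation=r.get("yield_correlation"),
            )
            for m, r in payload["reports"].items()
        }
        return cls(
            reports=reports,
            representation_pairwise=payload.get("representation_pairwise", {}),
            reproducibility_pairwise=payload.get("reproducibility_pairwise", {}),
            cross_method_correlation=payload.get("cross_method_correlation"),
        )


def _split_by_label(distances: np.ndarray, labels: list[str]) -> dict | None:
    """Wilcoxon between the two level-groups of a block label, if exactly two."""
    levels = sorted(set(labels))
    if len(levels) != 2:
        return None
    a = distances[[i for i, l in enumerate(labels) if l == levels[0]]]
    b = distances[[i for i, l in enumerate(labels) if l == levels[1]]]
    if a.size == 0 or b.size == 0:
        return None
    result = wilcoxon_rank_sum(a, b)
    result["groups"] = levels
    return result


def _mock_yields_by_method(yields: YieldTable) -> dict[str, np.ndarray]:
    df = yields.data
    mock_labels = [s for s in df["sample"].unique() if str(s).lower().startswith("mock")]
    sub = df[df["sample"].isin(mock_labels)] if mock_labels else df
    return {
        m: g.sort_values("replicate")["concentration"].to_numpy()
        for m, g in sub.groupby("method")
    }


def compare_methods(
    tables: dict[str, CountTable],
    expected: ProportionVector,
    yields: YieldTable | None = None,
    alpha: float = 0.05,
) -> MethodComparison:
    """Run the whole evaluation pipeline over per-method count tables."""
    methods = list(tables)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    if len(set(methods)) != len(methods):
        raise ValueError("method labels must be unique")

    yields_mock = _mock_yields_by_method(yields) if yields is not None else {}

    reports: dict[str, EvaluationReport] = {}
    for method in methods:
        table = tables[method]
        rep = representation_scores(table, expected)
        rpr = reproducibility_scores(table)
        experimenters = [m.experimenter for m in table.meta]
        days = [m.day for m in table.meta]
        y_corr = None
        y = yields_mock.get(method)
        if y is not None and y.size == rep.size and y.size >= 3:
            try:
                y_corr = spearman_correlation(y, rep)
            except ValueError:
                y_corr = None
        reports[method] = EvaluationReport(
            method=method,
            representation_distances=rep,
            reproducibility_distances=rpr,
            experimenter_test=_split_by_label(rep, experimenters),
            day_test=_split_by_label(rep, days),
            yield_correlation=y_corr,
        )

    pairs = list(combinations(sorted(methods), 2))
    m_family = len(pairs)
    rep_pairwise: dict[str, dict] = {}
    rpr_pairwise: dict[str, dict] = {}
    for a, b in pairs:
        key = MethodComparison.pair_key(a, b)
        w = wilcoxon_rank_sum(
            reports[a].representation_distances, reports[b].representation_distances
        )
        raw = w["p_two_sided"]
        rep_pairwise[key] = {
            "statistic": w["statistic"],
            "raw_p": raw,
            "adjusted_p": bonferroni_adjust([raw], m_family)[0],
            "significant": bonferroni_adjust([raw], m_family)[0] < alpha,
        }
        fk = fligner_killeen(
            [reports[a].reproducibility_distances, reports[b].reproducibility_distances]
        )
        rpr_pairwise[key] = {
            "statistic": fk["statistic"],
            "raw_p": fk["p"],
            "adjusted_p": bonferroni_adjust([fk["p"]], m_family)[0],
            "significant": bonferroni_adjust([fk["p"]], m_family)[0] < alpha,
        }

    cross = None
    if yields_mock:
        all_y, all_d = [], []
        for method in methods:
            y = yields_mock.get(method)
            if y is not None and y.size == reports[method].representation_distances.size:
                all_y.extend(y)
                all_d.extend(reports[method].representation_distances)
        if len(all_y) >= 3:
            try:
                cross = spearman_correlation(all_y, all_d)
            except ValueError:
                cross = None

    return MethodComparison(
        reports=reports,
        representation_pairwise=rep_pairwise,
        reproducibility_pairwise=rpr_pairwise,
        cross_method_correlation=cross,
    )
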