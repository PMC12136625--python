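"""Yield-frequency analysis for fertilizer dose recommendation.

When the fitted effect function is atypical, the marginal-derivative
optimum is meaningless and the recommended dose is obtained by frequency
analysis instead: choose a target yield interval, count — per nutrient and
per application level — the replicate plots whose yield falls inside it,
and summarize the dose distribution those counts induce:

    weighted mean   x̄ = Σ_j u_j n_j / Σ_j n_j
    SD              S = sqrt( Σ_j n_j (u_j − x̄)² / (Σ n_j − 1) )
    SE              S_x̄ = S / sqrt(Σ n_j)
    95% CI          x̄ ± q · S_x̄

where u_j is the dose at level j and n_j the in-interval plot count at
that level. The CI is the recommended dose range. The default quantile q
is the normal 1.96; the Student-t quantile with Σn_j − 1 degrees of
freedom is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .design import FACTORS
from .effect import QuadraticEffectModel
from .io import TrialData

__all__ = [
    "YieldInterval",
    "FrequencyTable",
    "RecommendationSummary",
    "DoseRecommendation",
    "FrequencyDoseRecommender",
    "count_frequencies",
    "weighted_mean",
    "weighted_sd",
    "standard_error",
    "confidence_interval",
    "recommend_doses",
]


@dataclass(frozen=True)
class YieldInterval:
    """A target yield band [lower, upper] with per-bound inclusivity.

    ``closure`` is one of "both", "left", "right", "neither" — which bounds
    are inclusive. The canonical band is [296, 413] both-inclusive: the
    rounded minimum treatment mean up to the maximum plot yield.
    """

    lower: float
    upper: float
    closure: str = "both"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"interval lower {self.lower} exceeds upper {self.upper}")
        if self.closure not in ("both", "left", "right", "neither"):
            raise ValueError(f"closure must be both/left/right/neither, got {self.closure!r}")

    def contains(self, y: float) -> bool:
        lo_ok = y >= self.lower if self.closure in ("both", "left") else y > self.lower
        hi_ok = y <= self.upper if self.closure in ("both", "right") else y < self.upper
        return lo_ok and hi_ok


@dataclass(frozen=True)
class FrequencyTable:
    """Per-level in-interval plot counts for one nutrient."""

    factor_id: str
    level_doses: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.level_doses) != len(self.counts):
            raise ValueError("one count per level dose required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def rates(self) -> tuple[float, ...]:
        """Per-level share of in-interval plots (fractions of total)."""
        t = self.total
        return tuple(c / t if t else 0.0 for c in self.counts)


@dataclass(frozen=True)
class RecommendationSummary:
    """Dose-distribution summary for one nutrient: mean, SD, SE, CI."""

    factor_id: str
    mean: float
    sd: float
    se: float
    ci: tuple[float, float]
    quantile_used: float
    table: FrequencyTable | None = None


@dataclass(frozen=True)
class DoseRecommendation:
    """Per-nutrient recommendations plus the predicted yield at the point doses."""

    summaries: dict[str, RecommendationSummary]
    point_doses: tuple[float, float, float]
    predicted_yield: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, s in self.summaries.items():
            row = {
                "factor": f,
                "mean": s.mean,
                "sd": s.sd,
                "se": s.se,
                "ci_lower": s.ci[0],
                "ci_upper": s.ci[1],
            }
            if s.table is not None:
                for lv, (u, n) in enumerate(zip(s.table.level_doses, s.table.counts)):
                    row[f"level{lv}_dose"] = u
                    row[f"level{lv}_count"] = n
                row["total"] = s.table.total
            rows.append(row)
        return pd.DataFrame(rows)


def count_frequencies(trial: TrialData, interval: YieldInterval, factor_id: str) -> FrequencyTable:
    """Count plots whose yield lies in the interval, by the plot's level of one factor.

    The counting unit is the individual replicate plot, not the treatment
    mean; each plot contributes to exactly one level per factor.
    """
    if factor_id not in FACTORS:
        raise KeyError(f"unknown factor {factor_id!r}; expected one of {FACTORS}")
    fi = FACTORS.index(factor_id)
    scheme = trial.design.schemes[factor_id]
    n_levels = len(scheme.level_multipliers)
    counts = [0] * n_levels
    for p in trial.plots:
        if interval.contains(p.yield_g):
            counts[p.treatment.levels[fi]] += 1
    return FrequencyTable(
        factor_id=factor_id,
        level_doses=tuple(scheme.dose(lv) for lv in range(n_levels)),
        counts=tuple(counts),
    )


def weighted_mean(table: FrequencyTable) -> float:
    """Frequency-weighted mean dose: Σ u_j n_j / Σ n_j (g/plant)."""
    if table.total == 0:
        raise ZeroDivisionError(f"no in-interval plots for factor {table.factor_id}")
    return sum(u * n for u, n in zip(table.level_doses, table.counts)) / table.total


def weighted_sd(table: FrequencyTable, mean: float | None = None) -> float:
    """Frequency-weighted sample SD of the dose: sqrt(Σ n_j (u_j − x̄)²/(n−1)).

    ``mean`` may be supplied externally (e.g. a published value) to push a
    fixed intermediate through the downstream formulas.
    """
    if table.total < 2:
        raise ValueError(f"need at least 2 in-interval plots, got {table.total}")
    m = weighted_mean(table) if mean is None else mean
    ss = sum(n * (u - m) ** 2 for u, n in zip(table.level_doses, table.counts))
    return sqrt(ss / (table.total - 1))


def standard_error(sd: float, total: int) -> float:
    """SE of the weighted mean dose: sd / sqrt(total)."""
    if total <= 0:
        raise ZeroDivisionError("total count must be positive")
    return sd / sqrt(total)


def _quantile(rule: str, total: int, level: float) -> float:
    if rule == "normal":
        return float(stats.norm.ppf(0.5 + level / 2))
    if rule == "student":
        return float(stats.t.ppf(0.5 + level / 2, df=total - 1))
    raise ValueError(f"quantile rule must be 'normal' or 'student', got {rule!r}")


def confidence_interval(
    mean: float,
    sd: float,
    total: int,
    quantile_rule: str = "normal",
    level: float = 0.95,
) -> tuple[float, float]:
    """Dose range mean ± q·sd/√total.

    ``quantile_rule="normal"`` uses the normal quantile (1.96 at 95%, the
    default, matching how published ranges are customarily derived);
    ``"student"`` uses Student-t with total−1 degrees of freedom.
    """
    if total < 2:
        raise ValueError("confidence interval needs total ≥ 2")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    half = _quantile(quantile_rule, total, level) * standard_error(sd, total)
    return (mean - half, mean + half)


class FrequencyDoseRecommender(BaseEstimator):
    """Frequency-analysis dose recommender (scikit-learn style).

    Parameters
    ----------
    lower, upper : float
        Target yield band in g/plant.
    closure : {"both", "left", "right", "neither"}
        Which bounds are inclusive.
    quantile_rule : {"normal", "student"}
        Quantile for the recommended range.
    level : float
        Confidence level of the range.

    Attributes (after ``fit``)
    --------------------------
    tables_ : dict[str, FrequencyTable]
        Per-nutrient in-interval counts by level.
    summaries_ : dict[str, RecommendationSummary]
        Mean, SD, SE and recommended range per nutrient.
    point_doses_ : tuple of float
        The three weighted-mean doses (N, P2O5, K2O).
    """

    def __init__(
        self,
        lower: float = 296.0,
        upper: float = 413.0,
        closure: str = "both",
        quantile_rule: str = "normal",
        level: float = 0.95,
    ):
        self.lower = lower
        self.upper = upper
        self.closure = closure
        self.quantile_rule = quantile_rule
        self.level = level

    def fit(self, trial: TrialData, y=None):
        interval = YieldInterval(self.lower, self.upper, self.closure)
        self.tables_ = {}
        self.summaries_ = {}
        for f in FACTORS:
            table = count_frequencies(trial, interval, f)
            m = weighted_mean(table)
            sd = weighted_sd(table, m)
            se = standard_error(sd, table.total)
            q = _quantile(self.quantile_rule, table.total, self.level)
            ci = (m - q * se, m + q * se)
            self.tables_[f] = table
            self.summaries_[f] = RecommendationSummary(
                factor_id=f, mean=m, sd=sd, se=se, ci=ci, quantile_used=q, table=table
            )
        self.point_doses_ = tuple(self.summaries_[f].mean for f in FACTORS)
        return self

    def recommend(
        self,
        surface: QuadraticEffectModel,
        point_doses: Sequence[float] | None = None,
    ) -> DoseRecommendation:
        """Bundle the per-nutrient summaries with a predicted yield.

        ``point_doses`` overrides the weighted means (e.g. to evaluate a
        published dose point); ``surface`` must span all three nutrients.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "summaries_")
        doses = tuple(float(d) for d in (point_doses or self.point_doses_))
        if tuple(surface.factors) != FACTORS:
            raise ValueError("predicted yield needs a three-factor effect function")
        return DoseRecommendation(
            summaries=dict(self.summaries_),
            point_doses=doses,  # type: ignore[arg-type]
            predicted_yield=surface.evaluate(doses),
        )


def recommend_doses(
    trial: TrialData,
    interval: YieldInterval,
    ternary_fit: QuadraticEffectModel,
    quantile_rule: str = "normal",
    point_doses: Sequence[float] | None = None,
) -> DoseRecommendation:
    """Full frequency-analysis recommendation: counts → mean → SD → SE → CI → yield."""
    rec = FrequencyDoseRecommender(
        lower=interval.lower,
        upper=interval.upper,
        closure=interval.closure,
        quantile_rule=quantile_rule,
    ).fit(trial)
    return rec.recommend(ternary_fit, point_doses=point_doses)
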