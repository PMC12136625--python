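"""Agronomic and economic indices for omission-plot trials.

Relative yield — the mean yield of a nutrient-omission treatment as a
fraction of the full-fertilizer reference — indexes the soil's capacity to
supply that nutrient (abundance classes: extremely low < 50%, low 50–75%,
medium 75–95%, high ≥ 95%). Per-gram gains and pairwise-combination gains
rank nutrients and nutrient pairs by their contribution to yield. Economic
quantities follow the standard output-value / fertilizer-cost / ratio
definitions with prices per kg and doses/yields in g/plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .design import CONTROL, FACTORS, FACTOR_OXIDE, REFERENCE, TreatmentCode, omission_code
from .io import TrialData

__all__ = [
    "PriceSchedule",
    "AbundanceClass",
    "ABUNDANCE_CLASSES",
    "relative_yield",
    "classify_abundance",
    "per_gram_gain",
    "combination_gain_ranking",
    "output_value",
    "fertilizer_cost",
    "profit_to_investment",
    "yield_increase_pct",
    "usd_gain_vs_control",
    "abundance_report",
    "economics_report",
    "UndefinedRatioError",
]


class UndefinedRatioError(ZeroDivisionError):
    """Profit-to-investment ratio requested for a zero-cost (control) treatment."""


@dataclass(frozen=True)
class PriceSchedule:
    """Crop and fertilizer prices, per kg.

    ``crop_price`` and ``nutrient_prices`` share one currency (CNY in the
    canonical schedule); ``usd_per_cny`` optionally converts derived values
    to USD.
    """

    crop_price: float
    nutrient_prices: Mapping[str, float]
    usd_per_cny: float | None = None

    def __post_init__(self) -> None:
        if self.crop_price <= 0 or any(v <= 0 for v in self.nutrient_prices.values()):
            raise ValueError("all prices must be positive")

    @property
    def usd_crop_price(self) -> float:
        if self.usd_per_cny is None:
            raise ValueError("price schedule has no USD conversion")
        return self.crop_price * self.usd_per_cny


#: Abundance classes as (label, lower bound on relative yield); lower-inclusive.
ABUNDANCE_CLASSES: tuple[tuple[str, float], ...] = (
    ("extremely_low", 0.0),
    ("low", 0.50),
    ("medium", 0.75),
    ("high", 0.95),
)

AbundanceClass = str


def relative_yield(omission_mean: float, reference_mean: float) -> float:
    """Omission-treatment mean as a fraction of the full-fertilizer mean."""
    if reference_mean <= 0:
        raise ZeroDivisionError("reference mean yield must be positive")
    return omission_mean / reference_mean


def classify_abundance(rel_yield: float) -> AbundanceClass:
    """Map a relative yield to its soil-nutrient abundance class.

    Bins are lower-inclusive: [0, 0.50) extremely_low, [0.50, 0.75) low,
    [0.75, 0.95) medium, [0.95, ∞) high.
    """
    if rel_yield < 0:
        raise ValueError(f"relative yield must be nonnegative, got {rel_yield}")
    label = ABUNDANCE_CLASSES[0][0]
    for name, lower in ABUNDANCE_CLASSES:
        if rel_yield >= lower:
            label = name
    return label


def per_gram_gain(full_mean: float, omission_mean: float, dose: float) -> float:
    """Yield gained per gram of nutrient: (full − omission) / dose, g per g."""
    if dose <= 0:
        raise ZeroDivisionError("dose must be positive for a per-gram gain")
    return (full_mean - omission_mean) / dose


_PAIR_ORDER = (("P", "K"), ("N", "P"), ("N", "K"))


def combination_gain_ranking(trial: TrialData) -> list[tuple[str, float]]:
    """Rank nutrient pairs by the yield gain of their level-2 combination.

    The gain of pair (A, B) is the relative increase over the control of
    the treatment supplying exactly A and B at level 2 (the third nutrient
    omitted). Pairs are sorted by descending gain; ties keep the fixed
    order PK, NP, NK.
    """
    control_mean = trial.mean(CONTROL)
    if control_mean <= 0:
        raise ZeroDivisionError("control mean yield must be positive")
    gains = []
    for pair in _PAIR_ORDER:
        omitted = next(f for f in FACTORS if f not in pair)
        code = omission_code(omitted)
        try:
            m = trial.mean(code)
        except KeyError:
            raise KeyError(
                f"pair {''.join(pair)} needs treatment {code.label}, absent from trial"
            ) from None
        gains.append(("".join(pair), (m - control_mean) / control_mean))
    return sorted(gains, key=lambda t: -t[1])


def output_value(mean_yield: float, prices: PriceSchedule) -> float:
    """Crop value per plant: yield (g) × crop price (per kg) / 1000."""
    if mean_yield < 0:
        raise ValueError("yield must be nonnegative")
    return mean_yield * prices.crop_price / 1000.0


def fertilizer_cost(doses: Sequence[float], prices: PriceSchedule) -> float:
    """Fertilizer input per plant: Σ dose_i (g) × price_i (per kg) / 1000 over N, P2O5, K2O."""
    if any(d < 0 for d in doses):
        raise ValueError("doses must be nonnegative")
    return sum(d * prices.nutrient_prices[f] for f, d in zip(FACTORS, doses)) / 1000.0


def profit_to_investment(output_val: float, cost: float) -> float:
    """Output value divided by fertilizer cost (unitless)."""
    if cost <= 0:
        raise UndefinedRatioError("ratio undefined for zero fertilizer cost")
    return output_val / cost


def yield_increase_pct(treatment_mean: float, control_mean: float) -> float:
    """Fractional yield increase over the control: (treatment − control)/control."""
    if control_mean <= 0:
        raise ZeroDivisionError("control mean yield must be positive")
    return (treatment_mean - control_mean) / control_mean


def usd_gain_vs_control(
    treatment_mean: float, control_mean: float, usd_crop_price: float
) -> float:
    """Gross output-value gain over the control in USD per plant.

    (treatment − control) yield (g) × USD crop price (per kg) / 1000; no
    fertilizer-cost subtraction.
    """
    if usd_crop_price <= 0:
        raise ValueError("USD crop price must be positive")
    return (treatment_mean - control_mean) * usd_crop_price / 1000.0


# ---------------------------------------------------------------- reports
def abundance_report(trial: TrialData) -> pd.DataFrame:
    """Relative-yield / abundance table for control and omission treatments.

    One row per treatment in {control, N-, P-, K-omission, reference}:
    mean yield, relative yield (%), abundance class, and — for omission
    rows — the per-gram yield gain of the withheld nutrient.
    """
    try:
        ref_mean = trial.mean(REFERENCE)
    except KeyError:
        raise KeyError("abundance report requires the full-fertilizer treatment N2P2K2") from None
    rows = []
    entries: list[tuple[TreatmentCode, str | None]] = [(CONTROL, None)]
    entries += [(omission_code(f), f) for f in FACTORS]
    entries.append((REFERENCE, None))
    for code, omitted in entries:
        try:
            m = trial.mean(code)
        except KeyError:
            raise KeyError(f"abundance report requires treatment {code.label}") from None
        ry = relative_yield(m, ref_mean)
        row = {
            "treatment": code.label,
            "mean_yield": m,
            "relative_yield_pct": 100.0 * ry,
            "abundance_class": classify_abundance(ry),
            "omitted_nutrient": FACTOR_OXIDE[omitted] if omitted else "",
            "per_gram_gain": float("nan"),
        }
        if omitted is not None:
            dose = trial.design.schemes[omitted].dose(2)
            row["per_gram_gain"] = per_gram_gain(ref_mean, m, dose)
        rows.append(row)
    return pd.DataFrame(rows)


def economics_report(trial: TrialData, prices: PriceSchedule) -> pd.DataFrame:
    """Per-treatment economics: output value, cost, ratio, gains vs control.

    Mirrors the standard trial economics table; the control row's ratio is
    NaN (zero cost). USD gains are included when the schedule carries a
    conversion.
    """
    control_mean = trial.mean(CONTROL)
    rows = []
    for i, (code, doses) in enumerate(trial.design.treatments, start=1):
        try:
            m = trial.mean(code)
        except KeyError:
            continue
        ov = output_value(m, prices)
        cost = fertilizer_cost(doses, prices)
        try:
            ratio = profit_to_investment(ov, cost)
        except UndefinedRatioError:
            ratio = float("nan")
        row = {
            "number": i,
            "treatment": code.label,
            "mean_yield": m,
            "increase_vs_control_pct": 100.0 * yield_increase_pct(m, control_mean),
            "output_value": ov,
            "fertilizer_cost": cost,
            "ratio": ratio,
        }
        if prices.usd_per_cny is not None:
            row["usd_gain_vs_control"] = usd_gain_vs_control(
                m, control_mean, prices.usd_crop_price
            )
        rows.append(row)
    return pd.DataFrame(rows)
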