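"""Canonical honeysuckle '3414' trial: the packaged reference fixture.

A four-year-old *Lonicera japonica* (honeysuckle) formula-fertilization
trial on the Loess Plateau: 14 treatments × 3 replicate plots, level-2
doses 30 g N, 10 g P2O5, 16 g K2O per plant, fresh-bud yield per plant.

Two granularities are packaged, because the published plot table prints
integer replicate yields whose averages differ in the second decimal from
the published treatment means (e.g. 378.67 vs 378.5 for N2P1K2):

* plot-level integer yields (used for frequency counting, 42 plots);
* two-decimal treatment means (used for regression and economics).

``canonical_trial()`` returns the plots with the two-decimal means
attached, so mean-based analyses reproduce the published coefficient
tables while plot-level counting reproduces the frequency table.

The published mean for N0P2K2 appears as both 338.5 and 338.53 in
different tables of the source trial report; 338.53 is stored because only
it reproduces the report's own economics row (ratio 43.22, +14.46%).
"""

from __future__ import annotations

from .design import TreatmentCode, TrialDesign, build_3414_design
from .effect import QuadraticEffectModel
from .indices import PriceSchedule
from .io import PlotYield, TrialData

#: Level-2 doses (N, P2O5, K2O) in g/plant.
CANONICAL_LEVEL2 = (30.0, 10.0, 16.0)

#: Plot-level yields (g/plant), three replicates per treatment, in design order.
PLOT_YIELDS: dict[str, tuple[int, int, int]] = {
    "N0P0K0": (297, 296, 295),
    "N0P2K2": (337, 338, 340),
    "N1P2K2": (386, 396, 387),
    "N2P0K2": (313, 307, 325),
    "N2P1K2": (376, 370, 390),
    "N2P2K2": (391, 402, 407),
    "N2P3K2": (406, 412, 408),
    "N2P2K0": (324, 323, 322),
    "N2P2K1": (370, 369, 378),
    "N2P2K3": (395, 397, 394),
    "N3P2K2": (407, 413, 405),
    "N1P1K2": (364, 373, 366),
    "N1P2K1": (390, 381, 390),
    "N2P1K1": (359, 341, 360),
}

#: Published two-decimal treatment means (g/plant).
TREATMENT_MEANS: dict[str, float] = {
    "N0P0K0": 295.77,
    "N0P2K2": 338.53,
    "N1P2K2": 389.7,
    "N2P0K2": 314.67,
    "N2P1K2": 378.5,
    "N2P2K2": 399.83,
    "N2P3K2": 408.70,
    "N2P2K0": 322.73,
    "N2P2K1": 372.27,
    "N2P2K3": 395.27,
    "N3P2K2": 407.93,
    "N1P1K2": 367.80,
    "N1P2K1": 386.73,
    "N2P1K1": 353.4,
}

#: Treatment subsets used for the published sub-fits (1-based design order).
FIT_TREATMENTS: dict[str, tuple[int, ...]] = {
    "N": (2, 3, 6, 11),
    "P": (4, 5, 6, 7),
    "K": (6, 8, 9, 10),
    "NP": (2, 3, 4, 5, 6, 7, 11, 12),
    "NK": (2, 3, 6, 8, 9, 10, 11, 13),
    "PK": (4, 5, 6, 7, 8, 9, 10, 14),
    "NPK": tuple(range(1, 15)),
}


def canonical_design() -> TrialDesign:
    """The canonical design: '3414' ladder on level-2 doses (30, 10, 16) g/plant."""
    return build_3414_design(CANONICAL_LEVEL2)


def canonical_trial(means: str = "published") -> TrialData:
    """The canonical trial fixture.

    Parameters
    ----------
    means : {"published", "plots"}
        "published" attaches the two-decimal published treatment means
        (the default used for regression and economics); "plots" recomputes
        means from the integer plot yields.
    """
    design = canonical_design()
    plots = [
        PlotYield(TreatmentCode.parse(code), rep, float(y))
        for code, ys in PLOT_YIELDS.items()
        for rep, y in enumerate(ys, start=1)
    ]
    trial = TrialData(design=design, plots=plots)
    if means == "published":
        trial = trial.with_means(
            {TreatmentCode.parse(c): v for c, v in TREATMENT_MEANS.items()}
        )
    elif means != "plots":
        raise ValueError(f"means must be 'published' or 'plots', got {means!r}")
    return trial


def treatments_by_number(numbers: tuple[int, ...] | list[int]) -> list[TreatmentCode]:
    """Map 1-based canonical design positions to treatment codes."""
    codes = canonical_design().codes
    return [codes[i - 1] for i in numbers]


def default_prices() -> PriceSchedule:
    """The canonical price schedule (CNY/kg) with its USD conversion.

    Crop 24, N 4.8, P2O5 6, K2O 8 CNY per kg; 0.1376 USD per CNY
    (equivalently 3.3024 USD/kg for the crop).
    """
    return PriceSchedule(
        crop_price=24.0,
        nutrient_prices={"N": 4.8, "P": 6.0, "K": 8.0},
        usd_per_cny=0.1376,
    )


def published_ternary_model() -> QuadraticEffectModel:
    """The published three-factor quadratic effect function.

    Y = 296.66 − 0.81·X1 + 11.53·X2 + 4.05·X3 − 0.051·X1² − 0.60·X2²
        − 0.28·X3² + 0.13·X1X2 + 0.20·X1X3 − 0.029·X2X3
    with doses in g/plant (X1 = N, X2 = P2O5, X3 = K2O).
    """
    return QuadraticEffectModel.from_coefficients(
        factors=("N", "P", "K"),
        intercept=296.66,
        linear=(-0.81, 11.53, 4.05),
        quadratic=(-0.051, -0.60, -0.28),
        interactions={("N", "P"): 0.13, ("N", "K"): 0.20, ("P", "K"): -0.029},
    )


def published_single_factor_models() -> dict[str, QuadraticEffectModel]:
    """The published single-factor quadratic effect functions."""
    coeffs = {
        "N": (340.95, 3.60, -0.048),
        "P": (316.55, 14.31, -0.55),
        "K": (322.40, 8.11, -0.21),
    }
    return {
        f: QuadraticEffectModel.from_coefficients(
            factors=(f,), intercept=b0, linear=(b1,), quadratic=(b2,)
        )
        for f, (b0, b1, b2) in coeffs.items()
    }


#: Published frequency-analysis intermediates (used as fixed inputs for the
#: standard-error / confidence-interval stages; the published weighted means
#: and the N-factor counts are not reproducible from the counting rule).
PUBLISHED_FREQUENCY_STATS: dict[str, dict[str, float]] = {
    "N": {"mean": 22.5, "sd": 13.17, "total": 37},
    "P": {"mean": 7.5, "sd": 4.05, "total": 41},
    "K": {"mean": 12.0, "sd": 6.40, "total": 41},
}
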