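"""Synthetic '3414' trials from a known quadratic response surface.

The generator draws plot yields as surface value + independent zero-mean
Gaussian noise, truncated at zero. Its defaults emulate the canonical
honeysuckle trial: the (30, 10, 16) g/plant design, three replicate plots
per treatment, and a plot SD of 5 g — the order of the replicate spread
observed in the canonical yield table (±1–10 g). Noise is homoscedastic;
spatial field trends and plot-size effects are deliberately not modeled.

Each plot's noise stream is seeded from (root seed, treatment index,
replicate index), so the same root seed reproduces the same trial and
adding replicates never perturbs earlier draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TrialDesign, build_3414_design
from .effect import QuadraticEffectModel, fit_effect_function
from .io import PlotYield, TrialData

__all__ = ["simulate_trial", "parameter_recovery_report", "TruncationWarning"]


class TruncationWarning(UserWarning):
    """Some simulated plot yields were negative and floored at zero."""


def simulate_trial(
    design: TrialDesign | None,
    surface: QuadraticEffectModel,
    noise_sd: float = 5.0,
    replicates: int = 3,
    seed: int = 0,
) -> TrialData:
    """Simulate a balanced trial from a true response surface.

    Parameters
    ----------
    design :
        Trial design (``None`` for the default (30, 10, 16) '3414' design).
    surface :
        True effect function; must span exactly the design's three factors
        (build one with :meth:`QuadraticEffectModel.from_coefficients`).
    noise_sd :
        Plot-level Gaussian SD in g/plant (0 gives noiseless surface values).
    replicates :
        Plots per treatment; must be ≥ 1.
    seed :
        Root seed; identical seeds give identical trials.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be ≥ 1, got {replicates}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    if design is None:
        design = build_3414_design()
    idx = [("N", "P", "K").index(f) for f in surface.factors]
    plots: list[PlotYield] = []
    n_truncated = 0
    for ti, (code, doses) in enumerate(design.treatments):
        mu = surface.evaluate([doses[i] for i in idx])
        for ri in range(1, replicates + 1):
            rng = np.random.default_rng([int(seed), ti, ri])
            y = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            if y < 0:
                n_truncated += 1
                y = 0.0
            plots.append(PlotYield(code, ri, float(y)))
    if n_truncated:
        warnings.warn(
            f"{n_truncated} simulated plot yields were negative and floored at 0",
            TruncationWarning,
            stacklevel=2,
        )
    return TrialData(design=design, plots=plots)


def parameter_recovery_report(
    surface: QuadraticEffectModel,
    noise_sd: float = 5.0,
    replicates: int = 3,
    n_sims: int = 200,
    design: TrialDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo recovery of surface coefficients by repeated simulate-and-refit.

    Simulates ``n_sims`` trials (root seeds ``seed .. seed+n_sims−1``),
    refits the effect function on treatment means each time, and reports
    per-coefficient truth, mean estimate, bias and RMSE, plus — in the
    frame's ``attrs["typicality_match_rate"]`` — how often the refitted
    surface's typicality verdict matches the true surface's.
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be ≥ 1, got {n_sims}")
    if design is None:
        design = build_3414_design()
    true_typical = surface.typicality().is_typical
    truth = np.asarray(surface.coef_, dtype=float)
    estimates = np.empty((n_sims, truth.size))
    matches = 0
    for s in range(n_sims):
        trial = simulate_trial(design, surface, noise_sd, replicates, seed=seed + s)
        fit = fit_effect_function(trial, factors=surface.factors)
        estimates[s] = fit.coef_
        if fit.typicality().is_typical == true_typical:
            matches += 1
    bias = estimates.mean(axis=0) - truth
    rmse = np.sqrt(((estimates - truth) ** 2).mean(axis=0))
    report = pd.DataFrame(
        {
            "term": surface.term_names(),
            "truth": truth,
            "mean_estimate": estimates.mean(axis=0),
            "bias": bias,
            "rmse": rmse,
        }
    )
    report.attrs["typicality_match_rate"] = matches / n_sims
    report.attrs["n_sims"] = n_sims
    return report
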