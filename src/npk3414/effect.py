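"""Quadratic fertilizer effect functions.

The fertilizer effect function relates nutrient dose to yield per plant by
a quadratic polynomial — with pairwise interaction terms when more than one
nutrient varies:

    Y = b0 + Σ_i b_i x_i + Σ_i b_ii x_i² + Σ_{i<j} b_ij x_i x_j

where x_i are doses in g/plant (N, P2O5, K2O). A *typical* effect function
obeys the law of diminishing returns — every linear coefficient positive
and every pure quadratic coefficient negative — and then has a well-defined
maximum-yield dose (the vertex) and a marginal economic optimum where the
value of the marginal yield response equals the nutrient's unit price. An
*atypical* function (mixed linear signs, as when a nutrient depresses yield
at the margin) makes the marginal-derivative optimum meaningless, and dose
recommendation falls back to yield-frequency analysis.

:class:`QuadraticEffectModel` is a scikit-learn style regressor: ``fit``
takes a dose matrix (one column per factor, g/plant) and yields (g/plant);
fitted coefficients, goodness of fit, typicality and stationary-point
analyses hang off the fitted estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .design import FACTORS, TreatmentCode
from .io import TrialData

__all__ = [
    "QuadraticEffectModel",
    "StationaryPoint",
    "TypicalityVerdict",
    "RankDeficiencyError",
    "AtypicalModelError",
    "NoStationaryPointError",
    "fit_effect_function",
    "evaluate_effect_function",
]


class RankDeficiencyError(ValueError):
    """The dose design does not identify all polynomial coefficients."""


class AtypicalModelError(ValueError):
    """A marginal economic optimum was requested for an atypical effect function."""


class NoStationaryPointError(ValueError):
    """The quadratic-term matrix is singular; no stationary point exists."""


@dataclass(frozen=True)
class TypicalityVerdict:
    """Law-of-diminishing-returns sign check.

    ``violations`` holds one entry per breached sign rule:
    (term, expected sign, observed coefficient). Strict inequalities are
    used, so a zero coefficient counts as a violation.
    """

    is_typical: bool
    violations: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        assert self.is_typical == (len(self.violations) == 0)


@dataclass(frozen=True)
class StationaryPoint:
    """A zero-gradient dose point of a fitted quadratic surface."""

    doses: tuple[float, ...]
    predicted_yield: float
    nature: str  # "maximum" | "minimum" | "saddle"
    factors: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float | str]:
        d: dict[str, float | str] = {f"{f}_dose": x for f, x in zip(self.factors, self.doses)}
        d["predicted_yield"] = self.predicted_yield
        d["nature"] = self.nature
        return d


class QuadraticEffectModel(RegressorMixin, BaseEstimator):
    """Quadratic (response-surface) fertilizer effect function.

    Parameters
    ----------
    factors : tuple of str
        The nutrients whose doses form the columns of ``X``, a subset of
        ("N", "P", "K") in that order. P and K doses are P2O5 / K2O mass.

    Attributes
    ----------
    intercept_ : float
        b0, the predicted yield at zero dose (g/plant).
    linear_ : ndarray of shape (k,)
        b_i, yield response per g of nutrient.
    quadratic_ : ndarray of shape (k,)
        b_ii, curvature per g².
    interactions_ : dict[(str, str), float]
        b_ij for each unordered factor pair (empty for one factor).
    coef_ : ndarray
        Full coefficient vector in design-matrix order
        (intercept, linear, quadratic, interactions).
    r_squared_, f_statistic_, p_value_ : float
        Coefficient of determination and the overall regression F-test
        with (p−1, n−p) degrees of freedom (upper-tail p).
    residuals_ : ndarray
        Observed minus fitted yields, g/plant.
    """

    def __init__(self, factors: Sequence[str] = ("N", "P", "K")):
        self.factors = tuple(factors)

    # ------------------------------------------------------------------ fit
    def _validate_factors(self) -> tuple[str, ...]:
        factors = tuple(self.factors)
        if not factors or any(f not in FACTORS for f in factors):
            raise ValueError(f"factors must be a nonempty subset of {FACTORS}, got {factors}")
        return factors

    @property
    def n_coefficients_(self) -> int:
        k = len(self.factors)
        return 1 + 2 * k + k * (k - 1) // 2

    def _design_matrix(self, X: np.ndarray) -> np.ndarray:
        k = X.shape[1]
        cols = [np.ones(len(X))]
        cols += [X[:, i] for i in range(k)]
        cols += [X[:, i] ** 2 for i in range(k)]
        cols += [X[:, i] * X[:, j] for i, j in combinations(range(k), 2)]
        return np.column_stack(cols)

    def fit(self, X, y):
        """Least-squares fit of the quadratic surface to (dose, yield) points."""
        factors = self._validate_factors()
        X, y = check_X_y(X, y, ensure_min_samples=1)
        k = len(factors)
        if X.shape[1] != k:
            raise ValueError(f"X has {X.shape[1]} columns but model has factors {factors}")
        p = self.n_coefficients_
        if len(y) < p:
            raise RankDeficiencyError(
                f"{len(y)} points cannot identify {p} coefficients for factors {factors}; "
                f"need at least {p - len(y)} more"
            )
        M = self._design_matrix(X)
        coef, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
        if rank < p:
            raise RankDeficiencyError(
                f"dose design is rank deficient: rank {rank} < {p} coefficients "
                f"({p - rank} unidentifiable degrees of freedom)"
            )
        self.coef_ = coef
        self.intercept_ = float(coef[0])
        self.linear_ = coef[1 : 1 + k].copy()
        self.quadratic_ = coef[1 + k : 1 + 2 * k].copy()
        self.interactions_ = {
            (factors[i], factors[j]): float(c)
            for (i, j), c in zip(combinations(range(k), 2), coef[1 + 2 * k :])
        }
        fitted = M @ coef
        self.residuals_ = y - fitted
        self.n_points_ = len(y)
        ss_res = float(self.residuals_ @ self.residuals_)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot > 0:
            self.r_squared_ = 1.0 - ss_res / ss_tot
        else:
            self.r_squared_ = 1.0 if ss_res <= 1e-12 else 0.0
        self.df_model_ = p - 1
        self.df_resid_ = len(y) - p
        if self.df_resid_ > 0 and ss_res > 0:
            self.f_statistic_ = ((ss_tot - ss_res) / self.df_model_) / (ss_res / self.df_resid_)
            self.p_value_ = float(stats.f.sf(self.f_statistic_, self.df_model_, self.df_resid_))
        else:
            self.f_statistic_ = float("inf")
            self.p_value_ = 0.0
        return self

    @classmethod
    def from_coefficients(
        cls,
        factors: Sequence[str],
        intercept: float,
        linear: Sequence[float],
        quadratic: Sequence[float],
        interactions: Mapping[tuple[str, str], float] | None = None,
    ) -> "QuadraticEffectModel":
        """Build a model directly from known coefficients (e.g. a published fit).

        Goodness-of-fit attributes are left unset; prediction, typicality and
        stationary-point analysis are available.
        """
        model = cls(factors=tuple(factors))
        factors = model._validate_factors()
        k = len(factors)
        if len(linear) != k or len(quadratic) != k:
            raise ValueError("linear and quadratic must supply one coefficient per factor")
        inter = dict(interactions or {})
        model.intercept_ = float(intercept)
        model.linear_ = np.asarray(linear, dtype=float)
        model.quadratic_ = np.asarray(quadratic, dtype=float)
        model.interactions_ = {
            (factors[i], factors[j]): float(
                inter.get((factors[i], factors[j]), inter.get((factors[j], factors[i]), 0.0))
            )
            for i, j in combinations(range(k), 2)
        }
        model.coef_ = np.concatenate(
            [
                [model.intercept_],
                model.linear_,
                model.quadratic_,
                [model.interactions_[(factors[i], factors[j])] for i, j in combinations(range(k), 2)],
            ]
        )
        return model

    # -------------------------------------------------------------- predict
    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_min_samples=1)
        if X.shape[1] != len(self.factors):
            raise ValueError(
                f"X has {X.shape[1]} dose columns but model has factors {self.factors}"
            )
        return self._design_matrix(np.asarray(X, dtype=float)) @ self.coef_

    def evaluate(self, doses: Sequence[float]) -> float:
        """Predicted yield (g/plant) at a single dose point, one dose per factor."""
        doses = np.atleast_1d(np.asarray(doses, dtype=float))
        if doses.shape != (len(self.factors),):
            raise ValueError(
                f"expected {len(self.factors)} doses for factors {self.factors}, "
                f"got shape {doses.shape}"
            )
        return float(self.predict(doses.reshape(1, -1))[0])

    # ----------------------------------------------------- surface analysis
    def _hessian(self) -> np.ndarray:
        """Second-derivative matrix: 2·b_ii on the diagonal, b_ij off it."""
        check_is_fitted(self, "coef_")
        k = len(self.factors)
        H = np.diag(2.0 * self.quadratic_)
        for (i, j), (fi, fj) in zip(combinations(range(k), 2), combinations(self.factors, 2)):
            H[i, j] = H[j, i] = self.interactions_[(fi, fj)]
        return H

    def gradient(self, doses: Sequence[float]) -> np.ndarray:
        """∂Y/∂x at a dose point (g yield per g nutrient)."""
        doses = np.asarray(doses, dtype=float)
        return self.linear_ + self._hessian() @ doses

    def stationary_point(self, tol: float = 1e-9) -> StationaryPoint:
        """Solve ∇Y = 0 and classify the point by the Hessian's definiteness.

        For a single factor this is the vertex −b₁/(2·b₁₁). Raises
        :class:`NoStationaryPointError` when the quadratic-term matrix is
        singular.
        """
        H = self._hessian()
        if np.linalg.cond(H) > 1e12:
            raise NoStationaryPointError(
                f"quadratic-term matrix for factors {self.factors} is singular"
            )
        doses = np.linalg.solve(H, -self.linear_)
        grad_norm = float(np.linalg.norm(self.gradient(doses)))
        scale = max(1.0, float(np.linalg.norm(self.linear_)))
        if grad_norm > tol * scale:  # pragma: no cover - solver guard
            raise NoStationaryPointError(f"gradient norm {grad_norm:.2e} exceeds tolerance")
        eig = np.linalg.eigvalsh(H)
        if np.all(eig < 0):
            nature = "maximum"
        elif np.all(eig > 0):
            nature = "minimum"
        else:
            nature = "saddle"
        return StationaryPoint(
            doses=tuple(float(x) for x in doses),
            predicted_yield=self.evaluate(doses),
            nature=nature,
            factors=self.factors,
        )

    def typicality(self) -> TypicalityVerdict:
        """Check the law-of-diminishing-returns sign pattern.

        Typical ⇔ every linear coefficient strictly positive and every pure
        quadratic coefficient strictly negative. Interaction terms carry no
        sign constraint.
        """
        check_is_fitted(self, "coef_")
        violations: list[tuple[str, str, float]] = []
        for f, b in zip(self.factors, self.linear_):
            if not b > 0:
                violations.append((f"{f}_linear", "positive", float(b)))
        for f, b in zip(self.factors, self.quadratic_):
            if not b < 0:
                violations.append((f"{f}_quadratic", "negative", float(b)))
        return TypicalityVerdict(is_typical=not violations, violations=tuple(violations))

    def marginal_optimum(self, prices) -> StationaryPoint:
        """Economic optimum by the marginal-derivative method.

        Solves, per nutrient, marginal yield value = marginal fertilizer
        cost: ``∂Y/∂x_i × crop_price = nutrient_price_i`` (both prices per
        kg, so the ratio is unit-free). Only meaningful for a typical
        effect function with a negative-definite quadratic matrix; an
        atypical fit raises :class:`AtypicalModelError`, mirroring the
        fall-back to frequency analysis.
        """
        verdict = self.typicality()
        if not verdict.is_typical:
            names = ", ".join(v[0] for v in verdict.violations)
            raise AtypicalModelError(
                f"marginal-derivative optimum undefined for atypical effect function "
                f"(sign violations: {names}); use frequency analysis instead"
            )
        H = self._hessian()
        eig = np.linalg.eigvalsh(H)
        if not np.all(eig < 0):
            raise NoStationaryPointError(
                "quadratic-term matrix is not negative definite; no economic optimum"
            )
        target = np.array(
            [prices.nutrient_prices[f] / prices.crop_price for f in self.factors]
        )
        doses = np.linalg.solve(H, target - self.linear_)
        return StationaryPoint(
            doses=tuple(float(x) for x in doses),
            predicted_yield=self.evaluate(doses),
            nature="maximum",
            factors=self.factors,
        )

    # ------------------------------------------------------------- reports
    def term_names(self) -> list[str]:
        k = len(self.factors)
        names = ["intercept"]
        names += [f"{f}" for f in self.factors]
        names += [f"{f}^2" for f in self.factors]
        names += [f"{a}*{b}" for a, b in combinations(self.factors, 2)]
        return names

    def coefficients_frame(self) -> pd.DataFrame:
        """One row per coefficient: term, estimate."""
        check_is_fitted(self, "coef_")
        return pd.DataFrame({"term": self.term_names(), "estimate": self.coef_})

    def to_report(self) -> dict:
        """JSON-serializable fit report: coefficients, diagnostics, typicality, vertex."""
        check_is_fitted(self, "coef_")
        report: dict = {
            "factors": list(self.factors),
            "coefficients": dict(zip(self.term_names(), (float(c) for c in self.coef_))),
        }
        for attr in ("r_squared_", "f_statistic_", "p_value_", "n_points_"):
            if hasattr(self, attr):
                val = getattr(self, attr)
                report[attr.rstrip("_")] = float(val) if val is not None else None
        verdict = self.typicality()
        report["typical"] = verdict.is_typical
        report["violations"] = [list(v) for v in verdict.violations]
        try:
            report["stationary_point"] = self.stationary_point().as_dict()
        except NoStationaryPointError:
            report["stationary_point"] = None
        return report


# ---------------------------------------------------------------- wrappers
def _resolve_treatments(
    trial: TrialData, treatments: Sequence | None
) -> list[TreatmentCode]:
    if treatments is None:
        return trial.design.codes
    codes = []
    for t in treatments:
        if isinstance(t, int):
            codes.append(trial.design.codes[t - 1])
        else:
            codes.append(TreatmentCode.parse(t))
    return codes


def fit_effect_function(
    trial: TrialData,
    factors: Sequence[str] = ("N", "P", "K"),
    treatments: Sequence | None = None,
    data: str = "means",
) -> QuadraticEffectModel:
    """Fit a quadratic effect function on a trial's treatment means or plots.

    Parameters
    ----------
    trial :
        The trial; doses come from its design.
    factors :
        Nutrients to include (the rest are implicit in the treatment choice).
    treatments :
        Treatment selection — codes, "N2P1K2"-style strings, or 1-based
        design positions. Defaults to every treatment in the design.
    data : {"means", "plots"}
        Fit on per-treatment mean yields (default) or individual plots.
        On a balanced trial both give identical coefficients.
    """
    codes = _resolve_treatments(trial, treatments)
    idx = [FACTORS.index(f) for f in factors]
    if data == "means":
        X = np.array([[trial.design.doses_for(c)[i] for i in idx] for c in codes])
        y = np.array([trial.mean(c) for c in codes])
    elif data == "plots":
        sel = set(codes)
        pts = [p for p in trial.plots if p.treatment in sel]
        X = np.array([[trial.design.doses_for(p.treatment)[i] for i in idx] for p in pts])
        y = np.array([p.yield_g for p in pts])
    else:
        raise ValueError(f"data must be 'means' or 'plots', got {data!r}")
    return QuadraticEffectModel(factors=tuple(factors)).fit(X, y)


def evaluate_effect_function(fit: QuadraticEffectModel, doses: Sequence[float]) -> float:
    """Predicted yield of a fitted effect function at one dose point (g/plant)."""
    return fit.evaluate(doses)
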