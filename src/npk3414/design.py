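"""The '3414' incomplete factorial design for N–P–K fertilization trials.

The '3414' scheme — three nutrients (N, P as P2O5, K as K2O), four
application levels each, fourteen treatments — is the standard field-trial
layout of China's soil-testing / formula-fertilization programme. Level 2
is the locally optimal dose, level 1 is half of it, level 3 is one-and-a-half
times it, and level 0 is omission. The fourteen treatments comprise the
control (all level 0), the full-fertilizer reference (all level 2), three
single-nutrient omission treatments, dose ladders for each nutrient with the
other two held at level 2, and four lower-level combinations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

FACTORS: tuple[str, str, str] = ("N", "P", "K")

#: Oxide form each factor's dose is expressed in.
FACTOR_OXIDE = {"N": "N", "P": "P2O5", "K": "K2O"}

#: The fourteen canonical treatments, as (N, P, K) level triples, in
#: standard order (control first, full-fertilizer reference sixth).
CANONICAL_LEVELS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),
    (0, 2, 2),
    (1, 2, 2),
    (2, 0, 2),
    (2, 1, 2),
    (2, 2, 2),
    (2, 3, 2),
    (2, 2, 0),
    (2, 2, 1),
    (2, 2, 3),
    (3, 2, 2),
    (1, 1, 2),
    (1, 2, 1),
    (2, 1, 1),
)

DEFAULT_MULTIPLIERS: tuple[float, float, float, float] = (0.0, 0.5, 1.0, 1.5)

_CODE_RE = re.compile(r"^N\s*(\d)\s*[_\-/., ]*P\s*(\d)\s*[_\-/., ]*K\s*(\d)$", re.I)


@dataclass(frozen=True)
class FactorScheme:
    """Dose ladder for one nutrient.

    Parameters
    ----------
    factor_id : {"N", "P", "K"}
        Nutrient identity; P and K doses are expressed as P2O5 and K2O.
    level2_dose : float
        The level-2 ("locally optimal") dose in g/plant; must be positive.
    level_multipliers : tuple of float
        Fractions of the level-2 dose for levels 0..3.
    """

    factor_id: str
    level2_dose: float
    level_multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS

    def __post_init__(self) -> None:
        if self.factor_id not in FACTORS:
            raise ValueError(f"unknown factor {self.factor_id!r}; expected one of {FACTORS}")
        if not self.level2_dose > 0:
            raise ValueError(
                f"level-2 dose for {self.factor_id} must be positive, got {self.level2_dose}"
            )

    def dose(self, level: int) -> float:
        """Dose in g/plant at the given coded level."""
        return self.level_multipliers[level] * self.level2_dose


@dataclass(frozen=True)
class TreatmentCode:
    """A coded treatment: one application level per factor, e.g. N2P1K2."""

    levels: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != 3 or any(lv not in (0, 1, 2, 3) for lv in self.levels):
            raise ValueError(f"levels must be a triple of integers in 0..3, got {self.levels}")

    @classmethod
    def parse(cls, text: str | Sequence[int] | "TreatmentCode") -> "TreatmentCode":
        """Parse a compact code like ``"N2P3K2"`` (case/separator tolerant) or a level triple."""
        if isinstance(text, TreatmentCode):
            return text
        if not isinstance(text, str):
            return cls(tuple(int(v) for v in text))  # type: ignore[arg-type]
        m = _CODE_RE.match(text.strip())
        if m:
            return cls(tuple(int(g) for g in m.groups()))  # type: ignore[arg-type]
        digits = re.findall(r"\d", text)
        if len(digits) == 3:
            return cls(tuple(int(d) for d in digits))  # type: ignore[arg-type]
        raise ValueError(f"cannot parse treatment code {text!r}")

    @property
    def label(self) -> str:
        n, p, k = self.levels
        return f"N{n}P{p}K{k}"

    @property
    def is_canonical(self) -> bool:
        return self.levels in CANONICAL_LEVELS

    def level(self, factor_id: str) -> int:
        return self.levels[FACTORS.index(factor_id)]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class TrialDesign:
    """A '3414' trial design: dose schemes plus the ordered treatment list."""

    schemes: dict[str, FactorScheme]
    treatments: list[tuple[TreatmentCode, tuple[float, float, float]]] = field(
        default_factory=list
    )

    def doses_for(self, code: TreatmentCode | str) -> tuple[float, float, float]:
        code = TreatmentCode.parse(code)
        for c, d in self.treatments:
            if c == code:
                return d
        raise KeyError(f"treatment {code.label} not in design")

    def __contains__(self, code: object) -> bool:
        try:
            self.doses_for(code)  # type: ignore[arg-type]
        except (KeyError, ValueError):
            return False
        return True

    @property
    def codes(self) -> list[TreatmentCode]:
        return [c for c, _ in self.treatments]

    def to_frame(self) -> pd.DataFrame:
        """Design table with one row per treatment, mirroring the standard layout."""
        rows = []
        for i, (code, doses) in enumerate(self.treatments, start=1):
            rows.append(
                {
                    "number": i,
                    "treatment": code.label,
                    "n_level": code.levels[0],
                    "p_level": code.levels[1],
                    "k_level": code.levels[2],
                    "n_dose": doses[0],
                    "p_dose": doses[1],
                    "k_dose": doses[2],
                }
            )
        return pd.DataFrame(rows)


def build_3414_design(
    level2_doses: Sequence[float] = (30.0, 10.0, 16.0),
    level_multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
) -> TrialDesign:
    """Construct the canonical 14-treatment '3414' design.

    Parameters
    ----------
    level2_doses : (N, P2O5, K2O) in g/plant
        The level-2 doses; each must be positive. The default is the local
        conventional rate of the canonical honeysuckle trial (30, 10, 16).
    level_multipliers :
        Fractions of the level-2 dose applied at levels 0..3.

    Returns
    -------
    TrialDesign
        The fourteen treatments in canonical order, with dose triples equal
        to elementwise ``multiplier × level2_dose``.
    """
    if len(level2_doses) != 3:
        raise ValueError("level2_doses must be a (N, P2O5, K2O) triple")
    schemes = {
        f: FactorScheme(f, float(d), tuple(float(m) for m in level_multipliers))
        for f, d in zip(FACTORS, level2_doses)
    }
    treatments = []
    for levels in CANONICAL_LEVELS:
        code = TreatmentCode(levels)
        doses = tuple(schemes[f].dose(lv) for f, lv in zip(FACTORS, levels))
        treatments.append((code, doses))
    return TrialDesign(schemes=schemes, treatments=treatments)


def omission_code(factor_id: str) -> TreatmentCode:
    """The single-nutrient omission treatment for a factor (level 0 for it, 2 elsewhere)."""
    levels = tuple(0 if f == factor_id else 2 for f in FACTORS)
    return TreatmentCode(levels)  # type: ignore[arg-type]


CONTROL = TreatmentCode((0, 0, 0))
REFERENCE = TreatmentCode((2, 2, 2))
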