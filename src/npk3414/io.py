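"""Reading and writing plot-level trial tables.

Trial tables are UTF-8 comma-separated files with a header row and one row
per plot: treatment code (or the three coded levels), replicate index, and
fresh-bud yield in g/plant. Doses may be present in the file or derived
from a supplied design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

from .design import FACTORS, TreatmentCode, TrialDesign, build_3414_design

TABLE_COLUMNS = [
    "treatment",
    "n_level",
    "p_level",
    "k_level",
    "n_dose",
    "p_dose",
    "k_dose",
    "replicate",
    "yield",
]


class TrialParseError(ValueError):
    """A trial table row could not be interpreted; the message names the row."""


@dataclass(frozen=True)
class PlotYield:
    """One plot: a treatment replicate with its fresh-bud yield (g/plant)."""

    treatment: TreatmentCode
    replicate: int
    yield_g: float

    def __post_init__(self) -> None:
        if self.yield_g < 0:
            raise ValueError(f"plot yield must be nonnegative, got {self.yield_g}")
        if self.replicate < 1:
            raise ValueError(f"replicate index must be positive, got {self.replicate}")


@dataclass
class TrialData:
    """A trial: design, plot-level yields, and per-treatment mean yields.

    ``means`` defaults to the arithmetic mean of each treatment's plot
    yields but may be supplied explicitly — e.g. the two-decimal published
    treatment means of a trial whose plot table prints rounded replicates.
    """

    design: TrialDesign
    plots: list[PlotYield]
    means: dict[TreatmentCode, float] | None = None

    def __post_init__(self) -> None:
        for p in self.plots:
            if p.treatment not in self.design:
                raise ValueError(f"plot treatment {p.treatment.label} not in design")
        if self.means is None:
            self.means = self.computed_means()

    def computed_means(self) -> dict[TreatmentCode, float]:
        """Arithmetic mean of each treatment's plot yields, in design order."""
        sums: dict[TreatmentCode, list[float]] = {}
        for p in self.plots:
            sums.setdefault(p.treatment, []).append(p.yield_g)
        return {
            c: sum(v) / len(v)
            for c in self.design.codes
            if (v := sums.get(c))
        }

    def mean(self, code: TreatmentCode | str) -> float:
        code = TreatmentCode.parse(code)
        assert self.means is not None
        try:
            return self.means[code]
        except KeyError:
            raise KeyError(f"no mean yield for treatment {code.label}") from None

    def with_means(self, means: dict[TreatmentCode, float]) -> "TrialData":
        return TrialData(self.design, list(self.plots), dict(means))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.plots:
            doses = self.design.doses_for(p.treatment)
            n, pl, k = p.treatment.levels
            rows.append(
                {
                    "treatment": p.treatment.label,
                    "n_level": n,
                    "p_level": pl,
                    "k_level": k,
                    "n_dose": doses[0],
                    "p_dose": doses[1],
                    "k_dose": doses[2],
                    "replicate": p.replicate,
                    "yield": p.yield_g,
                }
            )
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def read_trial_table(source: str | Path | IO[str], design: TrialDesign | None = None) -> TrialData:
    """Read a plot-level trial table (CSV) into :class:`TrialData`.

    Parameters
    ----------
    source : path or text buffer
        CSV with header; requires ``treatment`` (or the three ``*_level``
        columns), ``replicate``, and ``yield`` columns.
    design :
        Design supplying doses. When omitted, a canonical '3414' design is
        reconstructed from the file's dose columns (level-2 rows), falling
        back to the default (30, 10, 16) ladder.

    Raises
    ------
    TrialParseError
        On an unknown treatment code or a missing/non-numeric yield; the
        message identifies the offending row.
    """
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    if "yield" not in df.columns:
        raise TrialParseError("trial table lacks a 'yield' column")

    if design is None:
        design = _infer_design(df)

    plots: list[PlotYield] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, counting the header line
        try:
            if "treatment" in df.columns and isinstance(row["treatment"], str):
                code = TreatmentCode.parse(row["treatment"])
            else:
                code = TreatmentCode(
                    tuple(int(row[c]) for c in ("n_level", "p_level", "k_level"))
                )
        except (ValueError, KeyError, TypeError) as exc:
            raise TrialParseError(f"row {rowno}: bad treatment code ({exc})") from exc
        raw = row["yield"]
        try:
            y = float(raw)
        except (TypeError, ValueError):
            raise TrialParseError(
                f"row {rowno}: non-numeric yield {raw!r} for treatment {code.label}"
            ) from None
        if pd.isna(y):
            raise TrialParseError(f"row {rowno}: missing yield for treatment {code.label}")
        rep = int(row["replicate"]) if "replicate" in df.columns and not pd.isna(row["replicate"]) else 1
        if code not in design:
            raise TrialParseError(f"row {rowno}: treatment {code.label} not in design")
        plots.append(PlotYield(code, rep, y))
    return TrialData(design=design, plots=plots)


def _infer_design(df: pd.DataFrame) -> TrialDesign:
    dose_cols = {"n_dose", "p_dose", "k_dose"}
    if dose_cols <= set(df.columns) and {"n_level", "p_level", "k_level"} <= set(df.columns):
        level2 = [None, None, None]
        for _, row in df.iterrows():
            for i, (lc, dc) in enumerate(
                zip(("n_level", "p_level", "k_level"), ("n_dose", "p_dose", "k_dose"))
            ):
                try:
                    if int(row[lc]) == 2:
                        level2[i] = float(row[dc])
                except (TypeError, ValueError):
                    continue
        if all(v is not None and v > 0 for v in level2):
            return build_3414_design(tuple(level2))  # type: ignore[arg-type]
    return build_3414_design()


def write_trial_table(trial: TrialData, destination: str | Path | IO[str]) -> None:
    """Write a trial to CSV; round-trips bit-identically through :func:`read_trial_table`."""
    trial.to_frame().to_csv(destination, index=False)


def write_design_table(design: TrialDesign, destination: str | Path | IO[str]) -> None:
    """Export a design as CSV, one row per treatment with levels and doses."""
    design.to_frame().to_csv(destination, index=False)
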