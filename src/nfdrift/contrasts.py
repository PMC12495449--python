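"""Hypothesis-driven condition contrasts via the generalized inverse.

The task has four conditions — Control (static circle) and three rates of
continuous circle modification (1, 5, 10 Hz) — and three planned hypotheses:

* ``ExpVsControl``: mean of the three experimental conditions minus Control
  (does *any* continuous modification change band power?),
* ``5v1``: 5 Hz minus 1 Hz,
* ``10v5``: 10 Hz minus 5 Hz.

Following the hypothesis-matrix approach to custom contrast coding, each
hypothesis is written as a weight row over condition means (rows sum to zero;
the intercept row holds grand-mean weights 1/4).  The model's condition
columns are the Moore–Penrose generalized inverse of that hypothesis matrix,
so each fitted coefficient estimates exactly its hypothesis quantity even
though the contrasts are not orthogonal.

All entries are kept as exact :class:`fractions.Fraction`; floats appear only
when a numeric design matrix is exported.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
import sympy as sp

CONDITIONS = ("Control", "1Hz", "5Hz", "10Hz")
HYPOTHESES = ("Intercept", "ExpVsControl", "5v1", "10v5")


class DesignError(ValueError):
    """Raised for rank-deficient hypothesis matrices or unknown labels."""


def _to_fraction_array(rows: Sequence[Sequence]) -> list[list[Fraction]]:
    return [[Fraction(x) for x in row] for row in rows]


@dataclass(frozen=True)
class HypothesisMatrix:
    """Hypotheses × conditions weight matrix (exact rationals)."""

    entries: list[list[Fraction]]
    row_labels: tuple[str, ...] = HYPOTHESES
    col_labels: tuple[str, ...] = CONDITIONS

    def as_sympy(self) -> sp.Matrix:
        return sp.Matrix([[sp.Rational(f.numerator, f.denominator) for f in row]
                          for row in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[str(f) for f in row] for row in self.entries],
            index=list(self.row_labels), columns=list(self.col_labels),
        )


@dataclass(frozen=True)
class ContrastMatrix:
    """Conditions × contrast-columns matrix (exact rationals).

    ``entries[i][j]`` is the coding value condition ``row_labels[i]`` takes in
    contrast column ``col_labels[j]``; the first column is the all-ones
    intercept.
    """

    entries: list[list[Fraction]]
    row_labels: tuple[str, ...] = CONDITIONS
    col_labels: tuple[str, ...] = HYPOTHESES

    def value(self, condition: str, contrast: str) -> Fraction:
        return self.entries[self.row_labels.index(condition)][self.col_labels.index(contrast)]

    def to_frame(self, exact: bool = True) -> pd.DataFrame:
        if exact:
            data = [[str(f) for f in row] for row in self.entries]
        else:
            data = [[float(f) for f in row] for row in self.entries]
        return pd.DataFrame(data, index=list(self.row_labels), columns=list(self.col_labels))

    def as_float(self) -> np.ndarray:
        return np.array([[float(f) for f in row] for row in self.entries])


def build_hypothesis_matrix() -> HypothesisMatrix:
    """The study's hypothesis matrix.

    Rows: grand-mean intercept (1/4 per condition); experimental-vs-control
    (mean of 1/5/10 Hz minus Control); 5 Hz − 1 Hz; 10 Hz − 5 Hz.
    """
    third = Fraction(1, 3)
    rows = [
        [Fraction(1, 4)] * 4,
        [Fraction(-1), third, third, third],
        [0, -1, 1, 0],
        [0, 0, -1, 1],
    ]
    return HypothesisMatrix(_to_fraction_array(rows))


def contrast_from_hypotheses(h: HypothesisMatrix) -> ContrastMatrix:
    """Moore–Penrose generalized inverse of the hypothesis matrix.

    For a full-row-rank hypothesis matrix the pseudoinverse is exact in
    rational arithmetic; the result is arranged conditions × contrasts.
    """
    m = h.as_sympy()
    if m.rank() < m.rows:
        raise DesignError("hypothesis matrix is rank deficient; hypotheses are redundant")
    pinv = m.pinv()  # conditions × hypotheses
    entries = [[Fraction(int(sp.fraction(x)[0]), int(sp.fraction(x)[1]))
                for x in pinv.row(i)] for i in range(pinv.rows)]
    return ContrastMatrix(entries, col_labels=h.row_labels, row_labels=h.col_labels)


def condition_contrast_matrix() -> ContrastMatrix:
    """Convenience: the study's printed contrast matrix."""
    return contrast_from_hypotheses(build_hypothesis_matrix())


@dataclass(frozen=True)
class DesignTable:
    """Model-ready design: response frame plus fixed-effect column names."""

    frame: pd.DataFrame
    fixed_columns: tuple[str, ...]
    trial_column: str = "trial_c"
    subject_column: str = "subject"


# contrast column names as used in design tables
_CONTRAST_COLS = ("c_exp_vs_control", "c_5v1", "c_10v5")


def encode_design(
    records: pd.DataFrame,
    contrasts: ContrastMatrix | None = None,
    trial_coding: str = "within_condition",
) -> DesignTable:
    """Attach contrast codes and the trial covariate to a band-power table.

    ``trial_coding='within_condition'`` builds the full model design: the
    per-condition trial index 1..8 is coded ``trial − 1`` (the first trial is
    the reference, so condition effects are read at trial 1), three contrast
    columns code the condition, and three products code the trial×contrast
    interactions.  ``'whole_task'`` codes the global trial 1..32 as
    ``global_trial − 1`` with no condition columns (the exploratory
    whole-task trend model).  ``'control_only'`` keeps Control rows with the
    within-condition trial covariate only.
    """
    df = records.copy()
    if trial_coding == "whole_task":
        df["trial_c"] = df["global_trial_index"].astype(float) - 1.0
        return DesignTable(df, fixed_columns=("trial_c",))
    if trial_coding == "control_only":
        df = df[df["condition"] == "Control"].copy()
        if df.empty:
            raise DesignError("no Control rows in table")
        df["trial_c"] = df["trial_index"].astype(float) - 1.0
        return DesignTable(df, fixed_columns=("trial_c",))
    if trial_coding != "within_condition":
        raise DesignError(f"unknown trial_coding {trial_coding!r}")

    contrasts = contrasts if contrasts is not None else condition_contrast_matrix()
    unknown = set(df["condition"].unique()) - set(contrasts.row_labels)
    if unknown:
        raise DesignError(f"unknown condition labels: {sorted(unknown)}")
    df["trial_c"] = df["trial_index"].astype(float) - 1.0
    for col_name, contrast in zip(_CONTRAST_COLS, contrasts.col_labels[1:]):
        mapping = {cond: float(contrasts.value(cond, contrast)) for cond in contrasts.row_labels}
        df[col_name] = df["condition"].map(mapping)
        df[f"trial_x_{col_name[2:]}"] = df["trial_c"] * df[col_name]
    fixed = ("trial_c",) + _CONTRAST_COLS + tuple(f"trial_x_{c[2:]}" for c in _CONTRAST_COLS)
    return DesignTable(df, fixed_columns=fixed)
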