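"""Dive-shape x year contingency analysis.

Pearson chi-square test of independence on the 3 x 3 table of dive
counts (years x {U, V-early, V-late}), with expected counts and cellwise
Pearson residuals — the residuals are the interpretable quantity: which
year/shape cells are over- or under-represented relative to independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = ["ContingencyTable", "build_table", "chi_square_independence", "shape_year_analysis"]

SHAPE_CLASSES = ["U", "V-early", "V-late"]


@dataclass
class ContingencyTable:
    rows: list
    cols: list
    observed: np.ndarray
    expected: np.ndarray
    residuals: np.ndarray
    chi2: float
    df: int
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per cell with O, E and residual."""
        recs = [
            (r, c, self.observed[i, j], self.expected[i, j], self.residuals[i, j])
            for i, r in enumerate(self.rows)
            for j, c in enumerate(self.cols)
        ]
        return pd.DataFrame(recs, columns=["row", "col", "observed", "expected", "residual"])


def build_table(events: pd.DataFrame) -> pd.DataFrame:
    """Observed counts by year x shape class.

    U dives are counted regardless of phase; V dives are split into
    V-early / V-late by their phase label.
    """
    if events.empty:
        return pd.DataFrame(columns=SHAPE_CLASSES, dtype=int)
    cls = np.where(events["shape"] == "U", "U",
                   np.where(events["phase"] == "early", "V-early", "V-late"))
    tab = pd.crosstab(events["year"], pd.Categorical(cls, categories=SHAPE_CLASSES))
    tab = tab.reindex(columns=SHAPE_CLASSES, fill_value=0)
    tab.index.name = "year"
    return tab


def chi_square_independence(observed, rows=None, cols=None) -> ContingencyTable:
    """Pearson chi-square test of independence on a 2-D count table.

    expected_ij = row_i * col_j / N; residual_ij = (O - E) / sqrt(E);
    chi2 = sum residual^2; df = (r-1)(c-1); p from the upper tail of the
    chi-square distribution via the regularised incomplete gamma function.
    No continuity correction is applied.
    """
    if isinstance(observed, pd.DataFrame):
        rows = list(observed.index) if rows is None else rows
        cols = list(observed.columns) if cols is None else cols
        observed = observed.to_numpy()
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (O < 0).any() or not np.allclose(O, np.round(O)):
        raise ValueError("observed counts must be non-negative integers")
    N = O.sum()
    if N <= 0:
        raise ValueError("grand total must be positive")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    E = np.outer(row, col) / N
    if (E == 0).any():
        raise ValueError("degenerate margin: some expected count is zero")
    resid = (O - E) / np.sqrt(E)
    chi2 = float((resid ** 2).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(special.gammaincc(df / 2.0, chi2 / 2.0))
    r_labels = rows if rows is not None else list(range(O.shape[0]))
    c_labels = cols if cols is not None else list(range(O.shape[1]))
    return ContingencyTable(r_labels, c_labels, O.astype(int), E, resid, chi2, df, p)


def shape_year_analysis(observed_3col) -> dict:
    """The standard two-part summary of a years x (U, V-early, V-late) table.

    The headline test of independence between year and dive *shape* pools
    the two V phases into a single column (years x {U, V}); the phase-split
    3-column table is kept for the descriptive expected counts and Pearson
    residuals, which localise which year/class cells depart from
    independence.  Returns ``{"shape_test": ..., "phase_table": ...}``.
    """
    if isinstance(observed_3col, pd.DataFrame):
        rows = list(observed_3col.index)
        O = observed_3col.to_numpy()
    else:
        O = np.asarray(observed_3col)
        rows = list(range(O.shape[0]))
    if O.shape[1] != 3:
        raise ValueError("expected three columns: U, V-early, V-late")
    pooled = np.c_[O[:, 0], O[:, 1] + O[:, 2]]
    return {
        "shape_test": chi_square_independence(pooled, rows=rows, cols=["U", "V"]),
        "phase_table": chi_square_independence(O, rows=rows, cols=SHAPE_CLASSES),
    }
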