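"""Contingency chi-squared tests of urban representation with adjusted residuals.

Two modes cover the two natural readings of "is global richness
proportionally represented in cities": a two-way contingency test
(urban/non-urban counts by group) and a goodness-of-fit test of observed
urban counts against expected proportions.  Agresti's adjusted residuals
identify which cells drive a significant overall test; |r| > 2 flags a
cell as significantly over- or under-represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyResult", "chi2_adjusted", "chi2_goodness_of_fit"]


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    adjusted_residuals: np.ndarray
    mode: str
    row_labels: list | None = None
    col_labels: list | None = None

    @property
    def significant_cells(self) -> np.ndarray:
        return np.abs(self.adjusted_residuals) > 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjusted_residuals, index=self.row_labels,
                            columns=self.col_labels)


def chi2_adjusted(observed, row_labels=None, col_labels=None) -> ContingencyResult:
    """Two-way contingency chi-squared with Agresti adjusted residuals.

    Expected counts are the product-margin counts E_ij = n_i·n_j / N; the
    adjusted residual of a cell is

        r_ij = (O_ij − E_ij) / sqrt(E_ij (1 − n_i/N)(1 − n_j/N)).

    No continuity correction is applied.  A warning is issued when any
    expected count falls below 5.
    """
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("observed must be a matrix with >= 2 rows and columns")
    if np.any(O < 0):
        raise ValueError("observed counts must be nonnegative")
    N = O.sum()
    if N <= 0:
        raise ValueError("grand total must be positive")
    rows, cols = O.sum(axis=1), O.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    chi2, p, df, E = stats.chi2_contingency(O, correction=False)
    if np.any(E < 5):
        warnings.warn(
            f"{int((E < 5).sum())} cells have expected count < 5; the "
            "chi-squared approximation may be poor", stacklevel=2,
        )
    denom = np.sqrt(E * np.outer(1.0 - rows / N, 1.0 - cols / N))
    r = (O - E) / denom
    return ContingencyResult(
        observed=O, expected=E, chi2=float(chi2), df=int(df), p=float(p),
        adjusted_residuals=r, mode="two_way",
        row_labels=list(row_labels) if row_labels is not None else None,
        col_labels=list(col_labels) if col_labels is not None else None,
    )


def chi2_goodness_of_fit(observed, expected_proportions,
                         labels=None) -> ContingencyResult:
    """Goodness-of-fit chi-squared of counts against expected proportions.

    Tests whether urban species counts per group are proportional to a
    reference richness distribution; df = k − 1.  Adjusted (standardized)
    residuals are (O_i − E_i)/sqrt(E_i (1 − p_i)).
    """
    O = np.asarray(observed, dtype=float)
    pr = np.asarray(expected_proportions, dtype=float)
    if O.ndim != 1 or O.shape != pr.shape:
        raise ValueError("observed and expected_proportions must be "
                         "1-d and the same length")
    if np.any(O < 0) or np.any(pr <= 0):
        raise ValueError("counts must be >= 0 and proportions > 0")
    pr = pr / pr.sum()
    N = O.sum()
    if N <= 0:
        raise ValueError("grand total must be positive")
    E = N * pr
    chi2 = float(((O - E) ** 2 / E).sum())
    df = len(O) - 1
    p = float(stats.chi2.sf(chi2, df))
    if np.any(E < 5):
        warnings.warn("expected counts < 5 present", stacklevel=2)
    r = (O - E) / np.sqrt(E * (1.0 - pr))
    return ContingencyResult(
        observed=O[None, :], expected=E[None, :], chi2=chi2, df=df, p=p,
        adjusted_residuals=r[None, :], mode="goodness_of_fit",
        row_labels=["observed"],
        col_labels=list(labels) if labels is not None else None,
    )
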