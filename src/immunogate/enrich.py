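"""Tissue-enrichment statistics and composition summaries.

For a labels x tissues contingency table, enrichment is shown as chi-squared
standardized residuals. Two variants are computed: the Pearson residual
``(O - E)/sqrt(E)`` and the adjusted (Haberman) residual
``(O - E)/sqrt(E (1 - R/N)(1 - C/N))`` — the latter has unit variance under
independence, so it can be read against an N(0,1) reference. For display the
adjusted residuals can additionally be scaled linearly to [-1, 1] by dividing
by their maximum magnitude; scaling preserves sign and ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError


def contingency_table(labels, tissues) -> pd.DataFrame:
    """Cross-tabulate cell labels (rows) against tissues (columns)."""
    return pd.crosstab(pd.Series(list(labels)), pd.Series(list(tissues)))


@dataclass
class EnrichmentResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    pearson: pd.DataFrame
    adjusted: pd.DataFrame
    scaled: pd.DataFrame | None
    chi_square: float
    df: int


def standardized_residuals(
    table: pd.DataFrame, scale_linear: bool = False
) -> EnrichmentResult:
    """Chi-squared standardized residuals of a contingency table.

    ``E_ij = R_i C_j / N``; Pearson ``r = (O - E)/sqrt(E)`` (0 where E = 0);
    adjusted ``s = r / sqrt((1 - R_i/N)(1 - C_j/N))``; the chi-square
    statistic is ``sum r^2`` with ``(rows-1)(cols-1)`` degrees of freedom.
    With a single row or column no enrichment is possible: residuals are all
    zero and a warning is issued.
    """
    table = pd.DataFrame(table)
    obs = table.to_numpy(dtype=float)
    if obs.min() < 0:
        raise ValidationError("negative counts in contingency table")
    n = obs.sum()
    if n <= 0:
        raise ValidationError("empty contingency table")
    r = obs.sum(axis=1)
    c = obs.sum(axis=0)
    expected = np.outer(r, c) / n

    if obs.shape[0] < 2 or obs.shape[1] < 2:
        warnings.warn("single row or column: no enrichment possible")
        zeros = np.zeros_like(obs)
        zdf = pd.DataFrame(zeros, index=table.index, columns=table.columns)
        return EnrichmentResult(
            observed=table,
            expected=pd.DataFrame(expected, index=table.index, columns=table.columns),
            pearson=zdf,
            adjusted=zdf.copy(),
            scaled=zdf.copy() if scale_linear else None,
            chi_square=0.0,
            df=0,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.where(expected > 0, (obs - expected) / np.sqrt(expected), 0.0)
        denom = np.sqrt(np.outer(1.0 - r / n, 1.0 - c / n))
        adjusted = np.where(denom > 0, pearson / denom, 0.0)
    chi_square = float((pearson**2).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)

    scaled = None
    if scale_linear:
        m = np.abs(adjusted).max()
        scaled_arr = adjusted / m if m > 0 else adjusted
        scaled = pd.DataFrame(scaled_arr, index=table.index, columns=table.columns)

    wrap = lambda a: pd.DataFrame(a, index=table.index, columns=table.columns)
    return EnrichmentResult(
        observed=table,
        expected=wrap(expected),
        pearson=wrap(pearson),
        adjusted=wrap(adjusted),
        scaled=scaled,
        chi_square=chi_square,
        df=df,
    )


def composition_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue composition: ``f_ij = O_ij / C_j`` (columns sum to 1).

    Zero-count tissue columns yield fractions of 0 with a warning.
    """
    table = pd.DataFrame(table)
    obs = table.to_numpy(dtype=float)
    if obs.sum() <= 0:
        raise ValidationError("empty contingency table")
    c = obs.sum(axis=0)
    if np.any(c == 0):
        warnings.warn("zero-count tissue column; fractions set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(c > 0, obs / np.maximum(c, 1e-300), 0.0)
    return pd.DataFrame(frac, index=table.index, columns=table.columns)
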