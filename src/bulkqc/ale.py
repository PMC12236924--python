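"""Accumulated Local Effects (ALE) for model interpretation.

ALE decomposes a fitted predictor into centered per-variable effect
functions by accumulating, over an empirical-quantile grid, the average
local change in prediction when the variable moves across each interval
while all other variables keep their observed values.  Unlike partial
dependence, ALE stays faithful under correlated features because it
only evaluates the model near the data.

Two orders are provided:

* first-order: the main effect f_i(x_i) of one variable, centered so
  that the effect averaged over the data is zero;
* second-order: the pure interaction surface f_ij(x_i, x_j) of a pair,
  with both main effects removed and the surface centered.

A scalar importance summarizes each effect as the average absolute
centered effect over the data,

    ALEAvgImp(x_i) = (1/n) * sum_j |f_i(x_ij)|,

which is comparable across variables because every effect is on the
scale of the model output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ALEResult", "ale_effect_1d", "ale_effect_2d", "ale_average_importance"]


@dataclass
class ALEResult:
    """Centered ALE effect for one variable or a pair.

    ``grid`` holds the interval edges (1-D: length K+1; 2-D: tuple of two
    edge vectors).  ``effect`` holds the centered effect at the grid
    (1-D: length K+1; 2-D: (K1+1, K2+1) surface).  ``sample_effects``
    are the centered effects evaluated at the data (interval-mid
    convention), so they average to zero; ``importance`` is their mean
    absolute value.
    """

    variable: str | tuple[str, str]
    grid: np.ndarray | tuple[np.ndarray, np.ndarray]
    effect: np.ndarray
    sample_effects: np.ndarray
    importance: float


def ale_average_importance(sample_effects) -> float:
    """Mean absolute centered effect over the data."""
    return float(np.mean(np.abs(np.asarray(sample_effects, dtype=float))))


def _quantile_grid(x: np.ndarray, n_intervals: int) -> np.ndarray:
    """Unique empirical-quantile edges; may return fewer intervals."""
    qs = np.linspace(0, 1, n_intervals + 1)
    z = np.unique(np.quantile(x, qs))
    return z


def _interval_index(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Interval of each x in 0..K-1 with z[k] < x <= z[k+1]; min goes to 0."""
    idx = np.searchsorted(z, x, side="left") - 1
    return np.clip(idx, 0, len(z) - 2)


def ale_effect_1d(predict, X: pd.DataFrame, variable: str, n_intervals: int = 40) -> ALEResult:
    """First-order ALE of ``variable`` under ``predict`` on data ``X``.

    ``predict`` maps a DataFrame with X's columns to a 1-D array of
    model outputs (for a quality classifier, the probability of the
    high-quality class).  A constant variable yields a zero effect.
    """
    x = X[variable].to_numpy(dtype=float)
    if np.all(x == x[0]):
        zeros = np.zeros(len(X))
        return ALEResult(variable, np.array([x[0], x[0]]), np.zeros(2), zeros, 0.0)
    z = _quantile_grid(x, n_intervals)
    K = len(z) - 1
    idx = _interval_index(x, z)

    lo = X.copy()
    hi = X.copy()
    lo[variable] = z[idx]
    hi[variable] = z[idx + 1]
    delta = np.asarray(predict(hi), dtype=float) - np.asarray(predict(lo), dtype=float)

    counts = np.bincount(idx, minlength=K).astype(float)
    sums = np.bincount(idx, weights=delta, minlength=K)
    with np.errstate(invalid="ignore"):
        avg = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    fJ = np.concatenate([[0.0], np.cumsum(avg)])  # effect at grid edges
    mids = (fJ[:-1] + fJ[1:]) / 2.0  # effect attributed to each interval
    center = np.sum(mids * counts) / counts.sum()
    fJ -= center
    sample_effects = (mids - center)[idx]
    return ALEResult(variable, z, fJ, sample_effects, ale_average_importance(sample_effects))


def ale_effect_2d(
    predict,
    X: pd.DataFrame,
    variable_pair: tuple[str, str],
    n_intervals: int = 10,
) -> ALEResult:
    """Second-order (pure interaction) ALE surface for a variable pair.

    Second differences of the prediction across grid cells are averaged
    per cell, doubly accumulated, stripped of both first-order effects
    and centered.  Empty cells inherit the second difference of the
    nearest populated cell.  For an additive model the surface is zero
    up to discretization error.
    """
    v1, v2 = variable_pair
    x1 = X[v1].to_numpy(dtype=float)
    x2 = X[v2].to_numpy(dtype=float)
    if np.all(x1 == x1[0]) or np.all(x2 == x2[0]):
        raise ValueError("both variables must be non-constant")
    z1 = _quantile_grid(x1, n_intervals)
    z2 = _quantile_grid(x2, n_intervals)
    K1, K2 = len(z1) - 1, len(z2) - 1
    i1 = _interval_index(x1, z1)
    i2 = _interval_index(x2, z2)

    def pred_at(a, b):
        Xm = X.copy()
        Xm[v1] = a
        Xm[v2] = b
        return np.asarray(predict(Xm), dtype=float)

    second_diff = (
        pred_at(z1[i1 + 1], z2[i2 + 1])
        - pred_at(z1[i1], z2[i2 + 1])
        - pred_at(z1[i1 + 1], z2[i2])
        + pred_at(z1[i1], z2[i2])
    )

    flat = i1 * K2 + i2
    counts = np.bincount(flat, minlength=K1 * K2).astype(float).reshape(K1, K2)
    sums = np.bincount(flat, weights=second_diff, minlength=K1 * K2).reshape(K1, K2)
    with np.errstate(invalid="ignore"):
        delta = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    # nearest-populated-cell imputation for empty cells
    if np.isnan(delta).any():
        filled = np.argwhere(counts > 0)
        empty = np.argwhere(counts == 0)
        for (a, b) in empty:
            d2 = ((filled[:, 0] - a) ** 2 + (filled[:, 1] - b) ** 2)
            na, nb = filled[np.argmin(d2)]
            delta[a, b] = delta[na, nb]

    # double accumulation with a zero border
    H = np.zeros((K1 + 1, K2 + 1))
    H[1:, 1:] = np.cumsum(np.cumsum(delta, axis=0), axis=1)

    # remove first-order components (weighted by cell occupancy)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    d1 = H[1:, :] - H[:-1, :]  # K1 x (K2+1)
    avg1 = ((d1[:, :-1] + d1[:, 1:]) / 2.0 * counts).sum(axis=1) / np.maximum(row_tot, 1)
    avg1[row_tot == 0] = 0.0
    f1 = np.concatenate([[0.0], np.cumsum(avg1)])
    d2_ = H[:, 1:] - H[:, :-1]  # (K1+1) x K2
    avg2 = ((d2_[:-1, :] + d2_[1:, :]) / 2.0 * counts).sum(axis=0) / np.maximum(col_tot, 1)
    avg2[col_tot == 0] = 0.0
    f2 = np.concatenate([[0.0], np.cumsum(avg2)])
    H = H - f1[:, None] - f2[None, :]

    cell_mid = (H[:-1, :-1] + H[:-1, 1:] + H[1:, :-1] + H[1:, 1:]) / 4.0
    center = (cell_mid * counts).sum() / counts.sum()
    H -= center
    sample_effects = (cell_mid - center)[i1, i2]
    return ALEResult(
        (v1, v2), (z1, z2), H, sample_effects, ale_average_importance(sample_effects)
    )
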