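"""Agreement metrics between predicted and reference signals/maps.

NRMSE is the root-mean-square error normalized by the dynamic range
(max - min) of the reference over the evaluated set; this convention is
recorded in every metrics record so thresholds stay interpretable.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def nrmse(predicted, reference) -> float:
    """Range-normalized RMSE (fraction, not percent)."""
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    if predicted.shape != reference.shape:
        raise ValueError("shape mismatch")
    rng = reference.max() - reference.min()
    if rng == 0:
        raise ValueError("reference has zero dynamic range")
    return float(np.sqrt(np.mean((predicted - reference) ** 2)) / rng)


def evaluate_trajectories(predicted, reference) -> dict:
    """Pooled agreement record: NRMSE, Pearson r and its p-value."""
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    err = nrmse(predicted, reference)
    r, p = stats.pearsonr(predicted.ravel(), reference.ravel())
    return {
        "nrmse": err,
        "nrmse_percent": 100.0 * err,
        "pearson_r": float(r),
        "pearson_p": float(p),
        "n_elements": int(predicted.size),
        "normalization": "reference dynamic range (max - min)",
    }


def per_iteration_nrmse(predicted, reference) -> np.ndarray:
    """NRMSE per schedule element (columns), normalized by the global
    reference range, for error-vs-iteration trend analysis."""
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    if predicted.shape != reference.shape or predicted.ndim != 2:
        raise ValueError("expect matching (n_trajectories, n_elements) arrays")
    rng = reference.max() - reference.min()
    if rng == 0:
        raise ValueError("reference has zero dynamic range")
    return np.sqrt(np.mean((predicted - reference) ** 2, axis=0)) / rng


def iteration_trend(predicted, reference) -> dict:
    """Spearman trend of per-iteration NRMSE against the iteration index."""
    errs = per_iteration_nrmse(predicted, reference)
    rho, p = stats.spearmanr(np.arange(len(errs)), errs)
    return {"per_iteration_nrmse": errs, "spearman_rho": float(rho),
            "spearman_p": float(p)}


def binned_nrmse(predicted, reference, values, n_bins: int = 5):
    """Pooled NRMSE stratified into quantile bins of a per-trajectory value
    (exchange rate, volume fraction, mean B1, ...).

    Returns (bin_centers, errors); bins with no members yield NaN.
    """
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    values = np.asarray(values, float)
    rng = reference.max() - reference.min()
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    errs = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            errs[b] = np.sqrt(np.mean((predicted[sel] - reference[sel]) ** 2)) / rng
    return centers, errs
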