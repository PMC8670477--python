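"""Population-coding metrics: sparseness, specificity, geometry, ablation.

Lifetime sparseness (Treves–Rolls) and valence specificity are per-KC
selectivity measures in [0, 1], undefined (NaN) for KCs that never respond.
Angular distance and participation-ratio dimensionality summarize the
geometry of the population code.  ``ablate_top`` removes the most selective
KCs and replaces them with useless ones, the manipulation used to show that
a small minority of selective cells carries the dense-coding advantage.
"""

from __future__ import annotations

import warnings

import numpy as np

from .network import ResponseTensor

__all__ = [
    "lifetime_sparseness",
    "valence_specificity",
    "angular_distance",
    "dimensionality",
    "ablate_top",
    "silent_fraction",
]


def _odor_rates(responses) -> np.ndarray:
    """(n_kc, n_odor) trial-averaged rates from tensor/matrix input."""
    if isinstance(responses, ResponseTensor):
        return responses.odor_means()
    r = np.asarray(responses, dtype=float)
    if r.ndim == 3:
        return r.mean(axis=2)
    return r


def lifetime_sparseness(rates: np.ndarray) -> np.ndarray | float:
    """Treves–Rolls lifetime sparseness across stimuli.

    ``S = (1 - (sum(r)/n)^2 / (sum(r^2)/n)) / (1 - 1/n)`` over the n odors:
    1 for a cell firing to exactly one stimulus, 0 for a uniform responder,
    NaN (undefined) for a cell that fires to no stimulus.  Accepts a single
    rate vector or an (n_kc, n_odor) matrix (row-wise).
    """
    r = np.asarray(rates, dtype=float)
    single = r.ndim == 1
    r = np.atleast_2d(r)
    n = r.shape[1]
    if n < 2:
        raise ValueError("lifetime sparseness needs at least two stimuli")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    sum_r = r.sum(axis=1)
    sum_r2 = (r**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (1.0 - (sum_r / n) ** 2 / (sum_r2 / n)) / (1.0 - 1.0 / n)
    s = np.where(sum_r > 0, s, np.nan)
    return float(s[0]) if single else s


def valence_specificity(
    rates: np.ndarray, valences: np.ndarray
) -> np.ndarray | float:
    """|total activity to rewarded − to punished| / total activity.

    NaN for silent KCs.  Both valences must be present.
    """
    r = np.asarray(rates, dtype=float)
    single = r.ndim == 1
    r = np.atleast_2d(r)
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    valences = np.asarray(valences, dtype=bool)
    if valences.shape[0] != r.shape[1]:
        raise ValueError("one valence per odor is required")
    if valences.all() or not valences.any():
        raise ValueError("both valences must be present")
    rew = r[:, valences].sum(axis=1)
    pun = r[:, ~valences].sum(axis=1)
    total = rew + pun
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.abs(rew - pun) / total
    v = np.where(total > 0, v, np.nan)
    return float(v[0]) if single else v


def angular_distance(responses, degrees: bool = True) -> float:
    """Mean pairwise angle between odor centroids in KC space.

    Centroids are trial averages per odor; the angle between centroids a, b
    is ``arccos(<a,b> / (|a||b|))``.  Pairs involving a zero centroid are
    skipped with a warning.
    """
    cent = _odor_rates(responses)  # (n_kc, n_odor) columns are centroids
    n_odor = cent.shape[1]
    if n_odor < 2:
        raise ValueError("need at least two odors")
    norms = np.linalg.norm(cent, axis=0)
    ok = norms > 0
    n_skipped = 0
    angles = []
    for i in range(n_odor):
        for j in range(i + 1, n_odor):
            if not (ok[i] and ok[j]):
                n_skipped += 1
                continue
            cosang = cent[:, i] @ cent[:, j] / (norms[i] * norms[j])
            angles.append(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if n_skipped:
        warnings.warn(f"{n_skipped} centroid pairs skipped (zero centroid)")
    if not angles:
        return float("nan")
    mean = float(np.mean(angles))
    return float(np.degrees(mean)) if degrees else mean


def dimensionality(responses) -> float:
    """Participation ratio of the KC covariance spectrum.

    ``dim = (sum lambda_i)^2 / sum lambda_i^2`` over the eigenvalues of the
    covariance of KC activity across odor(-trial) samples: 1 when all
    samples lie on a line through the mean, k for isotropic spread in k
    dimensions.  NaN when the covariance vanishes.  Computed from singular
    values of the centered sample matrix (no n_kc x n_kc matrix is formed).
    """
    if isinstance(responses, ResponseTensor):
        samples = responses.odor_means()
    else:
        samples = np.asarray(responses, dtype=float)
        if samples.ndim == 3:
            samples = samples.mean(axis=2)
    if samples.shape[1] < 2:
        raise ValueError("need at least two samples")
    centered = samples - samples.mean(axis=1, keepdims=True)
    s = np.linalg.svd(centered, compute_uv=False)
    lam = s**2  # proportional to covariance eigenvalues; scale cancels
    total = lam.sum()
    if total <= 0:
        return float("nan")
    return float(total**2 / (lam**2).sum())


def silent_fraction(rates: np.ndarray) -> float:
    """Fraction of KCs with zero total activity (undefined metrics)."""
    r = _odor_rates(rates)
    return float((r.sum(axis=1) == 0).mean())


def ablate_top(
    responses,
    metric_values: np.ndarray,
    fraction: float,
    replacement: str = "silent",
) -> np.ndarray:
    """Replace the top-fraction KCs by a metric with useless KCs.

    The ``ceil(fraction * n_kc)`` KCs with the highest metric values are
    replaced (undefined/NaN entries rank last; ties break by KC index).
    ``replacement="silent"`` zeroes them; ``"uniform"`` sets each replaced
    KC's response to its own mean activity on every odor-trial, preserving
    its total activity (and hence the coding level under dense coding).
    Returns a modified copy of the (n_kc, n_odor[, n_trials]) array.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    if replacement not in ("silent", "uniform"):
        raise ValueError("replacement must be 'silent' or 'uniform'")
    y = (responses.y if isinstance(responses, ResponseTensor) else np.asarray(responses)).copy()
    metric = np.asarray(metric_values, dtype=float)
    if metric.shape[0] != y.shape[0]:
        raise ValueError("metric_values must align with KCs")
    n_top = int(np.ceil(fraction * y.shape[0]))
    key = np.where(np.isnan(metric), -np.inf, metric)
    # stable sort descending on value, ascending on index for ties
    order = np.lexsort((np.arange(len(key)), -key))
    top = order[:n_top]
    if replacement == "silent":
        y[top] = 0.0
    else:
        flat_means = y[top].reshape(n_top, -1).mean(axis=1)
        y[top] = flat_means.reshape((n_top,) + (1,) * (y.ndim - 1))
    return y
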