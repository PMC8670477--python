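"""Synthetic odor panels: PN firing rates, trial noise, valences, odor groups.

The stimulus world of the model is a matrix of projection-neuron (PN) firing
rates, one row per PN (24 olfactory channels by default) and one column per
odor.  Panels can be generated from parametric per-PN marginals (each PN's
responses across odors are i.i.d. draws from that PN's own tuning
distribution), bootstrapped from an existing matrix such as one derived from
real recordings, or given group structure to emulate chemical classes of
odors.  Trial-to-trial variability is multiplicative-CV Gaussian noise,
rectified at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OdorPanel",
    "NoiseModel",
    "MarginalParams",
    "default_marginals",
    "generate_base_panel",
    "resample_panel_from_matrix",
    "orn_to_pn",
    "make_trials",
    "assign_valences",
    "make_grouped_panel",
    "load_panel_csv",
]

DEFAULT_N_PN = 24


@dataclass
class OdorPanel:
    """PN-by-odor firing-rate matrix with optional per-odor group labels.

    Attributes
    ----------
    rates
        Array of shape ``(n_pn, n_odor)``, nonnegative firing rates (spikes/s).
    pn_ids, odor_ids
        Row / column identifiers.
    group
        Optional per-odor categorical label (a surrogate for odor chemical
        class).
    """

    rates: np.ndarray
    pn_ids: list[str] = field(default_factory=list)
    odor_ids: list[str] = field(default_factory=list)
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be a 2-D (n_pn x n_odor) matrix")
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be nonnegative")
        if not self.pn_ids:
            self.pn_ids = [f"PN{i}" for i in range(self.rates.shape[0])]
        if not self.odor_ids:
            self.odor_ids = [f"odor{i}" for i in range(self.rates.shape[1])]
        if len(self.pn_ids) != self.rates.shape[0]:
            raise ValueError("pn_ids length does not match rates")
        if len(self.odor_ids) != self.rates.shape[1]:
            raise ValueError("odor_ids length does not match rates")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape[0] != self.rates.shape[1]:
                raise ValueError("group labels must align with odors")

    @property
    def n_pn(self) -> int:
        return self.rates.shape[0]

    @property
    def n_odor(self) -> int:
        return self.rates.shape[1]

    def subset(self, odor_idx: Sequence[int] | np.ndarray) -> "OdorPanel":
        """Panel restricted to a subset of odor columns."""
        odor_idx = np.asarray(odor_idx, dtype=int)
        return OdorPanel(
            rates=self.rates[:, odor_idx],
            pn_ids=list(self.pn_ids),
            odor_ids=[self.odor_ids[i] for i in odor_idx],
            group=None if self.group is None else self.group[odor_idx],
        )

    def to_csv(self, path: str | Path, group_path: str | Path | None = None) -> None:
        """Write rates as CSV (rows = PNs, columns = odors); groups separately."""
        df = pd.DataFrame(self.rates, index=self.pn_ids, columns=self.odor_ids)
        df.to_csv(path, index_label="pn_id")
        if group_path is not None:
            if self.group is None:
                raise ValueError("panel has no group labels to write")
            pd.DataFrame({"odor_id": self.odor_ids, "group": self.group}).to_csv(
                group_path, index=False
            )


def load_panel_csv(path: str | Path, group_path: str | Path | None = None) -> OdorPanel:
    """Load an :class:`OdorPanel` from CSV (rows = PNs, columns = odors).

    Accepts any user matrix in this dialect, e.g. PN responses derived from
    published receptor recordings.
    """
    df = pd.read_csv(path, index_col=0)
    group = None
    odor_ids = [str(c) for c in df.columns]
    if group_path is not None:
        gdf = pd.read_csv(group_path)
        gmap = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1]))
        group = np.array([gmap[o] for o in odor_ids])
    return OdorPanel(
        rates=df.to_numpy(dtype=float),
        pn_ids=[str(i) for i in df.index],
        odor_ids=odor_ids,
        group=group,
    )


@dataclass
class NoiseModel:
    """Trial-to-trial PN noise: Gaussian with per-PN coefficient of variation.

    ``scale`` is a global multiplier on all CVs (0.5 / 1 / 2 correspond to
    half, the measured, and double the measured noise level).
    """

    cv: np.ndarray | float = 0.25
    scale: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.cv) < 0):
            raise ValueError("cv must be nonnegative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def cv_vector(self, n_pn: int) -> np.ndarray:
        cv = np.asarray(self.cv, dtype=float)
        if cv.ndim == 0:
            return np.full(n_pn, float(cv))
        if cv.shape[0] != n_pn:
            raise ValueError("cv vector length must equal n_pn")
        return cv


@dataclass
class MarginalParams:
    """Per-PN zero-inflated log-normal tuning marginal.

    Each PN responds to an odor with probability ``p_respond``; a nonzero
    response amplitude is log-normal with parameters ``mu_log`` (log spikes/s)
    and ``sigma_log``.  This reproduces sparse, heavy-tailed PN tuning.
    """

    p_respond: np.ndarray
    mu_log: np.ndarray
    sigma_log: np.ndarray

    def __post_init__(self) -> None:
        self.p_respond = np.atleast_1d(np.asarray(self.p_respond, dtype=float))
        self.mu_log = np.atleast_1d(np.asarray(self.mu_log, dtype=float))
        self.sigma_log = np.atleast_1d(np.asarray(self.sigma_log, dtype=float))
        if not (self.p_respond.shape == self.mu_log.shape == self.sigma_log.shape):
            raise ValueError("marginal parameter arrays must share a shape")
        if np.any((self.p_respond < 0) | (self.p_respond > 1)):
            raise ValueError("p_respond must lie in [0, 1]")
        if np.any(self.sigma_log < 0):
            raise ValueError("sigma_log must be nonnegative")

    @property
    def n_pn(self) -> int:
        return self.p_respond.shape[0]

    def mean(self) -> np.ndarray:
        """Analytic mean rate per PN (zero-inflation times log-normal mean)."""
        return self.p_respond * np.exp(self.mu_log + 0.5 * self.sigma_log**2)


def default_marginals(n_pn: int = DEFAULT_N_PN, rng_seed: int = 0) -> MarginalParams:
    """Heterogeneous per-channel receptor (ORN) tuning marginals.

    Response probabilities spread over [0.2, 0.95] and log-median rates
    around ~40 spikes/s with a heavy tail — sparse, skewed receptor tuning.
    Panels built from these are passed through the saturating
    :func:`orn_to_pn` transform by default, which compresses the tail the
    way antennal-lobe gain control does.
    """
    rng = np.random.default_rng(rng_seed)
    p = rng.uniform(0.2, 0.95, size=n_pn)
    mu = rng.normal(np.log(40.0), 0.5, size=n_pn)
    sigma = np.full(n_pn, 0.6)
    return MarginalParams(p_respond=p, mu_log=mu, sigma_log=sigma)


def _sample_marginal(
    marg: MarginalParams, n_odor: int, rng: np.random.Generator
) -> np.ndarray:
    amp = rng.lognormal(
        mean=marg.mu_log[:, None],
        sigma=marg.sigma_log[:, None],
        size=(marg.n_pn, n_odor),
    )
    responds = rng.random((marg.n_pn, n_odor)) < marg.p_respond[:, None]
    return np.where(responds, amp, 0.0)


def generate_base_panel(
    n_odor: int,
    n_pn: int = DEFAULT_N_PN,
    marginals: MarginalParams | None = None,
    rng_seed: int = 0,
    transform: bool = True,
) -> OdorPanel:
    """Generate a synthetic panel: each channel's responses across odors are
    i.i.d. draws from that channel's marginal, independent across channels.

    By default the draws are treated as receptor (ORN) rates and passed
    through the saturating :func:`orn_to_pn` transform, as PN activity is a
    saturating function of receptor activity; ``transform=False`` uses the
    marginal draws as PN rates directly.
    """
    if n_odor < 2:
        raise ValueError("n_odor must be >= 2")
    if n_pn < 1:
        raise ValueError("n_pn must be >= 1")
    if marginals is None:
        marginals = default_marginals(n_pn, rng_seed=rng_seed)
    if marginals.n_pn != n_pn:
        raise ValueError("marginals do not match n_pn")
    rng = np.random.default_rng(rng_seed)
    rates = _sample_marginal(marginals, n_odor, rng)
    if transform:
        rates = orn_to_pn(rates)
    return OdorPanel(rates=rates)


def resample_panel_from_matrix(
    base: OdorPanel, n_odor: int, rng_seed: int = 0
) -> OdorPanel:
    """Bootstrap a new panel: each PN's row is resampled (with replacement)
    from that PN's responses in ``base``, independently across PNs.

    This is how a small recorded odor set is expanded into an arbitrarily
    large stimulus world while preserving each PN's marginal tuning.
    """
    if base.n_odor < 1:
        raise ValueError("base panel is empty")
    rng = np.random.default_rng(rng_seed)
    cols = rng.integers(0, base.n_odor, size=(base.n_pn, n_odor))
    rates = base.rates[np.arange(base.n_pn)[:, None], cols]
    return OdorPanel(rates=rates, pn_ids=list(base.pn_ids))


def orn_to_pn(
    orn: np.ndarray,
    rmax: float = 165.0,
    sigma: float = 12.0,
    exponent: float = 1.5,
    lateral_weight: float = 0.05,
) -> np.ndarray:
    """Saturating divisive normalization from ORN to PN firing rates.

    ``pn_i = rmax * orn_i^m / (sigma^m + orn_i^m + (s * sum_k orn_k)^m)``,
    the standard antennal-lobe lateral-inhibition transform: a power
    nonlinearity on the cell's own channel, divisively normalized by a
    semi-saturation constant plus a scaled pool over all channels.

    Parameters follow the conventional ranges (ceiling ``rmax`` spikes/s,
    semi-saturation ``sigma``, exponent ``m`` = 1.5, pool weight ``s``).
    ORN input along axis 0 (channels); any trailing axes are odors.
    """
    orn = np.asarray(orn, dtype=float)
    if np.any(orn < 0):
        raise ValueError("ORN rates must be nonnegative")
    own = orn**exponent
    pool = (lateral_weight * orn.sum(axis=0, keepdims=True)) ** exponent
    return rmax * own / (sigma**exponent + own + pool)


def make_trials(
    panel: OdorPanel,
    noise: NoiseModel | None = None,
    n_trials: int = 1,
    rng_seed: int = 0,
) -> np.ndarray:
    """Noisy trials of each odor: ``max(0, rate + N(0, scale*cv_i*rate))``.

    Returns an array of shape ``(n_pn, n_odor, n_trials)``.  Noise is
    multiplicative in the coefficient-of-variation sense (sd proportional to
    the mean rate), rectified at zero because rates are nonnegative.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(rng_seed)
    cv = noise.cv_vector(panel.n_pn)
    sd = noise.scale * cv[:, None, None] * panel.rates[:, :, None]
    draws = rng.normal(0.0, 1.0, size=(panel.n_pn, panel.n_odor, n_trials))
    return np.maximum(0.0, panel.rates[:, :, None] + sd * draws)


def assign_valences(
    odor_ids: Sequence[str] | int, rng_seed: int = 0
) -> np.ndarray:
    """Randomly assign half the odors to reward and half to punishment.

    Returns a boolean array, ``True`` = rewarded.  For an odd count the
    rewarded class gets the extra odor; the assignment is then permuted.
    """
    n = odor_ids if isinstance(odor_ids, int) else len(odor_ids)
    if n < 2:
        raise ValueError("need at least two odors to assign valences")
    labels = np.zeros(n, dtype=bool)
    labels[: (n + 1) // 2] = True
    rng = np.random.default_rng(rng_seed)
    return rng.permutation(labels)


def make_grouped_panel(
    n_groups: int,
    odors_per_group: int,
    within_group_correlation: float = 0.5,
    n_pn: int = DEFAULT_N_PN,
    marginals: MarginalParams | None = None,
    rng_seed: int = 0,
) -> OdorPanel:
    """Panel with odor "chemical-group" structure.

    Each group has a group-level PN response vector g (a draw from the
    marginals); each odor in the group mixes that vector with an independent
    odor-level draw: ``rate = rho * g + (1 - rho) * independent``.  At rho=0
    groups are pure labels; as rho→1 odors within a group become identical.
    Groups are exchangeable.
    """
    rho = within_group_correlation
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if not (0 <= rho < 1):
        raise ValueError("within_group_correlation must lie in [0, 1)")
    if marginals is None:
        marginals = default_marginals(n_pn, rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    group_vecs = orn_to_pn(_sample_marginal(marginals, n_groups, rng))
    n_odor = n_groups * odors_per_group
    indiv = orn_to_pn(_sample_marginal(marginals, n_odor, rng))
    group_idx = np.repeat(np.arange(n_groups), odors_per_group)
    rates = rho * group_vecs[:, group_idx] + (1 - rho) * indiv
    labels = np.array([f"G{g}" for g in group_idx])
    return OdorPanel(rates=rates, group=labels)
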