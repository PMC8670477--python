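"""Associative memory at the KC→MBON synapse: depression learning + softmax.

Two mushroom-body output neurons (MBONs) drive "approach" and "avoid".
Training pairs each odor with reward or punishment; KCs active during a
rewarded odor depress their synapses onto the avoid MBON (and vice versa)
by exponential decay, v <- v * exp(-eta * y).  Depression only — weights
never grow.  The decision is a probabilistic softmax over the two MBON
drives with gain c; accuracy is scored on unseen noisy trials of the
trained odors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .network import ResponseTensor

__all__ = [
    "MBONWeights",
    "TaskResult",
    "train",
    "decide",
    "evaluate",
    "best_learning_rate",
]


#: MBON drive unit, as a fraction of the expected total KC activity per
#: presentation.  Sets where the softmax gain axis lands: with c = 10 a
#: well-trained sparse network decides near-deterministically, with c = 1
#: decisions are appreciably stochastic, and c -> 0 is indifferent.
DRIVE_SCALE = 0.15


@dataclass
class MBONWeights:
    """Per-KC synaptic weights onto the approach and avoid MBONs.

    ``y_scale`` is the fixed drive normalization of the trained network
    (``DRIVE_SCALE`` times the mean total KC activity per training
    presentation).  It is a per-network constant, *not* a per-trial one:
    normalizing each trial separately would erase the differences in
    decision margin that distinguish networks with few vs many informative
    KCs.
    """

    v_approach: np.ndarray
    v_avoid: np.ndarray
    y_scale: float = 1.0

    def __post_init__(self) -> None:
        self.v_approach = np.asarray(self.v_approach, dtype=float)
        self.v_avoid = np.asarray(self.v_avoid, dtype=float)
        if self.v_approach.shape != self.v_avoid.shape:
            raise ValueError("MBON weight vectors must share a shape")
        if np.any(self.v_approach < 0) or np.any(self.v_avoid < 0):
            raise ValueError("MBON weights must be nonnegative")
        if self.y_scale <= 0:
            raise ValueError("y_scale must be positive")


@dataclass
class TaskResult:
    """Classification outcome: overall accuracy and per-odor correct rate."""

    accuracy: float
    per_odor: np.ndarray
    meta: dict

    def row(self, **extra) -> dict:
        """Tidy results row (model/seed/condition columns supplied by caller)."""
        return {"accuracy": self.accuracy, **self.meta, **extra}


def train(
    responses_train: ResponseTensor | np.ndarray,
    valences: np.ndarray,
    eta: float = 0.05,
    v_init: float = 1.0,
    rng_seed: int = 0,
    y_scale: float | None = None,
) -> MBONWeights:
    """Depress wrong-valence MBON synapses over all training presentations.

    For every odor-trial presentation, each KC j updates its synapse onto
    the *wrong* MBON (avoid for rewarded odors, approach for punished) as
    ``v_j <- v_j * exp(-eta * y_j)``.  The exponential updates commute, so
    presentation order (seeded shuffle in the sequential reading) cannot
    change the result; the closed-form product is computed directly.

    ``y_scale`` fixes the network's drive unit for the readout; when None
    it is measured from the training activity itself.  When several model
    variants are compared on one task, pass them a common scale so their
    decision margins are expressed in the same units.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    y = responses_train.y if isinstance(responses_train, ResponseTensor) else np.asarray(responses_train)
    if y.ndim == 2:
        y = y[:, :, None]
    valences = np.asarray(valences, dtype=bool)
    if valences.shape[0] != y.shape[1]:
        raise ValueError("one valence per trained odor is required")
    # total drive of each KC summed over rewarded / punished presentations
    drive_rewarded = y[:, valences, :].sum(axis=(1, 2))
    drive_punished = y[:, ~valences, :].sum(axis=(1, 2))
    if y_scale is None:
        y_scale = DRIVE_SCALE * float(y.sum(axis=0).mean())
    return MBONWeights(
        v_approach=v_init * np.exp(-eta * drive_punished),
        v_avoid=v_init * np.exp(-eta * drive_rewarded),
        y_scale=max(float(y_scale), 1e-300),
    )


def _mbon_drives(mbon: MBONWeights, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MBON drives ``sum_j v_k,j * y_j`` in the network's fixed drive unit."""
    y = np.asarray(y, dtype=float)
    flat = y.reshape(y.shape[0], -1) if y.ndim > 1 else y[:, None]
    m_app = (mbon.v_approach @ flat) / mbon.y_scale
    m_avo = (mbon.v_avoid @ flat) / mbon.y_scale
    return m_app, m_avo


def decide(
    mbon: MBONWeights,
    y: np.ndarray,
    c: float = 10.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Probability of choosing "avoid" for KC response vector(s) ``y``.

    P(avoid) = exp(c*m_avoid) / (exp(c*m_avoid) + exp(c*m_approach)),
    computed overflow-safely as a logistic of c*(m_avoid - m_approach),
    with the MBON drives in the trained network's fixed drive unit
    (:class:`MBONWeights`).  On that scale c = 10 is near-deterministic
    for a well-trained sparse network, c = 1 appreciably stochastic and
    c -> 0 indifferent; an untrained (or silent) response gives exactly
    0.5.  With a generator supplied, returns sampled binary actions
    instead (1 = avoid).
    """
    if c <= 0:
        raise ValueError("softmax gain c must be positive")
    m_app, m_avo = _mbon_drives(mbon, np.asarray(y, dtype=float))
    p_avoid = expit(c * (m_avo - m_app))
    if rng is not None:
        return (rng.random(p_avoid.shape) < p_avoid).astype(int)
    return p_avoid


def evaluate(
    responses_test: ResponseTensor | np.ndarray,
    mbon: MBONWeights,
    valences: np.ndarray,
    c: float = 10.0,
    sampled: bool = False,
    rng_seed: int = 0,
) -> TaskResult:
    """Score classification of unseen noisy odor trials.

    Accuracy is the mean over odors and test trials of the probability
    assigned to the correct action (avoid for punished, approach for
    rewarded); in ``sampled`` mode, binary decisions are drawn instead.
    """
    y = responses_test.y if isinstance(responses_test, ResponseTensor) else np.asarray(responses_test)
    if y.ndim == 2:
        y = y[:, :, None]
    n_kc, n_odor, n_trials = y.shape
    valences = np.asarray(valences, dtype=bool)
    if valences.shape[0] != n_odor:
        raise ValueError("one valence per test odor is required")
    p_avoid = decide(mbon, y, c=c).reshape(n_odor, n_trials)
    if sampled:
        rng = np.random.default_rng(rng_seed)
        action_avoid = rng.random(p_avoid.shape) < p_avoid
        correct = np.where(valences[:, None], ~action_avoid, action_avoid).astype(float)
    else:
        correct = np.where(valences[:, None], 1.0 - p_avoid, p_avoid)
    per_odor = correct.mean(axis=1)
    return TaskResult(
        accuracy=float(correct.mean()),
        per_odor=per_odor,
        meta={"c": c, "n_odor": n_odor, "n_test_trials": n_trials},
    )


def best_learning_rate(
    spec,
    panel,
    eta_grid,
    seeds,
    **run_kwargs,
) -> float:
    """Learning rate maximizing mean validation accuracy over seeds.

    Runs the full task pipeline (sample, calibrate, compensate, train,
    score) for every eta in the grid; ties break toward the smaller eta.
    """
    from .experiments import run_single  # local import: pipeline lives there

    eta_grid = list(eta_grid)
    if not eta_grid:
        raise ValueError("eta_grid must be nonempty")
    means = []
    for eta in eta_grid:
        accs = [
            run_single(spec, panel=panel, seed=s, eta=eta, **run_kwargs)["accuracy"]
            for s in seeds
        ]
        means.append(np.mean(accs))
    means = np.asarray(means)
    order = np.argsort(eta_grid, kind="stable")
    best = order[np.argmax(means[order])]  # scan in increasing eta; ties -> smaller
    return float(eta_grid[int(best)])
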