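"""Kenyon-cell population model: sampling, responses, coding-level calibration.

Each of ``n_kc`` Kenyon cells (KCs) receives excitatory input from a random
subset of N projection neurons (PNs) with per-connection weights w, global
inhibition from the APL interneuron with weight alpha, and a spiking
threshold theta.  The response to PN activity x is rectified-linear:

    e_j = sum_i w_ji x_i                 (excitatory drive)
    A   = sum_j e_j                      (pseudofeedforward APL activity)
    y_j = max(0, e_j - alpha_j A - theta_j)

APL inhibition is "pseudofeedforward": instead of simulating recurrent
KC<->APL dynamics in time, APL's activity is taken to be the summed
(unthresholded) excitatory drive of all KCs.

Eight base model regimes arise by fixing or varying each of {w, N, theta}
across KCs.  Thresholds and inhibition are calibrated by bisection on global
multipliers so that without inhibition 20% of KCs respond per odor and with
inhibition 10% do ("coding level" 0.1), mirroring the experimental finding
that blocking inhibition roughly doubles the responsive fraction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ParamDistributions",
    "ModelSpec",
    "KCPopulation",
    "ResponseTensor",
    "CalibrationError",
    "sample_population",
    "kc_response",
    "coding_level",
    "calibrate",
    "BASE_MODEL_SPECS",
]

DEFAULT_N_KC = 2000


@dataclass
class ParamDistributions:
    """Families of the experimentally measured KC parameter distributions.

    w (connection strength, EPSP amplitude in mV) is log-normal; N (number of
    PN inputs, "claws") and theta (spiking threshold minus rest, mV) are
    Gaussian.  Exact fit parameters are configurable; defaults keep the
    stated families with claw count mean 6 and moderate dispersion.
    """

    w_mu_log: float = 0.0          # log mV; overall scale is calibrated away
    w_sigma_log: float = 0.8
    n_mean: float = 6.0
    n_sd: float = 2.0
    n_min: int = 1
    n_max: int = 12
    theta_mean: float = 10.0       # mV above rest
    theta_cv: float = 0.25

    @property
    def w_mean(self) -> float:
        return float(np.exp(self.w_mu_log + 0.5 * self.w_sigma_log**2))

    def sample_n(self, size: int, rng: np.random.Generator) -> np.ndarray:
        n = np.rint(rng.normal(self.n_mean, self.n_sd, size=size)).astype(int)
        return np.clip(n, self.n_min, self.n_max)

    def sample_theta(self, size: int, rng: np.random.Generator) -> np.ndarray:
        sd = self.theta_cv * self.theta_mean
        theta = rng.normal(self.theta_mean, sd, size=size)
        # truncate at a small positive floor; thresholds must be positive
        while np.any(theta <= 0):
            bad = theta <= 0
            theta[bad] = rng.normal(self.theta_mean, sd, size=int(bad.sum()))
        return theta

    def sample_w(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(self.w_mu_log, self.w_sigma_log, size=size)


@dataclass
class ModelSpec:
    """Which parameters vary across KCs and which compensation is active."""

    variable_w: bool = False
    variable_N: bool = False
    variable_theta: bool = False
    compensation: str = "none"  # none | act_indep_w | homeo_w | homeo_alpha |
    #                             homeo_theta | homeo_theta_prob
    coding_level: float = 0.1
    coding_level_no_inhibition: float = 0.2
    inhibition_on: bool = True
    n_kc: int = DEFAULT_N_KC
    n_claws_fixed: int = 6

    _COMP_MODES = (
        "none",
        "act_indep_w",
        "homeo_w",
        "homeo_alpha",
        "homeo_theta",
        "homeo_theta_prob",
    )

    def __post_init__(self) -> None:
        if not (0 < self.coding_level <= 1):
            raise ValueError("coding_level must lie in (0, 1]")
        if self.inhibition_on and not (
            self.coding_level <= self.coding_level_no_inhibition <= 1
        ):
            raise ValueError(
                "need coding_level <= coding_level_no_inhibition <= 1"
            )
        if self.compensation not in self._COMP_MODES:
            raise ValueError(f"unknown compensation mode {self.compensation!r}")

    @property
    def n_variable(self) -> int:
        return sum([self.variable_w, self.variable_N, self.variable_theta])

    @property
    def name(self) -> str:
        if self.compensation != "none":
            return self.compensation
        if self.n_variable == 0:
            return "homogeneous"
        if self.n_variable == 3:
            return "random"
        parts = [
            p
            for p, v in (
                ("w", self.variable_w),
                ("N", self.variable_N),
                ("theta", self.variable_theta),
            )
            if v
        ]
        return "var_" + "+".join(parts)


def _base_specs() -> dict[str, ModelSpec]:
    out = {}
    for vw in (False, True):
        for vn in (False, True):
            for vt in (False, True):
                s = ModelSpec(variable_w=vw, variable_N=vn, variable_theta=vt)
                out[s.name] = s
    return out


#: The eight fixed/variable regimes, keyed by name ("homogeneous" ... "random").
BASE_MODEL_SPECS: dict[str, ModelSpec] = _base_specs()


class CalibrationError(RuntimeError):
    """Raised when the bisection bracket for a coding-level target fails."""


@dataclass
class KCPopulation:
    """A sampled KC population as dense index/weight arrays.

    ``pn_index[j]`` holds the PN indices of KC j's inputs (padded with -1 up
    to the max claw count); ``weights[j]`` the matching connection weights
    (0 on padding).  ``W`` materializes the dense n_kc x n_pn weight matrix.
    """

    pn_index: np.ndarray          # (n_kc, max_claws) int, -1 padding
    weights: np.ndarray           # (n_kc, max_claws) float, 0 on padding
    theta: np.ndarray             # (n_kc,)
    alpha: np.ndarray             # (n_kc,)
    n_pn: int
    meta: dict = field(default_factory=dict)

    @property
    def n_kc(self) -> int:
        return self.theta.shape[0]

    @property
    def claw_counts(self) -> np.ndarray:
        """Number of PN inputs (N) per KC."""
        return (self.pn_index >= 0).sum(axis=1)

    @property
    def mean_w(self) -> np.ndarray:
        """Mean connection weight per KC over its actual connections."""
        n = np.maximum(self.claw_counts, 1)
        return self.weights.sum(axis=1) / n

    @property
    def W(self) -> np.ndarray:
        """Dense (n_kc, n_pn) weight matrix."""
        W = np.zeros((self.n_kc, self.n_pn))
        rows = np.repeat(np.arange(self.n_kc), self.pn_index.shape[1])
        cols = self.pn_index.ravel()
        ok = cols >= 0
        W[rows[ok], cols[ok]] = self.weights.ravel()[ok]
        return W

    def copy(self) -> "KCPopulation":
        return KCPopulation(
            pn_index=self.pn_index.copy(),
            weights=self.weights.copy(),
            theta=self.theta.copy(),
            alpha=self.alpha.copy(),
            n_pn=self.n_pn,
            meta=dict(self.meta),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_pn": self.n_pn,
            "theta": self.theta.tolist(),
            "alpha": self.alpha.tolist(),
            "connections": [
                [
                    [int(i), float(w)]
                    for i, w in zip(row_i, row_w)
                    if i >= 0
                ]
                for row_i, row_w in zip(self.pn_index, self.weights)
            ],
            "meta": {k: v for k, v in self.meta.items() if _jsonable(v)},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "KCPopulation":
        payload = json.loads(Path(path).read_text())
        conns = payload["connections"]
        max_claws = max((len(c) for c in conns), default=1)
        n_kc = len(conns)
        pn_index = np.full((n_kc, max_claws), -1, dtype=int)
        weights = np.zeros((n_kc, max_claws))
        for j, c in enumerate(conns):
            for k, (i, w) in enumerate(c):
                pn_index[j, k] = i
                weights[j, k] = w
        return cls(
            pn_index=pn_index,
            weights=weights,
            theta=np.asarray(payload["theta"], dtype=float),
            alpha=np.asarray(payload["alpha"], dtype=float),
            n_pn=int(payload["n_pn"]),
            meta=payload.get("meta", {}),
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass
class ResponseTensor:
    """Rectified KC activities, shape ``(n_kc, n_odor, n_trials)``."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim == 2:
            self.y = self.y[:, :, None]
        if self.y.ndim != 3:
            raise ValueError("response tensor must be (n_kc, n_odor, n_trials)")

    @property
    def n_kc(self) -> int:
        return self.y.shape[0]

    @property
    def n_odor(self) -> int:
        return self.y.shape[1]

    @property
    def n_trials(self) -> int:
        return self.y.shape[2]

    def odor_means(self) -> np.ndarray:
        """Trial-averaged response per KC per odor, shape (n_kc, n_odor)."""
        return self.y.mean(axis=2)

    def flat(self) -> np.ndarray:
        """(n_kc, n_odor*n_trials) view of the samples."""
        return self.y.reshape(self.n_kc, -1)


def sample_population(
    spec: ModelSpec,
    dists: ParamDistributions | None = None,
    n_pn: int = 24,
    rng_seed: int = 0,
) -> KCPopulation:
    """Sample a KC population under the given fixed/variable regime.

    Fixed parameters take N = ``spec.n_claws_fixed`` claws, w and theta the
    means of their distributions; variable parameters are i.i.d. draws.  Each
    KC's PN subset is drawn uniformly without replacement.
    """
    if dists is None:
        dists = ParamDistributions()
    rng = np.random.default_rng(rng_seed)
    n_kc = spec.n_kc

    if spec.variable_N:
        N = dists.sample_n(n_kc, rng)
    else:
        N = np.full(n_kc, spec.n_claws_fixed, dtype=int)
    if np.max(N) > n_pn:
        raise ValueError("a KC cannot have more claws than there are PNs")

    max_claws = int(np.max(N))
    pn_index = np.full((n_kc, max_claws), -1, dtype=int)
    for j in range(n_kc):
        pn_index[j, : N[j]] = rng.choice(n_pn, size=N[j], replace=False)
    mask = pn_index >= 0

    if spec.variable_w:
        weights = dists.sample_w((n_kc, max_claws), rng)
    else:
        weights = np.full((n_kc, max_claws), dists.w_mean)
    weights = np.where(mask, weights, 0.0)

    if spec.variable_theta:
        theta = dists.sample_theta(n_kc, rng)
    else:
        theta = np.full(n_kc, dists.theta_mean)

    # untuned inhibition is uniform; 1/n_kc puts alpha*A on the scale of e_j
    alpha = np.full(n_kc, 1.0 / n_kc)

    return KCPopulation(
        pn_index=pn_index,
        weights=weights,
        theta=theta,
        alpha=alpha,
        n_pn=n_pn,
        meta={"spec": asdict(spec), "seed": rng_seed},
    )


def _as_samples(pn_activity: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Flatten PN activity to (n_pn, n_samples); remember trailing shape."""
    x = np.asarray(pn_activity, dtype=float)
    if x.ndim == 1:
        return x[:, None], ()
    return x.reshape(x.shape[0], -1), x.shape[1:]


def kc_response(
    pop: KCPopulation,
    pn_activity: np.ndarray,
    inhibition_on: bool = True,
) -> ResponseTensor:
    """KC responses to PN activity (vector, matrix or trial tensor).

    Implements the rectified-linear rule with pseudofeedforward APL
    inhibition (see module docstring).
    """
    x, trail = _as_samples(pn_activity)
    if np.any(x < 0):
        raise ValueError("PN activity must be nonnegative")
    if x.shape[0] != pop.n_pn:
        raise ValueError(
            f"PN dimension mismatch: population expects {pop.n_pn}, "
            f"got {x.shape[0]}"
        )
    e = pop.W @ x                       # (n_kc, n_samples)
    if inhibition_on:
        A = e.sum(axis=0, keepdims=True)
        net = e - pop.alpha[:, None] * A - pop.theta[:, None]
    else:
        net = e - pop.theta[:, None]
    y = np.maximum(0.0, net)
    if len(trail) == 0:
        y = y[:, :, None]
    elif len(trail) == 1:
        y = y[:, :, None]
        y = y.reshape(pop.n_kc, trail[0], 1)
    else:
        y = y.reshape(pop.n_kc, *trail)
    return ResponseTensor(y=y)


def coding_level(responses: ResponseTensor | np.ndarray) -> float:
    """Mean fraction of KCs active (y > 0) per odor-trial."""
    y = responses.y if isinstance(responses, ResponseTensor) else np.asarray(responses)
    if y.size == 0:
        raise ValueError("empty response tensor")
    return float((y > 0).mean())


def _bisect_multiplier(
    f, target: float, tol: float, lo: float = 2.0**-10, hi: float = 2.0**10,
    max_iter: int = 200,
) -> float:
    """Find m with f(m) = target for f monotone nonincreasing in m."""
    f_lo, f_hi = f(lo), f(hi)
    if f_lo < target - tol:
        raise CalibrationError(
            f"target {target} unreachable: even multiplier {lo} gives {f_lo:.4f}"
        )
    if f_hi > target + tol:
        raise CalibrationError(
            f"target {target} unreachable: even multiplier {hi} gives {f_hi:.4f}"
        )
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection over the dyadic range
        val = f(mid)
        if abs(val - target) <= tol:
            return mid
        if val > target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    return float(np.sqrt(lo * hi))


def calibrate(
    pop: KCPopulation,
    pn_activity: np.ndarray,
    spec: ModelSpec,
    tol: float = 0.005,
    stages: tuple[str, ...] = ("theta", "alpha"),
) -> KCPopulation:
    """Scale thresholds and inhibition to the target coding levels.

    Stage "theta" finds a single global multiplier on all thresholds by
    bisection so that, with inhibition off, the coding level equals
    ``spec.coding_level_no_inhibition``.  Stage "alpha" (skipped when
    ``spec.inhibition_on`` is false) finds a global multiplier on all
    inhibitory weights so that the coding level with inhibition equals
    ``spec.coding_level``.  Relative inter-KC variability of theta and alpha
    is preserved.  Calibration uses the provided (by default noiseless)
    PN activity for determinism.  ``stages`` restricts which multipliers are
    re-fit (after homeostatic tuning only the inhibition stage is re-run, so
    tuned thresholds are left alone).
    """
    pop = pop.copy()
    x, _ = _as_samples(pn_activity)

    e = pop.W @ x

    if "theta" in stages:
        theta0 = pop.theta.copy()

        def cl_theta(m: float) -> float:
            return float((e - m * theta0[:, None] > 0).mean())

        target1 = (
            spec.coding_level_no_inhibition if spec.inhibition_on else spec.coding_level
        )
        m_theta = _bisect_multiplier(cl_theta, target1, tol)
        pop.theta = m_theta * theta0

    if spec.inhibition_on and "alpha" in stages:
        A = e.sum(axis=0, keepdims=True)
        alpha0 = pop.alpha.copy()
        net0 = e - pop.theta[:, None]

        def cl_alpha(m: float) -> float:
            return float((net0 - m * alpha0[:, None] * A > 0).mean())

        m_alpha = _bisect_multiplier(cl_alpha, spec.coding_level, tol)
        pop.alpha = m_alpha * alpha0
    pop.meta["calibrated"] = True
    return pop
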