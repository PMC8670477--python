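"""Compensatory variability: mechanisms that equalize average KC activity.

Inter-KC variability in weights (w), claw counts (N) and thresholds (theta)
makes average activity unequal across KCs, which degrades sparse-coding
memory.  Two families of compensation are implemented:

* **Activity-independent**: weights are drawn from a conditional
  distribution P(w | N, theta) whose components realize w ∝ theta and
  w ∝ 1/N, while the pooled mixture over the whole population is constrained
  to match the unconditional (experimental-family) log-normal P(w).

* **Activity-dependent (homeostatic)**: each KC nudges one parameter —
  excitatory weight scale, inhibitory weight, or threshold — until its mean
  activity over a tuning odor set lies within a tolerance (±6% by default)
  of a common set point A0.  A variant equalizes response *probability*
  rather than mean activity by tuning thresholds.

These rules are fixed-point constructions, not models of a biological
mechanism; they exist to create the parameter correlations while keeping
marginal distributions realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    KCPopulation,
    ModelSpec,
    ParamDistributions,
    calibrate,
    kc_response,
)

__all__ = [
    "HomeostasisConfig",
    "ConditionalWeightSampler",
    "ConvergenceError",
    "FittingError",
    "fit_conditional_weight_components",
    "apply_activity_independent",
    "homeostatic_tune",
    "tune_threshold_response_prob",
    "negative_alpha_fraction",
]


class ConvergenceError(RuntimeError):
    """Homeostatic tuning failed to bring all KCs within tolerance."""

    def __init__(self, msg: str, fraction_out: float):
        super().__init__(msg)
        self.fraction_out = fraction_out


class FittingError(RuntimeError):
    """Conditional-weight mixture fit failed."""


@dataclass
class HomeostasisConfig:
    """Configuration for activity-dependent tuning.

    ``target`` selects the tuned parameter.  ``A0`` is the per-KC set point
    (mean activity in response units, or response probability for the
    ``theta_prob`` variant); ``None`` means use the population mean of the
    untuned calibrated network.  ``tolerance`` is relative (±6% of A0).
    ``eta_tune`` is the update gain; ``None`` selects a per-target default
    (0.1 for the multiplicative w rule, 1.0 for the additive theta/alpha and
    the multiplicative theta_prob rules, all stable for the rectified-linear
    response).
    """

    target: str = "w"  # w | alpha | theta | theta_prob
    A0: float | None = None
    tolerance: float = 0.06
    eta_tune: float | None = None
    max_iters: int = 500
    allow_negative_alpha: bool = True
    recalibrate: bool = True
    raise_on_failure: bool = True

    _TARGETS = ("w", "alpha", "theta", "theta_prob")

    def __post_init__(self) -> None:
        if self.target not in self._TARGETS:
            raise ValueError(f"unknown tuning target {self.target!r}")
        if not (0 < self.tolerance < 1):
            raise ValueError("tolerance must lie in (0, 1)")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")

    @property
    def gain(self) -> float:
        if self.eta_tune is not None:
            return self.eta_tune
        return 0.1 if self.target == "w" else 1.0


@dataclass
class ConditionalWeightSampler:
    """Log-normal components of P(w | N, theta) pooling to a target P(w).

    Component for claw count N and threshold bin centered at theta_b is
    log-normal with median ``kappa * theta_b / N`` and shared ``sigma_log``;
    kappa and sigma_log are fitted so that the mixture over the joint
    (N, theta) population reproduces the unconditional log-normal target
    (moment matching in log space).
    """

    kappa: float
    sigma_log: float
    theta_edges: np.ndarray          # bin edges over theta
    theta_centers: np.ndarray
    n_values: np.ndarray             # admissible claw counts
    dists: ParamDistributions = field(repr=False, default=None)

    def component_median(self, N: np.ndarray | int, theta: np.ndarray | float) -> np.ndarray:
        """Median of the w component for each (N, theta), theta snapped to
        its bin center (nearest bin outside the fitted grid)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        idx = np.clip(
            np.searchsorted(self.theta_edges, theta) - 1,
            0,
            len(self.theta_centers) - 1,
        )
        theta_b = self.theta_centers[idx]
        return self.kappa * theta_b / np.atleast_1d(N)

    def sample(
        self, N: np.ndarray, theta: np.ndarray, size_per_kc: np.ndarray,
        rng: np.random.Generator,
    ) -> list[np.ndarray]:
        """Draw each KC's weights from its (N, theta) component."""
        med = self.component_median(N, theta)
        return [
            m * rng.lognormal(0.0, self.sigma_log, size=int(k))
            for m, k in zip(med, size_per_kc)
        ]


def fit_conditional_weight_components(
    dists: ParamDistributions,
    n_grid: tuple[int, int] = (12, 20),
    n_pop: int = 200_000,
    rng_seed: int = 0,
) -> ConditionalWeightSampler:
    """Fit the compensatory conditional sampler P(w | N, theta).

    A large (N, theta) population is drawn from ``dists``; theta is binned
    into ``n_grid[1]`` quantile bins.  With component medians
    ``kappa * theta_bin / N`` and shared log-sd ``sigma_log``, the pooled
    log-weight over the population has mean ``log kappa + E[log theta_b] -
    E[log N]`` and variance ``Var[log theta_b - log N] + sigma_log**2``;
    moment matching against the target log-normal (``w_mu_log``,
    ``w_sigma_log``) gives kappa and sigma_log in closed form.
    """
    rng = np.random.default_rng(rng_seed)
    N = dists.sample_n(n_pop, rng).astype(float)
    theta = dists.sample_theta(n_pop, rng)

    n_theta_bins = int(n_grid[1])
    qs = np.linspace(0, 1, n_theta_bins + 1)
    edges = np.quantile(theta, qs)
    edges[0], edges[-1] = 0.0, np.inf
    centers_idx = np.clip(np.searchsorted(edges, theta) - 1, 0, n_theta_bins - 1)
    # bin centers = within-bin geometric means (natural for log-space matching)
    centers = np.array(
        [
            np.exp(np.mean(np.log(theta[centers_idx == b])))
            if np.any(centers_idx == b)
            else np.nan
            for b in range(n_theta_bins)
        ]
    )
    log_ratio = np.log(centers[centers_idx]) - np.log(N)

    target_mu, target_sigma = dists.w_mu_log, dists.w_sigma_log
    resid_var = target_sigma**2 - np.var(log_ratio)
    if resid_var <= 0:
        raise FittingError(
            "target P(w) is narrower than the spread induced by N and theta "
            f"(residual log-variance {resid_var:.4f} <= 0)"
        )
    kappa = float(np.exp(target_mu - np.mean(log_ratio)))
    sigma_log = float(np.sqrt(resid_var))
    return ConditionalWeightSampler(
        kappa=kappa,
        sigma_log=sigma_log,
        theta_edges=edges,
        theta_centers=centers,
        n_values=np.arange(dists.n_min, dists.n_max + 1),
        dists=dists,
    )


def apply_activity_independent(
    pop: KCPopulation,
    sampler: ConditionalWeightSampler,
    rng_seed: int = 0,
) -> KCPopulation:
    """Redraw each KC's weights from its (N, theta) compensatory component.

    Claw counts and thresholds are untouched, and so is the connectivity
    topology; only the weight magnitudes change.  Across the population the
    construction yields corr(mean w, N) < 0 and corr(mean w, theta) > 0.
    """
    pop = pop.copy()
    rng = np.random.default_rng(rng_seed)
    N = pop.claw_counts
    draws = sampler.sample(N, pop.theta, N, rng)
    weights = np.zeros_like(pop.weights)
    for j, d in enumerate(draws):
        weights[j, : len(d)] = d
    pop.weights = weights
    pop.meta["compensation"] = "act_indep_w"
    return pop


def _mean_activity(pop: KCPopulation, x: np.ndarray, inhibition_on: bool) -> np.ndarray:
    """Per-KC mean activity over tuning samples (n_pn x n_samples input)."""
    return kc_response(pop, x, inhibition_on=inhibition_on).flat().mean(axis=1)


def homeostatic_tune(
    pop: KCPopulation,
    tuning_activity: np.ndarray,
    cfg: HomeostasisConfig,
    spec: ModelSpec | None = None,
) -> KCPopulation:
    """Activity-dependent tuning of one parameter per KC.

    Iterates until every KC's mean activity over the tuning odors is within
    ``±tolerance*A0`` of the set point A0, updating the targeted parameter:

    * ``w``      — multiplicative: scale KC j's weights by (A0/Ābar_j)^eta
    * ``theta``  — additive: theta_j += eta * (Ābar_j - A0)
    * ``alpha``  — additive: alpha_j += eta * (Ābar_j - A0) / <A>, where <A>
      is the mean APL activity over tuning samples (normalizes the update to
      inhibition units); clamped at zero unless negative alpha is allowed

    Totally silent KCs under the multiplicative w rule get a fixed boost
    (x(1+eta)) until activity appears.

    Equal mean activity and the population coding-level target jointly
    determine the set point, so when ``cfg.A0`` is not given the set point
    starts at the untuned population mean and an outer loop rescales it
    until the coding level on the tuning odors is back at
    ``spec.coding_level`` (within the calibration tolerance).  Untargeted
    parameters are never altered.  Records a per-iteration convergence
    trace in ``pop.meta["tuning_trace"]``.
    """
    if cfg.target == "theta_prob":
        raise ValueError("use tune_threshold_response_prob for the theta_prob variant")
    if spec is None:
        spec = ModelSpec(**pop.meta["spec"]) if "spec" in pop.meta else ModelSpec()
    x = np.asarray(tuning_activity, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = x.reshape(x.shape[0], -1)

    pop = pop.copy()
    if cfg.A0 is None:
        A0 = float(_mean_activity(pop, x, spec.inhibition_on).mean())
    else:
        A0 = float(cfg.A0)
    if A0 <= 0:
        raise ValueError("tuning set point A0 must be positive")

    cl_tol = 0.005
    max_outer = 12 if (cfg.recalibrate and cfg.A0 is None) else 1
    frac_out = 0.0
    for _ in range(max_outer):
        pop, frac_out = _tune_loop(pop, x, cfg, spec, A0)
        cl = float(
            (kc_response(pop, x, inhibition_on=spec.inhibition_on).flat() > 0).mean()
        )
        if max_outer == 1 or abs(cl - spec.coding_level) <= cl_tol:
            break
        A0 *= spec.coding_level / cl
    pop.meta["compensation"] = f"homeo_{cfg.target}"
    pop.meta["A0"] = A0
    pop.meta["tuning_coding_level"] = cl
    if frac_out > 0 and cfg.raise_on_failure:
        raise ConvergenceError(
            f"homeostatic tuning ({cfg.target}) did not converge: "
            f"{100 * frac_out:.1f}% of KCs outside ±{100 * cfg.tolerance:.0f}% of A0",
            fraction_out=frac_out,
        )
    return pop


def _bisect_decreasing(f, lo: np.ndarray, hi: np.ndarray, target: float,
                       n_iter: int = 50) -> np.ndarray:
    """Vectorized per-KC bisection of a monotone-nonincreasing f to target."""
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        too_high = val > target
        lo = np.where(too_high, mid, lo)
        hi = np.where(too_high, hi, mid)
    return 0.5 * (lo + hi)


def _tune_loop(
    pop: KCPopulation,
    x: np.ndarray,
    cfg: HomeostasisConfig,
    spec: ModelSpec,
    A0: float,
) -> tuple[KCPopulation, float]:
    """Drive the per-KC raise/lower rule to its fixed point.

    Because APL inhibition is pseudofeedforward, a KC's mean activity is
    monotone in its own tuned parameter (decreasing in theta and alpha,
    increasing in its weight scale), so the overly-active-lower /
    inactive-raise dynamics converge to the unique per-KC root, found here
    by bisection.  For the weight target the shared APL term couples KCs,
    so the per-KC solve alternates with an update of APL activity until the
    joint fixed point is reached.  Returns (pop, fraction of KCs left
    outside tolerance) — nonzero only when a constraint (non-negative
    inhibition, a KC with zero drive) makes the set point unreachable.
    """
    e = pop.W @ x                            # (n_kc, n_samples)
    A_s = e.sum(axis=0) if spec.inhibition_on else np.zeros(x.shape[1])
    trace: list[float] = []

    if cfg.target == "theta":
        net0 = e - pop.alpha[:, None] * A_s
        lo = net0.mean(axis=1) - A0          # relu(z) >= z bounds f from below
        hi = net0.max(axis=1)
        pop.theta = _bisect_decreasing(
            lambda th: np.maximum(0.0, net0 - th[:, None]).mean(axis=1), lo, hi, A0
        )
    elif cfg.target == "alpha":
        drive = e - pop.theta[:, None]
        A_mean = max(A_s.mean(), 1e-300)
        lo = (drive.mean(axis=1) - A0) / A_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            hi = np.max(np.where(A_s > 0, drive / A_s, 0.0), axis=1)
        hi = np.maximum(hi, lo + 1e-12)
        pop.alpha = _bisect_decreasing(
            lambda al: np.maximum(0.0, drive - al[:, None] * A_s).mean(axis=1),
            lo, hi, A0,
        )
        if not cfg.allow_negative_alpha:
            pop.alpha = np.maximum(pop.alpha, 0.0)
    elif cfg.target == "w":
        scale = np.ones(pop.n_kc)
        offs = pop.theta
        # the shared APL term couples KCs; a handful of alternations between
        # the per-KC solve and the APL update reaches the joint fixed point
        # well inside the activity tolerance
        for _ in range(min(cfg.max_iters, 30)):
            A_s = (scale[:, None] * e).sum(axis=0) if spec.inhibition_on else 0.0
            inh = pop.alpha[:, None] * A_s if spec.inhibition_on else 0.0

            def abar_of(s):
                return np.maximum(0.0, s[:, None] * e - inh - offs[:, None]).mean(axis=1)

            hi = np.maximum(2.0 * scale, 2.0)
            for _ in range(40):  # grow until every KC can reach the set point
                short = abar_of(hi) < A0
                if not short.any():
                    break
                hi = np.where(short, hi * 2, hi)
            lo_s = np.zeros(pop.n_kc)
            for _ in range(30):  # increasing function: standard bisection
                mid = 0.5 * (lo_s + hi)
                below = abar_of(mid) < A0
                lo_s = np.where(below, mid, lo_s)
                hi = np.where(below, hi, mid)
            new_scale = 0.5 * (lo_s + hi)
            step = float(
                np.max(
                    np.abs(
                        np.log(
                            np.maximum(new_scale, 1e-12) / np.maximum(scale, 1e-12)
                        )
                    )
                )
            )
            scale = new_scale
            trace.append(step)
            if step < 1e-3 * cfg.tolerance / 0.06:
                break
        pop.weights = pop.weights * scale[:, None]

    abar = _mean_activity(pop, x, spec.inhibition_on)
    dev = np.abs(abar - A0) / A0
    trace.append(float(dev.max()))
    frac_out = float((dev > cfg.tolerance).mean())
    pop.meta["tuning_trace"] = trace
    pop.meta["tuning_fraction_out"] = frac_out
    return pop, frac_out


def tune_threshold_response_prob(
    pop: KCPopulation,
    tuning_activity: np.ndarray,
    cfg: HomeostasisConfig | None = None,
    spec: ModelSpec | None = None,
) -> KCPopulation:
    """Equalize per-KC response *probability* by tuning thresholds.

    Overly responsive KCs raise theta, silent KCs lower it until they
    respond.  Because inhibition is pseudofeedforward, a KC's response
    probability depends only on its own threshold, so the raise/lower rule
    is driven straight to its fixed point: each threshold settles between
    the order statistics of that KC's net drive across the tuning
    odor-trials, leaving every response probability within one sample flip
    (1/n_samples) of the target.
    """
    if cfg is None:
        cfg = HomeostasisConfig(target="theta_prob")
    if cfg.target != "theta_prob":
        raise ValueError("cfg.target must be 'theta_prob'")
    if spec is None:
        spec = ModelSpec(**pop.meta["spec"]) if "spec" in pop.meta else ModelSpec()
    x = np.asarray(tuning_activity, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = x.reshape(x.shape[0], -1)
    n_samples = x.shape[1]

    pop = pop.copy()
    target = spec.coding_level if cfg.A0 is None else float(cfg.A0)
    e = pop.W @ x
    net0 = e
    if spec.inhibition_on:
        net0 = e - pop.alpha[:, None] * e.sum(axis=0, keepdims=True)
    k = int(np.clip(round(target * n_samples), 1, n_samples - 1))
    srt = np.sort(net0, axis=1)[:, ::-1]
    pop.theta = 0.5 * (srt[:, k - 1] + srt[:, k])
    prob = (kc_response(pop, x, inhibition_on=spec.inhibition_on).flat() > 0).mean(
        axis=1
    )
    tol = max(cfg.tolerance * target, 1.0 / n_samples + 1e-12)
    frac_out = float((np.abs(prob - target) > tol).mean())
    pop.meta["tuning_trace"] = [float(np.abs(prob - target).max())]
    pop.meta["tuning_fraction_out"] = frac_out
    if frac_out > 0 and cfg.raise_on_failure:
        raise ConvergenceError(
            f"response-probability tuning left {100 * frac_out:.1f}% of KCs "
            "outside tolerance (tied net drives)",
            fraction_out=frac_out,
        )
    pop.meta["compensation"] = "homeo_theta_prob"
    return pop


def negative_alpha_fraction(pop: KCPopulation) -> float:
    """Fraction of KCs whose tuned inhibitory weight is negative."""
    return float((pop.alpha < 0).mean())
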