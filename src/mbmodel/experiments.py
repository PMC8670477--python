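"""Experiment orchestration: model grids, seeds, and comparison statistics.

Every experiment is a loop over model variants and seeded instances.  One
"instance" fixes the odor panel, the valence assignment, the PN–KC
connectivity and the trial noise; model variants within an instance share
these seeds, so paired (signed-rank) comparisons are valid wherever the
regimes allow identical connectivity.  Per-run seeds fan out from a master
seed through a counter-based scheme (`numpy` SeedSequence), so any run can
be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as met
from .compensation import (
    HomeostasisConfig,
    apply_activity_independent,
    fit_conditional_weight_components,
    homeostatic_tune,
    tune_threshold_response_prob,
)
from .memory import DRIVE_SCALE, evaluate, train
from .network import (
    BASE_MODEL_SPECS,
    KCPopulation,
    ModelSpec,
    ParamDistributions,
    calibrate,
    coding_level,
    kc_response,
    sample_population,
)
from .odors import NoiseModel, OdorPanel, assign_valences, generate_base_panel, make_trials
from .stats import pairwise_tests

__all__ = [
    "ExperimentConfig",
    "child_seeds",
    "compensated_spec",
    "COMPENSATION_MODEL_NAMES",
    "build_population",
    "run_single",
    "run_model_comparison",
    "run_compensation_comparison",
    "run_novel_environment",
    "run_sweep",
    "compare_models",
    "inhibition_only_coding_level",
]

COMPENSATION_MODEL_NAMES = (
    "homogeneous",
    "random",
    "act_indep_w",
    "homeo_w",
    "homeo_alpha",
    "homeo_theta",
)


@dataclass
class ExperimentConfig:
    """Shared knobs for the experiment drivers.

    Defaults mirror the reference conditions: 2000 KCs, 24 PNs, coding level
    0.1 (0.2 without inhibition), 100 odors, softmax gain c = 10, measured
    noise level, 15 training and 10 test trials per odor.
    """

    n_seeds: int = 30
    n_odor: int = 100
    n_kc: int = 2000
    n_pn: int = 24
    coding_level: float = 0.1
    coding_level_no_inhibition: float = 0.2
    inhibition_on: bool = True
    eta: float = 1e-4
    c: float = 10.0
    noise_scale: float = 1.0
    n_train_trials: int = 15
    n_test_trials: int = 10
    n_tuning_trials: int = 5
    #: raise on homeostatic non-convergence; off for small tuning odor sets,
    #: where a KC whose PNs are silent across the tuning odors is untunable
    strict_tuning: bool = True
    dists: ParamDistributions = field(default_factory=ParamDistributions)
    master_seed: int = 0

    def spec_overrides(self) -> dict:
        return dict(
            coding_level=self.coding_level,
            coding_level_no_inhibition=self.coding_level_no_inhibition,
            inhibition_on=self.inhibition_on,
            n_kc=self.n_kc,
        )


def child_seeds(master_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """Deterministic per-run seeds derived from a master seed.

    Counter-based: run i of stream s always receives the same seed whatever
    the execution order.  Seeds stay below 2**31.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(stream,))
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31)


def compensated_spec(mode: str, **overrides) -> ModelSpec:
    """ModelSpec for a named model, compensated modes fully variable."""
    if mode == "homogeneous":
        return ModelSpec(**overrides)
    if mode == "random":
        return ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, **overrides
        )
    return ModelSpec(
        variable_w=True,
        variable_N=True,
        variable_theta=True,
        compensation=mode,
        **overrides,
    )


_SAMPLER_CACHE: dict[tuple, object] = {}


def _weight_sampler(dists: ParamDistributions):
    key = (
        dists.w_mu_log, dists.w_sigma_log, dists.n_mean, dists.n_sd,
        dists.n_min, dists.n_max, dists.theta_mean, dists.theta_cv,
    )
    if key not in _SAMPLER_CACHE:
        _SAMPLER_CACHE[key] = fit_conditional_weight_components(dists)
    return _SAMPLER_CACHE[key]


def build_population(
    spec: ModelSpec,
    calibration_activity: np.ndarray,
    seed: int,
    dists: ParamDistributions | None = None,
    n_pn: int = 24,
    tuning_activity: np.ndarray | None = None,
    strict_tuning: bool = True,
) -> KCPopulation:
    """Sample, compensate and calibrate a KC population for one instance.

    Activity-independent compensation redraws weights before calibration;
    activity-dependent (homeostatic) modes calibrate on the (noiseless)
    calibration odors and then tune on ``tuning_activity`` — noisy trials
    of the tuning odors in the drivers, so the plasticity experiences the
    same trial statistics the task does.
    """
    if dists is None:
        dists = ParamDistributions()
    if tuning_activity is None:
        tuning_activity = calibration_activity
    pop = sample_population(spec, dists, n_pn=n_pn, rng_seed=seed)
    if spec.compensation == "act_indep_w":
        pop = apply_activity_independent(pop, _weight_sampler(dists), rng_seed=seed)
    pop = calibrate(pop, calibration_activity, spec)
    if spec.compensation in ("homeo_w", "homeo_alpha", "homeo_theta"):
        cfg = HomeostasisConfig(
            target=spec.compensation.removeprefix("homeo_"),
            raise_on_failure=strict_tuning,
        )
        pop = homeostatic_tune(pop, tuning_activity, cfg, spec=spec)
    elif spec.compensation == "homeo_theta_prob":
        cfg = HomeostasisConfig(
            target="theta_prob", raise_on_failure=strict_tuning
        )
        pop = tune_threshold_response_prob(pop, tuning_activity, cfg, spec=spec)
    return pop


_DRIVE_SCALE_CACHE: dict[tuple, float] = {}


def reference_drive_scale(
    panel: OdorPanel,
    spec: ModelSpec,
    seed: int,
    dists: ParamDistributions | None = None,
) -> float:
    """Common drive unit for all model variants of one task instance.

    The simulation's activity units are arbitrary (they follow the weight
    distribution's scale and the calibrated thresholds), so the softmax gain
    needs a fixed reference.  The unit is ``DRIVE_SCALE`` times the expected
    total KC activity per odor of the calibrated *homogeneous* network at
    the standard sparse operating point (coding level 0.1, halved by
    inhibition) on the noiseless panel.  It is independent both of the
    variant being evaluated and of the coding-level regime under test, so
    all models and regimes are compared in one set of units, as if measured
    physically: dense-coding networks, whose total activity is far larger,
    correspondingly produce larger MBON drives.
    """
    key = (
        seed,
        spec.n_kc,
        spec.n_claws_fixed,
        panel.n_odor,
        hash(panel.rates.tobytes()),
    )
    if key not in _DRIVE_SCALE_CACHE:
        ref_spec = ModelSpec(
            n_kc=spec.n_kc,
            n_claws_fixed=spec.n_claws_fixed,
        )
        pop = sample_population(ref_spec, dists, n_pn=panel.n_pn, rng_seed=seed)
        pop = calibrate(pop, panel.rates, ref_spec)
        y = kc_response(pop, panel.rates, inhibition_on=ref_spec.inhibition_on)
        _DRIVE_SCALE_CACHE[key] = DRIVE_SCALE * float(y.flat().sum(axis=0).mean())
    return _DRIVE_SCALE_CACHE[key]


def run_single(
    spec: ModelSpec,
    seed: int,
    panel: OdorPanel | None = None,
    cfg: ExperimentConfig | None = None,
    eta: float | None = None,
    c: float | None = None,
    tuning_panel: OdorPanel | None = None,
    collect_metrics: bool = False,
    c_values: tuple[float, ...] | None = None,
) -> dict | list[dict]:
    """One full task run: build network, train on noisy trials, score.

    Sub-seeds for the odor panel, connectivity, valences and trial noise are
    derived from ``seed``; two runs with the same arguments are identical.
    Returns a tidy results row (or one row per gain when ``c_values`` is
    given — the network is built and trained once and only the softmax
    evaluation is repeated).
    """
    cfg = cfg or ExperimentConfig()
    eta = cfg.eta if eta is None else eta
    c = cfg.c if c is None else c
    sub = child_seeds(seed, 6, stream=7)
    if panel is None:
        panel = generate_base_panel(cfg.n_odor, cfg.n_pn, rng_seed=int(sub[0]))
    tuning = panel if tuning_panel is None else tuning_panel
    noise = NoiseModel(scale=cfg.noise_scale)

    tuning_trials = make_trials(
        tuning, noise, cfg.n_tuning_trials, rng_seed=int(sub[5])
    ).reshape(tuning.n_pn, -1)
    pop = build_population(
        spec,
        tuning.rates,
        seed=int(sub[1]),
        dists=cfg.dists,
        n_pn=panel.n_pn,
        tuning_activity=tuning_trials,
        strict_tuning=cfg.strict_tuning,
    )
    valences = assign_valences(panel.n_odor, rng_seed=int(sub[2]))

    x_train = make_trials(panel, noise, cfg.n_train_trials, rng_seed=int(sub[3]))
    y_train = kc_response(pop, x_train, inhibition_on=spec.inhibition_on)
    y_scale = reference_drive_scale(panel, spec, int(sub[1]), dists=cfg.dists)
    mbon = train(y_train, valences, eta=eta, y_scale=y_scale)

    x_test = make_trials(panel, noise, cfg.n_test_trials, rng_seed=int(sub[4]))
    y_test = kc_response(pop, x_test, inhibition_on=spec.inhibition_on)

    def make_row(c_value: float) -> dict:
        result = evaluate(y_test, mbon, valences, c=c_value)
        row = {
            "model": spec.name,
            "seed": seed,
            "n_odor": panel.n_odor,
            "eta": eta,
            "c": c_value,
            "coding_level_target": spec.coding_level,
            "accuracy": result.accuracy,
            "coding_level": coding_level(y_test),
        }
        if collect_metrics:
            rates = y_test.odor_means()
            ls = met.lifetime_sparseness(rates)
            silent = met.silent_fraction(rates)
            row["sparseness_sd"] = float(np.nanstd(ls))
            row["silent_fraction"] = silent
            row["sparse_085_1_fraction"] = float(
                np.nanmean((ls >= 0.85) & (ls <= 1.0 + 1e-12)) * (1 - silent)
            )
        return row

    if c_values is not None:
        return [make_row(cv) for cv in c_values]
    return make_row(c)


def run_model_comparison(
    cfg: ExperimentConfig | None = None,
    specs: dict[str, ModelSpec] | None = None,
    collect_metrics: bool = False,
) -> pd.DataFrame:
    """The eight fixed/variable regimes, one accuracy row per (model, seed).

    Matched models share odor, connectivity, valence and noise seeds within
    an instance.
    """
    cfg = cfg or ExperimentConfig()
    if specs is None:
        specs = {
            name: replace(s, **cfg.spec_overrides())
            for name, s in BASE_MODEL_SPECS.items()
        }
    seeds = child_seeds(cfg.master_seed, cfg.n_seeds, stream=1)
    rows = []
    for name, spec in specs.items():
        for s in seeds:
            try:
                rows.append(
                    run_single(spec, int(s), cfg=cfg, collect_metrics=collect_metrics)
                )
            except RuntimeError as err:  # calibration/convergence failure
                rows.append(
                    {"model": name, "seed": int(s), "error": str(err)}
                )
    return pd.DataFrame(rows)


def run_compensation_comparison(
    cfg: ExperimentConfig | None = None,
    c_values: tuple[float, ...] = (10.0, 1.0),
    model_names: tuple[str, ...] = COMPENSATION_MODEL_NAMES,
) -> pd.DataFrame:
    """Uncompensated extremes vs the four compensation mechanisms.

    Rows per (model, seed, c); networks are built once per (model, seed) and
    evaluated at each softmax gain.  Includes the SD of KC lifetime
    sparseness per run.
    """
    cfg = cfg or ExperimentConfig(n_seeds=20)
    seeds = child_seeds(cfg.master_seed, cfg.n_seeds, stream=2)
    rows = []
    for name in model_names:
        spec = compensated_spec(name, **cfg.spec_overrides())
        for s in seeds:
            try:
                rows.extend(
                    run_single(
                        spec, int(s), cfg=cfg, c_values=tuple(c_values),
                        collect_metrics=True,
                    )
                )
            except RuntimeError as err:
                rows.append({"model": name, "seed": int(s), "error": str(err)})
    return pd.DataFrame(rows)


def run_novel_environment(
    cfg: ExperimentConfig | None = None,
    model_names: tuple[str, ...] = COMPENSATION_MODEL_NAMES,
    n_groups: int = 4,
    odors_per_group: int = 15,
    within_group_correlation: float = 0.5,
) -> pd.DataFrame:
    """Tune on one odor group, train/test on the others (novel environment).

    For each held-out group G_i the model's parameters (calibration and any
    activity-dependent tuning) are set using only G_i's odors, then the task
    runs on the remaining groups' odors.  A matched familiar control tunes,
    trains and tests on those same remaining groups.  Rows per (model,
    group, condition, seed).
    """
    from .odors import make_grouped_panel

    cfg = cfg or ExperimentConfig(n_seeds=20)
    cfg = replace(cfg, strict_tuning=False)  # small tuning sets: KCs whose
    # PNs are silent across one odor group are untunable there
    seeds = child_seeds(cfg.master_seed, cfg.n_seeds, stream=3)
    rows = []
    for s in seeds:
        panel = make_grouped_panel(
            n_groups,
            odors_per_group,
            within_group_correlation,
            n_pn=cfg.n_pn,
            rng_seed=int(s),
        )
        group_labels = np.unique(panel.group)
        for name in model_names:
            spec = compensated_spec(name, **cfg.spec_overrides())
            for g in group_labels:
                tune_idx = np.flatnonzero(panel.group == g)
                task_idx = np.flatnonzero(panel.group != g)
                task_panel = panel.subset(task_idx)
                for condition, tune_panel in (
                    ("novel", panel.subset(tune_idx)),
                    ("familiar", task_panel),
                ):
                    try:
                        row = run_single(
                            spec,
                            int(s),
                            panel=task_panel,
                            cfg=cfg,
                            tuning_panel=tune_panel,
                        )
                    except RuntimeError as err:
                        row = {"model": name, "seed": int(s), "error": str(err)}
                    row.update({"group": str(g), "condition": condition})
                    rows.append(row)
    return pd.DataFrame(rows)


def run_sweep(
    axis: str,
    values,
    models: tuple[str, ...] = ("homogeneous", "random"),
    cfg: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Robustness sweep of one condition axis for selected models.

    ``axis`` is one of ``n_odor``, ``eta``, ``noise_scale``, ``c``,
    ``coding_level`` or ``n_claws`` (the identical-input variant raises the
    claw count toward all 24 PNs).  Dense-coding values (coding_level > 0.5)
    automatically switch inhibition off, since inhibition is constrained to
    halve the coding level.
    """
    cfg = cfg or ExperimentConfig(n_seeds=20)
    seeds = child_seeds(cfg.master_seed, cfg.n_seeds, stream=4)
    rows = []
    for value in values:
        run_cfg = cfg
        overrides = {}
        if axis == "n_odor":
            run_cfg = replace(cfg, n_odor=int(value))
        elif axis in ("eta", "noise_scale", "c"):
            run_cfg = replace(cfg, **{axis: float(value)})
        elif axis == "coding_level":
            inhibition = value <= 0.5
            run_cfg = replace(
                cfg,
                coding_level=value,
                coding_level_no_inhibition=min(2 * value, 1.0),
                inhibition_on=inhibition,
            )
        elif axis == "n_claws":
            overrides = {"n_claws_fixed": int(value)}
        else:
            raise ValueError(f"unknown sweep axis {axis!r}")
        for name in models:
            spec = compensated_spec(name, **run_cfg.spec_overrides(), **overrides)
            for s in seeds:
                try:
                    row = run_single(spec, int(s), cfg=run_cfg)
                except RuntimeError as err:
                    row = {"model": name, "seed": int(s), "error": str(err)}
                row[axis] = value
                rows.append(row)
    return pd.DataFrame(rows)


def compare_models(
    results: pd.DataFrame,
    value: str = "accuracy",
    group: str = "model",
    paired: bool = True,
) -> pd.DataFrame:
    """Pairwise rank tests with Holm correction over a tidy results table.

    For paired tests rows are aligned on the ``seed`` column.
    """
    groups = {}
    for name, sub in results.dropna(subset=[value]).groupby(group, sort=False):
        sub = sub.sort_values("seed") if "seed" in sub else sub
        groups[str(name)] = sub[value].to_numpy()
    return pairwise_tests(groups, paired=paired)


def inhibition_only_coding_level(
    seed: int,
    cfg: ExperimentConfig | None = None,
    n_odor: int = 20,
) -> dict:
    """Sparseness enforced by non-negative tuned inhibition alone.

    Thresholds are set to zero so that, without inhibition, nearly every KC
    responds to every odor; per-KC inhibitory weights are then tuned to
    equalize mean activity under the constraint alpha >= 0, with the global
    inhibition level calibrated to coding level 0.1.  Returns the coding
    level measured with the inhibition term removed — the diagnostic for
    whether realistic threshold-driven sparseness is compatible with
    non-negative compensatory inhibition.
    """
    cfg = cfg or ExperimentConfig(n_seeds=20, n_odor=n_odor)
    sub = child_seeds(seed, 3, stream=8)
    panel = generate_base_panel(cfg.n_odor, cfg.n_pn, rng_seed=int(sub[0]))
    spec = compensated_spec("homeo_alpha", **cfg.spec_overrides())
    pop = sample_population(spec, cfg.dists, n_pn=cfg.n_pn, rng_seed=int(sub[1]))
    pop.theta = np.zeros_like(pop.theta)  # sparseness from inhibition alone
    pop = calibrate(pop, panel.rates, spec, stages=("alpha",))
    hcfg = HomeostasisConfig(
        target="alpha", allow_negative_alpha=False, raise_on_failure=False
    )
    pop = homeostatic_tune(pop, panel.rates, hcfg, spec=spec)
    y_no_inh = kc_response(pop, panel.rates, inhibition_on=False)
    y_inh = kc_response(pop, panel.rates, inhibition_on=True)
    return {
        "seed": seed,
        "coding_level_no_inhibition": coding_level(y_no_inh),
        "coding_level_with_inhibition": coding_level(y_inh),
        "negative_alpha_fraction": float((pop.alpha < 0).mean()),
    }
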