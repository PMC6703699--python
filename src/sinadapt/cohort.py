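"""Synthetic observers and cohorts for parameter-recovery and model-selection
experiments.

Observed gains are the noise-free hidden state of a chosen generative model
plus i.i.d. Gaussian observation noise standing in for saccadic/measurement
variability (the latent learner itself stays noise-free).  Two-way and
global adaptation are emulated only through the learning-rate ranges and the
noise level: Two-way learning rates (single-error models) span 0.01-0.035
per trial, global ones 0.005-0.015, with more measurement noise in the
global condition.

Seeding: one master seed; per-observer child seeds are spawned from
``numpy.random.SeedSequence(master).spawn`` in a fixed participant-major,
frequency-minor order, so cohorts are reproducible and extensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .paradigm import SessionDesign, build_session, single_block_design
from .state_model import (
    GenerativeParams,
    ModelSpec,
    enumerate_model_specs,
    get_model_spec,
    is_stable,
    self_consistent_initial_gain,
    simulate,
)
from .state_fit import FitResult, fit_state_model, group_weights, selection_table

#: default observation-noise sd per adaptation type (gain units)
DEFAULT_SIGMA = {"two-way": 0.08, "global": 0.15}

#: per-participant jitter ranges for the generative truth, anchored to the
#: fitted single-error learning-rate ranges per adaptation type
DEFAULT_PARAM_RANGES = {
    "two-way": {"K": (0.01, 0.035), "A": (0.98, 1.0), "m": (-0.006, -0.002)},
    "global": {"K": (0.005, 0.015), "A": (0.98, 1.0), "m": (-0.006, -0.002)},
}


@dataclass(frozen=True)
class NoiseModel:
    """i.i.d. Gaussian observation noise on the gain."""

    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Reproducible description of a synthetic cohort.

    ``param_ranges`` maps parameter names to (lo, hi) uniform jitter ranges;
    parameters absent from the mapping keep the value in ``truth_params``.
    Each participant draws one parameter set, shared across frequencies."""

    truth_model: str = "KAm"
    truth_params: GenerativeParams = field(
        default_factory=lambda: GenerativeParams(K=0.02, A=0.99, m=-0.004)
    )
    param_ranges: dict[str, tuple[float, float]] | None = None
    frequencies: tuple[int, ...] = (6,)
    n_participants: int = 13
    sigma: float = DEFAULT_SIGMA["two-way"]
    adaptation_type: str = "two-way"
    pre_length: int = 75
    adapt_length: int = 384
    seed: int = 0
    #: for truth models without a free G, set the generating initial state to
    #: the self-consistent value of the first-five-trial estimation convention
    consistent_init: bool = True


@dataclass
class ObserverRun:
    participant: int
    frequency: int
    seed_entropy: tuple
    truth: GenerativeParams
    trials: pd.DataFrame  # includes latent x and observed g columns


@dataclass
class RecoveryReport:
    """Truth-vs-estimate comparison and selection outcome of one experiment."""

    config: CohortConfig
    runs: pd.DataFrame              #: one row per (participant, frequency)
    bias: dict[str, float]          #: mean(estimate - truth) per free param
    rmse: dict[str, float]
    coverage: dict[str, float]      #: 95% CI coverage rate per free param
    selection: pd.DataFrame | None  #: per-model weights (average column)
    group_weights: pd.Series | None
    winner_group: str | None
    n_nonconverged: int


def generate_observer(
    design: SessionDesign,
    spec: ModelSpec | str,
    params: GenerativeParams,
    noise: NoiseModel | float,
    seed,
) -> pd.DataFrame:
    """Simulate one observer: session trial table with latent state ``x``
    and noisy observed gain ``g``.

    Raises if the truth parameters are unstable (synthetic observers must
    come from a well-behaved learner)."""
    spec = get_model_spec(spec) if isinstance(spec, str) else spec
    params = params.constrained(spec)
    if not is_stable(params.K, params.A, params.D):
        raise ValueError("unstable truth parameters; refusing to generate")
    sigma = noise.sigma if isinstance(noise, NoiseModel) else float(noise)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    trials = build_session(design)
    x, _ = simulate(None, params, trials)
    rng = np.random.default_rng(seed)
    g = x + rng.normal(0.0, sigma, size=x.size) if sigma > 0 else x.copy()
    out = trials.copy()
    out["x"] = x
    out["g"] = g
    return out


def _draw_truth(base: GenerativeParams, ranges, rng) -> GenerativeParams:
    if not ranges:
        return base
    updates = {p: float(rng.uniform(lo, hi)) for p, (lo, hi) in ranges.items()}
    return replace(base, **updates)


def generate_cohort(config: CohortConfig) -> list[ObserverRun]:
    """Generate ``n_participants`` observers per frequency.

    Each participant has one truth parameter set (uniform jitter within
    ``param_ranges``) and one session per frequency; every observer gets a
    child seed spawned deterministically from the master seed."""
    spec = get_model_spec(config.truth_model)
    master = np.random.SeedSequence(config.seed)
    n_freq = len(config.frequencies)
    children = master.spawn(config.n_participants * (n_freq + 1))
    runs: list[ObserverRun] = []
    for i in range(config.n_participants):
        part_rng = np.random.default_rng(children[i * (n_freq + 1)])
        truth = _draw_truth(config.truth_params, config.param_ranges, part_rng).constrained(spec)
        for j, f in enumerate(config.frequencies):
            child = children[i * (n_freq + 1) + 1 + j]
            design = single_block_design(
                f,
                adaptation_type=config.adaptation_type,
                pre_length=config.pre_length,
                adapt_length=config.adapt_length,
            )
            run_truth = truth
            if config.consistent_init and not spec.free_G:
                s = build_session(design)["s"].to_numpy()
                run_truth = replace(truth, G=self_consistent_initial_gain(truth, s))
            trials = generate_observer(design, spec, run_truth, config.sigma, child)
            runs.append(
                ObserverRun(
                    participant=i + 1,
                    frequency=int(f),
                    seed_entropy=(child.entropy, *child.spawn_key),
                    truth=run_truth,
                    trials=trials,
                )
            )
    return runs


def recovery_experiment(
    config: CohortConfig,
    fit_specs: list[ModelSpec] | None = None,
    select: bool = True,
    **fit_kw,
) -> RecoveryReport:
    """End-to-end parameter-recovery and model-selection run.

    Generates the cohort, fits the truth model to every observer for the
    truth-vs-estimate comparison and (optionally) the whole model family for
    Akaike-weight selection.  Non-convergence is recorded per run, never
    raised."""
    truth_spec = get_model_spec(config.truth_model)
    runs = generate_cohort(config)
    records = []
    per_participant_fits: list[list[FitResult]] = []
    n_noncov = 0
    for run in runs:
        g = run.trials["g"].to_numpy()
        trials = run.trials
        if select:
            specs = fit_specs if fit_specs is not None else enumerate_model_specs()
            fits = []
            for sp in specs:
                try:
                    fits.append(fit_state_model(g, trials, sp, **fit_kw))
                except Exception:
                    n_noncov += 1
                    continue
            per_participant_fits.append(fits)
            truth_fit = next((f for f in fits if f.name == truth_spec.name), None)
            if truth_fit is None:
                truth_fit = fit_state_model(g, trials, truth_spec, **fit_kw)
        else:
            truth_fit = fit_state_model(g, trials, truth_spec, **fit_kw)
        if not truth_fit.converged:
            n_noncov += 1
        rec = {"participant": run.participant, "frequency": run.frequency,
               "converged": truth_fit.converged}
        est = truth_fit.params
        for p in truth_spec.free_names:
            truth_val = getattr(run.truth, p)
            est_val = getattr(est, p)
            lo, hi = truth_fit.ci95.get(p, (np.nan, np.nan))
            rec[f"{p}_truth"] = truth_val
            rec[f"{p}_est"] = est_val
            rec[f"{p}_lo"] = lo
            rec[f"{p}_hi"] = hi
            rec[f"{p}_covered"] = bool(lo <= truth_val <= hi) if np.isfinite(lo) else False
        records.append(rec)
    runs_df = pd.DataFrame(records)
    bias, rmse, coverage = {}, {}, {}
    for p in truth_spec.free_names:
        err = runs_df[f"{p}_est"] - runs_df[f"{p}_truth"]
        bias[p] = float(err.mean())
        rmse[p] = float(np.sqrt((err**2).mean()))
        coverage[p] = float(runs_df[f"{p}_covered"].mean())
    table = gw = winner = None
    if select and per_participant_fits:
        table = selection_table(per_participant_fits)
        gw = group_weights(table)
        winner = str(gw.idxmax())
    return RecoveryReport(
        config=config,
        runs=runs_df,
        bias=bias,
        rmse=rmse,
        coverage=coverage,
        selection=table,
        group_weights=gw,
        winner_group=winner,
        n_nonconverged=n_noncov,
    )
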