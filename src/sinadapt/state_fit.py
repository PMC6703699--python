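"""Nonlinear least-squares estimation of the generative learning parameters
and AIC-weight model selection over the 16-model family.

Each model is fit by minimizing the squared discrepancy between the observed
adaptation gain and the pure forward simulation of the hidden state driven by
the stimulus gain (no teacher forcing).  Multimodality — real when the distal
rate D is free — is handled with Latin-hypercube multi-start; no bounds are
imposed at the solution, only on the start sampling.  Confidence intervals
come from the Jacobian linearization at the optimum; models are ranked by
Akaike weights, ``w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .state_model import (
    DIVERGENCE_BOUND,
    PARAM_ORDER,
    _sensitivity_kernel,
    _simulate_kernel,
    GenerativeParams,
    ModelSpec,
    enumerate_model_specs,
    get_model_spec,
    initial_gain_estimate,
    simulate,
)

#: Latin-hypercube start-sampling ranges (never enforced at the solution)
DEFAULT_START_RANGES = {
    "K": (0.001, 0.3),
    "A": (0.9, 1.0),
    "m": (-0.02, 0.02),
    "D": (-0.3, 0.05),
    "G": (-0.5, 0.5),  # offset around the first-five-trials gain average
}


@dataclass
class FitResult:
    """Outcome of fitting one model spec to one gain series."""

    spec: ModelSpec
    params: GenerativeParams
    ci95: dict[str, tuple[float, float]]
    rss: float
    n_fit: int
    loglik: float
    aic: float
    predicted: np.ndarray
    converged: bool
    unstable: bool = False

    @property
    def name(self) -> str:
        return self.spec.name


class StateSpaceModel(BaseEstimator, RegressorMixin):
    """Least-squares fit of one state-equation learner.

    Parameters
    ----------
    model : str or ModelSpec
        Canonical model name (e.g. ``"KAmDG"``) or a spec.
    n_starts : int
        Latin-hypercube multi-start count (best residual kept).
    seed : int
        Seed for the start sampler.
    start_ranges : dict, optional
        Overrides of :data:`DEFAULT_START_RANGES`.
    init_window : int
        Trials averaged for the initial-state proxy (fixed G, and the start
        center when G is free).
    aicc : bool
        Use the small-sample corrected AIC instead of plain AIC.

    Attributes
    ----------
    params_ : GenerativeParams
    ci95_ : dict of free parameter -> (lo, hi)
    rss_, aic_, loglik_ : float
    predicted_ : ndarray
    converged_, unstable_ : bool
    """

    def __init__(self, model="KAmDG", n_starts=8, seed=0, start_ranges=None,
                 init_window=5, aicc=False, max_nfev=None):
        self.model = model
        self.n_starts = n_starts
        self.seed = seed
        self.start_ranges = start_ranges
        self.init_window = init_window
        self.aicc = aicc
        self.max_nfev = max_nfev

    def _spec(self) -> ModelSpec:
        return self.model if isinstance(self.model, ModelSpec) else get_model_spec(self.model)

    def fit(self, X: pd.DataFrame, y) -> "StateSpaceModel":
        spec = self._spec()
        y = np.asarray(y, dtype=float)
        s = np.asarray(X["s"], dtype=float)
        if s.size != y.size:
            raise ValueError("trial table and gain series are misaligned")
        g0 = initial_gain_estimate(y, self.init_window)
        free = spec.free_names
        k = len(free)
        if y.size <= k + 1:
            raise ValueError("fewer trials than parameters")

        free_idx = np.array([PARAM_ORDER.index(p) for p in free])
        base = np.array([np.nan, 1.0, 0.0, 0.0, g0])  # fixed-parameter values

        def full_vector(theta: np.ndarray) -> np.ndarray:
            vec = base.copy()
            vec[free_idx] = theta
            return vec

        def assemble(theta: np.ndarray) -> GenerativeParams:
            return GenerativeParams(*full_vector(theta))

        def residuals(theta: np.ndarray) -> np.ndarray:
            K, A, m, D, G = full_vector(theta)
            return y - _simulate_kernel(s, K, A, m, D, G, DIVERGENCE_BOUND)[0]

        def jacobian(theta: np.ndarray) -> np.ndarray:
            K, A, m, D, G = full_vector(theta)
            sens = _sensitivity_kernel(s, K, A, m, D, G, DIVERGENCE_BOUND)[1]
            return -sens[:, free_idx]

        ranges = dict(DEFAULT_START_RANGES)
        if self.start_ranges:
            ranges.update(self.start_ranges)
        sampler = qmc.LatinHypercube(d=k, seed=self.seed)
        unit = sampler.random(self.n_starts)
        lo = np.array([ranges[p][0] + (g0 if p == "G" else 0.0) for p in free])
        hi = np.array([ranges[p][1] + (g0 if p == "G" else 0.0) for p in free])
        starts = lo + unit * (hi - lo)

        best = None
        for theta0 in starts:
            try:
                res = least_squares(residuals, theta0, jac=jacobian, method="lm",
                                    xtol=1e-9, ftol=1e-9, max_nfev=self.max_nfev)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all optimizer starts failed")

        theta = best.x
        self.params_ = assemble(theta)
        x, unstable = simulate(None, self.params_, s)
        self.predicted_ = x
        self.unstable_ = bool(unstable)
        self.rss_ = float(2.0 * best.cost)
        n = y.size
        self.n_fit_ = int(n)
        rss = max(self.rss_, 1e-300)
        self.loglik_ = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
        k_aic = k + 1  # + Gaussian noise scale
        self.aic_ = n * np.log(rss / n) + 2.0 * k_aic
        if self.aicc and n - k_aic - 1 > 0:
            self.aic_ += 2.0 * k_aic * (k_aic + 1) / (n - k_aic - 1)
        self.converged_ = bool(best.success) and not self.unstable_
        self.ci95_ = self._confidence_intervals(best.jac, theta, free, n)
        return self

    @staticmethod
    def _confidence_intervals(jac, theta, free, n):
        k = theta.size
        dof = n - k
        JtJ = jac.T @ jac
        try:
            cov = np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            return {p: (np.nan, np.nan) for p in free}
        return {"_cov": cov, "_theta": dict(zip(free, theta)), "_dof": dof}

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        x, _ = simulate(None, self.params_, np.asarray(X["s"], dtype=float))
        return x


def fit_state_model(
    g, trials: pd.DataFrame, spec: ModelSpec | str, **kw
) -> FitResult:
    """Fit one model spec; returns estimates, 95% CIs (Jacobian
    linearization), RSS, log-likelihood, AIC and the predicted trajectory."""
    est = StateSpaceModel(model=spec, **kw).fit(trials, g)
    ci = confidence_intervals(est)
    return FitResult(
        spec=est._spec(),
        params=est.params_,
        ci95=ci,
        rss=est.rss_,
        n_fit=est.n_fit_,
        loglik=est.loglik_,
        aic=est.aic_,
        predicted=est.predicted_,
        converged=est.converged_,
        unstable=est.unstable_,
    )


def confidence_intervals(est: StateSpaceModel) -> dict[str, tuple[float, float]]:
    """95% linearization intervals for the free parameters of a fitted model.

    Intervals are ``theta +- t(0.975, n-k) * se`` with the standard errors
    from ``sigma^2 (J'J)^-1``; a rank-deficient Jacobian yields NaN intervals
    (parameter unidentifiable)."""
    info = est.ci95_
    if "_cov" not in info:
        return {p: (np.nan, np.nan) for p in est._spec().free_names}
    cov = info["_cov"]
    theta = info["_theta"]
    dof = info["_dof"]
    sigma2 = est.rss_ / dof
    tval = stats.t.ppf(0.975, dof)
    out = {}
    for i, p in enumerate(theta):
        var = sigma2 * cov[i, i]
        if not np.isfinite(var) or var < 0:
            out[p] = (np.nan, np.nan)
        else:
            se = np.sqrt(var)
            out[p] = (theta[p] - tval * se, theta[p] + tval * se)
    return out


def akaike_weights(fits: list[FitResult] | np.ndarray) -> np.ndarray:
    """Akaike weights across a model set fitted to the same series."""
    if len(fits) and isinstance(fits[0], FitResult):
        aic = np.array([f.aic for f in fits])
    else:
        aic = np.asarray(fits, dtype=float)
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def average_weights(per_participant: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Element-wise mean of per-participant weight vectors (sums stay 1)."""
    arr = np.asarray(per_participant, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array of per-participant weights")
    return arr.mean(axis=0)


def fit_all_models(
    g, trials: pd.DataFrame, specs: list[ModelSpec] | None = None, **kw
) -> list[FitResult]:
    """Fit every member of the model family (default: all 16) to one series."""
    specs = specs if specs is not None else enumerate_model_specs()
    return [fit_state_model(g, trials, spec, **kw) for spec in specs]


def selection_table(
    per_participant_fits: list[list[FitResult]],
    condition: dict | None = None,
) -> pd.DataFrame:
    """Per-model Akaike weights per participant plus their average.

    Rows are models (ordered family enumeration); one column per participant
    and an ``average`` column.  Optional condition labels are attached as
    DataFrame attrs."""
    names = [f.name for f in per_participant_fits[0]]
    groups = [f.spec.group for f in per_participant_fits[0]]
    data = {}
    weights = []
    for i, fits in enumerate(per_participant_fits):
        if [f.name for f in fits] != names:
            raise ValueError("participants were fitted with different model sets")
        w = akaike_weights(fits)
        weights.append(w)
        data[f"p{i + 1}"] = w
    data["average"] = average_weights(weights)
    table = pd.DataFrame(data, index=pd.Index(names, name="model"))
    table.insert(0, "group", groups)
    if condition:
        table.attrs.update(condition)
    return table


def best_model(table: pd.DataFrame) -> str:
    """Model with the highest average weight; ties broken by fewer free
    parameters, then lexicographic name."""
    w = table["average"]
    top = w[np.isclose(w, w.max())]
    names = sorted(top.index, key=lambda nm: (len(get_model_spec(nm).free_names), nm))
    return names[0]


def group_weights(table: pd.DataFrame) -> pd.Series:
    """Average weight per model group (I-IV), summed over member models."""
    return table.groupby("group")["average"].sum()
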