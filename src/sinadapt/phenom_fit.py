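"""Phenomenological description of the adaptation gain and Bayesian model
comparison.

The response to a sinusoidal disturbance is described by a lagged sinusoid
riding on an exponentially decaying baseline::

    g(n) = a * sin(omega * j(n) - phi) + B * exp(-lambda * n) + B0,
    omega = 2 * pi * nu / N,

where ``n`` counts trials from the start of the fitted segment (the
pre-adaptation block is included), ``j(n)`` counts trials from the onset of
the adaptation block and the sinusoidal term is active only from that onset,
``nu`` is the response frequency in cycles per block and ``N`` the adaptation
block length.

Fitting is Bayesian with a Gaussian likelihood whose noise scale sigma is
integrated out under a Jeffreys (1/sigma) prior, leaving a posterior
proportional to ``RSS(theta)**(-n/2)`` over the remaining parameters.  The
sinusoid is parameterized internally by its in-phase/quadrature components
(alpha, beta), which makes the model linear in (alpha, beta, B, B0); those
four coordinates are marginalized in closed form and the two nonlinear
parameters (nu, lambda) are handled on a grid.  Marginal likelihoods obtained
this way are exactly additive across the nested chain
full -> drift-only (a = 0) -> noise-only (block mean, matched variance),
and model evidence is reported in decibels, ``10*log10`` of the odds, with
3 db the conventional significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator, RegressorMixin

from .paradigm import (
    ADAPTATION,
    adaptation_block_length,
    adaptation_onset_index,
)

DB_PER_NAT = 10.0 / np.log(10.0)
#: nesting order of the model chain (higher = more parameters)
NESTED_MODELS = {"noise": 0, "drift": 1, "full": 2}


@dataclass(frozen=True)
class PhenomParams:
    """Parameters of the phenomenological gain curve."""

    a: float = 0.0       #: periodic amplitude (gain units)
    nu: float = 0.0      #: response frequency (cycles per block)
    phi: float = 0.0     #: lag of the periodic component (radians)
    B: float = 0.0       #: amplitude of the baseline decay (gain units)
    lam: float = 0.0     #: decay timescale (1/trials)
    B0: float = 0.0      #: baseline asymptote (gain units)

    def omega(self, N: int) -> float:
        """Angular frequency per trial for adaptation-block length N."""
        return 2.0 * np.pi * self.nu / N


@dataclass(frozen=True)
class PhenomPriors:
    """Uniform prior ranges.  The periodic component is parameterized by its
    in-phase/quadrature components, each flat on ``amp_range``; nu and lambda
    are flat on their ranges.  ``lam_range`` starts slightly above zero
    because at lambda = 0 the decay column is indistinguishable from the
    constant baseline."""

    amp_range: tuple[float, float] = (-2.0, 2.0)
    B_range: tuple[float, float] = (-2.0, 2.0)
    B0_range: tuple[float, float] = (-2.0, 2.0)
    nu_range: tuple[float, float] = (0.5, 30.0)
    lam_range: tuple[float, float] = (0.002, 0.5)


@dataclass(frozen=True)
class PosteriorSummary:
    """First two moments of the marginal posterior per parameter."""

    moments: dict[str, tuple[float, float]]  #: name -> (mean, variance)

    def mean(self, name: str) -> float:
        return self.moments[name][0]

    def sd(self, name: str) -> float:
        return float(np.sqrt(self.moments[name][1]))


@dataclass(frozen=True)
class EvidenceReport:
    """Log-odds (decibels) across the nested model chain; additive by
    construction: full-vs-noise = full-vs-drift + drift-vs-noise."""

    db_full_vs_drift: float
    db_drift_vs_noise: float

    @property
    def db_full_vs_noise(self) -> float:
        return self.db_full_vs_drift + self.db_drift_vs_noise


def _segment_basis(trials: pd.DataFrame):
    """Trial index n (from segment start), sinusoid argument j (from
    adaptation onset, zero before it) and block length N."""
    n_tot = len(trials)
    t_idx = np.arange(1, n_tot + 1, dtype=float)
    mask = (trials["block_type"] == ADAPTATION).to_numpy()
    onset = adaptation_onset_index(trials)
    j = np.where(mask, t_idx - onset, 0.0)
    N = adaptation_block_length(trials)
    return t_idx, j, mask, N


def phenom_predict(params: PhenomParams, trials: pd.DataFrame) -> np.ndarray:
    """Evaluate the phenomenological curve on a trial table.

    The sinusoid acts on adaptation trials only (argument counted from
    adaptation onset); the exponential and the asymptote span the whole
    segment (argument counted from the first trial)."""
    t_idx, j, mask, N = _segment_basis(trials)
    w = params.omega(N)
    out = params.B * np.exp(-params.lam * t_idx) + params.B0
    out = out + np.where(mask, params.a * np.sin(w * j - params.phi), 0.0)
    return out


def _design_matrix(model, trials_basis, nu, lam):
    """Columns of the linear block for fixed nonlinear parameters."""
    t_idx, j, mask, N = trials_basis
    if model == "full":
        w = 2.0 * np.pi * nu / N
        return np.column_stack(
            [
                np.where(mask, np.sin(w * j), 0.0),
                np.where(mask, np.cos(w * j), 0.0),
                np.exp(-lam * t_idx),
                np.ones_like(t_idx),
            ]
        )
    if model == "drift":
        return np.column_stack([np.exp(-lam * t_idx), np.ones_like(t_idx)])
    if model == "noise":
        return np.ones((t_idx.size, 1))
    raise ValueError(f"unknown phenomenological model {model!r}")


def _linear_marginal(X: np.ndarray, y: np.ndarray):
    """Closed-form log marginal likelihood of the linear-Gaussian block with
    flat priors on the coefficients and a Jeffreys prior on sigma (prior
    normalization applied by the caller).  Returns (logZ, beta_hat, cov)."""
    n, p = X.shape
    m = n - p
    XtX = X.T @ X
    try:
        beta = np.linalg.solve(XtX, X.T @ y)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(p), np.full((p, p), np.nan)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sign, logdet = np.linalg.slogdet(XtX)
    if sign <= 0:
        return -np.inf, beta, np.full((p, p), np.nan)
    with np.errstate(divide="ignore"):
        log_rss = np.log(rss) if rss > 0 else -np.inf
    logz = gammaln(m / 2.0) - np.log(2.0) - 0.5 * logdet - (m / 2.0) * (np.log(np.pi) + log_rss)
    cov = rss / max(m - 2, 1) * np.linalg.inv(XtX)
    return logz, beta, cov


def _trapezoid_logweights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    if grid.size == 1:
        w[:] = 1.0
    else:
        w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
        w[0] = (grid[1] - grid[0]) / 2.0
        w[-1] = (grid[-1] - grid[-2]) / 2.0
    return np.log(w)


def _ab_to_aphi(alpha: float, beta: float) -> tuple[float, float]:
    """a*sin(wj - phi) = alpha*sin(wj) + beta*cos(wj)."""
    return float(np.hypot(alpha, beta)), float(np.arctan2(-beta, alpha))


class PhenomenologicalModel(BaseEstimator, RegressorMixin):
    """Bayesian fit of the phenomenological gain curve.

    Parameters
    ----------
    model : {"full", "drift", "noise"}
        Full six-parameter curve, drift-only baseline (a = 0), or the
        block-mean noise-only model.
    priors : PhenomPriors, optional
        Uniform prior ranges.
    nu_step, lam_step : float
        Grid resolution for the nonlinear parameters.
    refine : bool
        Polish the posterior mode by bounded least squares after the grid
        scan (point estimates are the refined mode; for the concentrated
        posteriors typical at these trial counts it coincides with the
        posterior mean within the reported sd).

    Attributes
    ----------
    params_ : PhenomParams
    posterior_ : PosteriorSummary
    log_evidence_ : float
        Natural-log marginal likelihood (prior-normalized).
    rss_ : float
    n_fit_ : int
    """

    def __init__(self, model="full", priors=None, nu_step=0.1, lam_step=0.02, refine=True):
        self.model = model
        self.priors = priors
        self.nu_step = nu_step
        self.lam_step = lam_step
        self.refine = refine

    # -- internal ---------------------------------------------------------

    def _prior_log_volume(self, priors: PhenomPriors) -> float:
        spans = {
            "full": [priors.amp_range, priors.amp_range, priors.B_range, priors.B0_range,
                     priors.nu_range, priors.lam_range],
            "drift": [priors.B_range, priors.B0_range, priors.lam_range],
            "noise": [priors.B0_range],
        }[self.model]
        return float(sum(np.log(hi - lo) for lo, hi in spans))

    def fit(self, X: pd.DataFrame, y) -> "PhenomenologicalModel":
        """Fit to a trial table ``X`` and aligned gain series ``y``."""
        if self.model not in NESTED_MODELS:
            raise ValueError(f"unknown phenomenological model {self.model!r}")
        priors = self.priors if self.priors is not None else PhenomPriors()
        y = np.asarray(y, dtype=float)
        if len(X) != y.size:
            raise ValueError("trial table and gain series are misaligned")
        k_all = {"full": 6, "drift": 3, "noise": 1}[self.model]
        if y.size <= k_all:
            raise ValueError("fewer trials than parameters")
        basis = _segment_basis(X) if self.model == "full" else (
            np.arange(1, y.size + 1, dtype=float), None, None, None)
        if self.model == "full":
            n_adapt_blocks = X.loc[X["block_type"] == ADAPTATION, "block"].nunique()
            if n_adapt_blocks != 1:
                raise ValueError(
                    "phenomenological fits operate on segments holding exactly "
                    f"one adaptation block (got {n_adapt_blocks})"
                )
        self._fit_grid(basis, y, priors)
        if self.refine:
            self._refine_mode(basis, y, priors)
        self.n_fit_ = int(y.size)
        return self

    def _grids(self, priors: PhenomPriors):
        nu = np.arange(priors.nu_range[0], priors.nu_range[1] + 1e-9, self.nu_step)
        lam = np.arange(priors.lam_range[0], priors.lam_range[1] + 1e-9, self.lam_step)
        return nu, lam

    def _fit_grid(self, basis, y, priors):
        model = self.model
        if model == "noise":
            logz, beta, cov = _linear_marginal(np.ones((y.size, 1)), y)
            self.log_evidence_ = float(logz - self._prior_log_volume(priors))
            b0 = float(beta[0])
            self.params_ = PhenomParams(B0=b0)
            self.posterior_ = PosteriorSummary({"B0": (b0, float(cov[0, 0]))})
            self.rss_ = float(np.sum((y - b0) ** 2))
            self._mode_ = (b0,)
            return
        nu_grid, lam_grid = self._grids(priors)
        if model == "drift":
            points = [(np.nan, lam) for lam in lam_grid]
            logw = _trapezoid_logweights(lam_grid)
            logw_pts = logw
        else:
            points = [(nu, lam) for nu in nu_grid for lam in lam_grid]
            logw_pts = (
                _trapezoid_logweights(nu_grid)[:, None] + _trapezoid_logweights(lam_grid)[None, :]
            ).ravel()
        p_lin = 4 if model == "full" else 2
        logz = np.empty(len(points))
        betas = np.empty((len(points), p_lin))
        covs = np.empty((len(points), p_lin, p_lin))
        for i, (nu, lam) in enumerate(points):
            Xd = _design_matrix(model, basis, nu, lam)
            logz[i], betas[i], covs[i] = _linear_marginal(Xd, y)
        tot = logsumexp(logz + logw_pts)
        self.log_evidence_ = float(tot - self._prior_log_volume(priors))
        if np.isposinf(tot):
            # exactly interpolating grid point (noise-free data): degenerate
            # posterior concentrated on the zero-residual points
            w = np.isposinf(logz).astype(float)
        else:
            with np.errstate(invalid="ignore"):
                w = np.exp(logz + logw_pts - tot)
            w = np.where(np.isfinite(w), w, 0.0)
            if w.sum() == 0:  # all grid points degenerate; flat fallback
                w = np.isfinite(logz).astype(float)
        w /= w.sum()
        # mixture moments: law of total variance across the grid
        pts = np.asarray(points, dtype=float)
        lam_mean = float(w @ pts[:, 1])
        lam_var = float(w @ (pts[:, 1] - lam_mean) ** 2)
        beta_mean = w @ betas
        beta_cov = np.einsum("i,ijk->jk", w, covs)
        dev = betas - beta_mean
        beta_cov = beta_cov + np.einsum("i,ij,ik->jk", w, dev, dev)
        self._grid_argmax_ = points[int(np.argmax(logz))]
        if model == "drift":
            moments = {
                "B": (float(beta_mean[0]), float(beta_cov[0, 0])),
                "lam": (lam_mean, lam_var),
                "B0": (float(beta_mean[1]), float(beta_cov[1, 1])),
            }
            self._mode_beta_ = betas[int(np.argmax(logz))]
        else:
            nu_mean = float(w @ pts[:, 0])
            nu_var = float(w @ (pts[:, 0] - nu_mean) ** 2)
            al, be = float(beta_mean[0]), float(beta_mean[1])
            a_mean, phi_mean = _ab_to_aphi(al, be)
            C = beta_cov[:2, :2]
            if a_mean > 0:
                ga = np.array([al, be]) / a_mean
                gp = np.array([be, -al]) / a_mean**2
                a_var = float(ga @ C @ ga)
                phi_var = float(gp @ C @ gp)
            else:
                a_var = float(np.trace(C))
                phi_var = float(np.pi**2 / 3.0)
            moments = {
                "a": (a_mean, a_var),
                "nu": (nu_mean, nu_var),
                "phi": (phi_mean, phi_var),
                "B": (float(beta_mean[2]), float(beta_cov[2, 2])),
                "lam": (lam_mean, lam_var),
                "B0": (float(beta_mean[3]), float(beta_cov[3, 3])),
            }
            self._mode_beta_ = betas[int(np.argmax(logz))]
        self.posterior_ = PosteriorSummary(moments)
        self._set_params_from_mode(basis, y)

    def _set_params_from_mode(self, basis, y):
        if self.model == "drift":
            lam = self._grid_argmax_[1]
            B, B0 = self._mode_beta_
            self.params_ = PhenomParams(B=float(B), lam=float(lam), B0=float(B0))
        else:
            nu, lam = self._grid_argmax_
            al, be, B, B0 = self._mode_beta_
            a, phi = _ab_to_aphi(al, be)
            self.params_ = PhenomParams(a=a, nu=float(nu), phi=phi, B=float(B),
                                        lam=float(lam), B0=float(B0))
        pred = self._predict_from_theta(basis, self._theta_from_params())
        self.rss_ = float(np.sum((y - pred) ** 2))

    def _theta_from_params(self):
        p = self.params_
        if self.model == "drift":
            return np.array([p.lam, p.B, p.B0])
        al = p.a * np.cos(p.phi)
        be = -p.a * np.sin(p.phi)
        return np.array([p.nu, p.lam, al, be, p.B, p.B0])

    def _predict_from_theta(self, basis, theta):
        if self.model == "drift":
            lam, B, B0 = theta
            Xd = _design_matrix("drift", basis, np.nan, lam)
            return Xd @ np.array([B, B0])
        nu, lam, al, be, B, B0 = theta
        Xd = _design_matrix("full", basis, nu, lam)
        return Xd @ np.array([al, be, B, B0])

    def _refine_mode(self, basis, y, priors):
        theta0 = self._theta_from_params()
        if self.model == "noise":
            return
        if self.model == "drift":
            lo = [priors.lam_range[0], priors.B_range[0], priors.B0_range[0]]
            hi = [priors.lam_range[1], priors.B_range[1], priors.B0_range[1]]
        else:
            lo = [priors.nu_range[0], priors.lam_range[0], priors.amp_range[0],
                  priors.amp_range[0], priors.B_range[0], priors.B0_range[0]]
            hi = [priors.nu_range[1], priors.lam_range[1], priors.amp_range[1],
                  priors.amp_range[1], priors.B_range[1], priors.B0_range[1]]
        theta0 = np.clip(theta0, lo, hi)
        res = least_squares(
            lambda th: y - self._predict_from_theta(basis, th),
            theta0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if res.cost * 2 <= np.sum((y - self._predict_from_theta(basis, theta0)) ** 2):
            if self.model == "drift":
                lam, B, B0 = res.x
                self.params_ = PhenomParams(B=float(B), lam=float(lam), B0=float(B0))
            else:
                nu, lam, al, be, B, B0 = res.x
                a, phi = _ab_to_aphi(al, be)
                self.params_ = PhenomParams(a=a, nu=float(nu), phi=phi, B=float(B),
                                            lam=float(lam), B0=float(B0))
            self.rss_ = float(2 * res.cost)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.model == "noise":
            return np.full(len(X), self.params_.B0)
        if self.model == "drift":
            n = np.arange(1, len(X) + 1, dtype=float)
            return self.params_.B * np.exp(-self.params_.lam * n) + self.params_.B0
        return phenom_predict(self.params_, X)


# -- functional wrappers ---------------------------------------------------

def fit_phenom(
    g, trials: pd.DataFrame, priors: PhenomPriors | None = None, model: str = "full", **kw
) -> tuple[PhenomParams, PosteriorSummary]:
    """Fit the phenomenological model; returns point estimates and marginal
    posterior moments."""
    est = PhenomenologicalModel(model=model, priors=priors, **kw).fit(trials, g)
    return est.params_, est.posterior_


def log_marginal_likelihood(
    g, trials: pd.DataFrame, model: str, priors: PhenomPriors | None = None, **kw
) -> float:
    est = PhenomenologicalModel(model=model, priors=priors, refine=False, **kw).fit(trials, g)
    return est.log_evidence_


def evidence_db(
    g, trials: pd.DataFrame, model_hi: str, model_lo: str,
    priors: PhenomPriors | None = None, **kw
) -> float:
    """Evidence for ``model_hi`` over ``model_lo`` in decibels
    (``10*log10`` of the marginal-likelihood ratio; antisymmetric)."""
    for m in (model_hi, model_lo):
        if m not in NESTED_MODELS:
            raise ValueError(f"{m!r} is not one of the nested models "
                             f"{sorted(NESTED_MODELS)}")
    if model_hi == model_lo:
        return 0.0
    z_hi = log_marginal_likelihood(g, trials, model_hi, priors, **kw)
    z_lo = log_marginal_likelihood(g, trials, model_lo, priors, **kw)
    return DB_PER_NAT * (z_hi - z_lo)


def evidence_report(g, trials: pd.DataFrame, priors: PhenomPriors | None = None, **kw
                    ) -> EvidenceReport:
    """Evidence across the nested chain, as stacked in model-quality plots."""
    z = {m: log_marginal_likelihood(g, trials, m, priors, **kw) for m in NESTED_MODELS}
    return EvidenceReport(
        db_full_vs_drift=DB_PER_NAT * (z["full"] - z["drift"]),
        db_drift_vs_noise=DB_PER_NAT * (z["drift"] - z["noise"]),
    )


def weighted_population_estimate(means, sds) -> float:
    """Pool per-participant posterior means, weighting by the inverse
    posterior variance (weights 1/sd^2); equal sds reduce to the arithmetic
    mean."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape:
        raise ValueError("means and sds must have equal length")
    if np.any(sds <= 0):
        raise ValueError("all sds must be positive; floor zero sds before pooling")
    w = 1.0 / sds**2
    return float(np.sum(w * means) / np.sum(w))
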