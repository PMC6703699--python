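"""Closed-form solution of the state-equation learner under sinusoidal drive.

For stimulus ``s(n) = sin(w n)`` the steady-state response of the recursion
``x(n+1) = (A-K) x(n) - D x(n-1) + K s(n) + D s(n-1) + m`` is a lagged
sinusoid riding on a constant baseline.  Writing the transfer function at
``z = exp(i w)`` gives

    x(n) -> (Q/R) sin(w n - (phi + varphi)) + B0,

with R, phi from the denominator, Q, varphi from the numerator, asymptote
``B0 = m / (1 - (A - (K + D)))`` and baseline decay modes equal to the roots
of ``r**2 - (A-K) r + D = 0`` (``exp(-lambda) = root``).  For D = 0 these
reduce to the single-error iteration solution: amplitude K/R, varphi = 0,
``exp(-lambda) = A - K``.

The module also provides the exact two-learner rewriting of the double-error
model: half-sum and half-difference channels with rates ``kappa = K + D``
(slow) and ``eta = K - D`` (fast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PeriodicSolution:
    """Periodic (steady-state) response to a unit sinusoidal stimulus."""

    a: float            #: amplitude (dimensionless)
    phi: float          #: bare lag (radians)
    varphi: float       #: extra lag induced by the distal term D (radians)
    R: float            #: denominator magnitude
    Q: float            #: numerator magnitude (reduces to K when D = 0)
    omega: float        #: angular frequency per trial

    @property
    def total_lag(self) -> float:
        """Behavioral lag phi + varphi (radians)."""
        return self.phi + self.varphi

    @property
    def total_lag_trials(self) -> float:
        """Behavioral lag expressed in trials, (phi + varphi) / omega."""
        return self.total_lag / self.omega


@dataclass(frozen=True)
class BaselineSolution:
    """Baseline drift of the response: asymptote and decay modes."""

    B0: float                   #: asymptote (gain units)
    modes: tuple[complex, ...]  #: roots of r**2 - (A-K) r + D (= exp(-lambda))
    oscillatory: bool           #: True when (A-K)**2 < 4 D (complex modes)

    @property
    def dominant_mode(self) -> float:
        """Signed value of the largest-magnitude mode."""
        mags = [abs(r) for r in self.modes]
        r = self.modes[int(np.argmax(mags))]
        return float(np.real(r)) if not self.oscillatory else float(abs(r))

    @property
    def dominant_lambda(self) -> float:
        """Decay timescale of the slow mode, -ln|root| (1/trials)."""
        return float(-np.log(max(abs(r) for r in self.modes)))


def asymptote(K: float, A: float = 1.0, m: float = 0.0, D: float = 0.0) -> float:
    """Large-trial asymptote of the baseline, ``B0 = m / (1 - (A - (K+D)))``.

    Vanishes whenever m = 0; for A ~ 1 it approaches m / (K + D).
    """
    den = 1.0 - (A - (K + D))
    if abs(den) < 1e-12:
        raise ValueError("marginally stable: 1 - (A - (K + D)) = 0, no asymptote")
    return m / den


def timescales(K: float, A: float = 1.0, D: float = 0.0) -> BaselineSolution:
    """Decay modes of the baseline, ``exp(-lambda) = ((A-K) +- sqrt((A-K)^2 - 4D)) / 2``.

    For D = 0 the single mode is ``A - K``; a negative D splits it into a slow
    positive (dominant) mode and a fast alternating one.  Complex modes are
    flagged as oscillatory, not raised.
    """
    b = A - K
    disc = b * b - 4.0 * D
    oscillatory = disc < 0
    sq = np.sqrt(complex(disc))
    modes = ((b + sq) / 2.0, (b - sq) / 2.0)
    if not oscillatory:
        modes = tuple(float(np.real(r)) for r in modes)
    if D == 0.0:
        # degenerate zero root is an artifact of the order-2 embedding
        modes = (float(b),)
    B = BaselineSolution(B0=np.nan, modes=modes, oscillatory=bool(oscillatory))
    return B


def periodic_response(
    K: float, A: float = 1.0, D: float = 0.0, omega: float = 0.0
) -> PeriodicSolution:
    """Amplitude and lag of the periodic response at angular frequency omega.

    ``R`` and the bare lag phi come from the denominator of the transfer
    function, ``Q`` and varphi from its numerator; the amplitude is
    ``a = Q / R`` (``K / R`` when D = 0) and the observable lag is
    ``phi + varphi``.
    """
    if not (0.0 < omega <= np.pi):
        raise ValueError("omega must lie in (0, pi]")
    cw, sw = np.cos(omega), np.sin(omega)
    re_den = cw - (A - K - D * cw)
    im_den = (1.0 - D) * sw
    R = float(np.hypot(re_den, im_den))
    if R < 1e-14:
        raise ValueError("degenerate (resonant) parameters: R = 0")
    phi = float(np.arctan2(im_den, re_den))
    re_num = K + D * cw
    im_num = D * sw
    Q = float(np.hypot(re_num, im_num))
    varphi = float(np.arctan2(im_num, re_num)) if Q > 0 else 0.0
    return PeriodicSolution(a=Q / R, phi=phi, varphi=varphi, R=R, Q=Q, omega=omega)


def baseline_solution(
    K: float, A: float = 1.0, m: float = 0.0, D: float = 0.0
) -> BaselineSolution:
    """Full baseline description: asymptote plus decay modes."""
    base = timescales(K, A, D)
    return BaselineSolution(
        B0=asymptote(K, A, m, D), modes=base.modes, oscillatory=base.oscillatory
    )


@dataclass(frozen=True)
class TwoLearnerView:
    """Exact rewriting of the double-error model as two single-error learners
    driven by the half-sum and half-difference of consecutive stimuli."""

    kappa: float        #: slow-channel rate K + D
    eta: float          #: fast-channel rate K - D
    S_plus: np.ndarray
    S_minus: np.ndarray
    X_plus: np.ndarray
    X_minus: np.ndarray


def two_learner_view(
    K: float,
    D: float,
    trials: pd.DataFrame | np.ndarray,
    traj: np.ndarray,
) -> TwoLearnerView:
    """Half-sum/half-difference channel decomposition of a trajectory.

    ``X+(n) = (x(n) + x(n-1))/2`` and ``X-(n) = (x(n) - x(n-1))/2`` (likewise
    for the stimulus), with the convention s(0) = 0, x(0) = x(1) used by the
    simulator.  The reconstruction ``x = X+ + X-`` is exact by construction.
    """
    s = np.asarray(trials["s"] if isinstance(trials, pd.DataFrame) else trials, dtype=float)
    x = np.asarray(traj, dtype=float)
    if s.shape != x.shape:
        raise ValueError("stimulus and trajectory must be aligned")
    s_lag = np.concatenate(([0.0], s[:-1]))
    x_lag = np.concatenate(([x[0]], x[:-1]))
    return TwoLearnerView(
        kappa=K + D,
        eta=K - D,
        S_plus=0.5 * (s + s_lag),
        S_minus=0.5 * (s - s_lag),
        X_plus=0.5 * (x + x_lag),
        X_minus=0.5 * (x - x_lag),
    )
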