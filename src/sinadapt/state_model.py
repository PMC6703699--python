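"""The 16-member family of noise-free linear time-invariant state-equation
learners and their forward simulation.

The hidden adaptation-gain state evolves by a modified delta rule with
retention, drift and double error sampling::

    x(n+1) = A*x(n) + K*(s(n) - x(n)) + m + D*(s(n-1) - x(n-1))

where K is the learning rate on the last feedback error, A the persistence
(retention) rate, m a non-error-based drift, and D a distal learning rate on
the next-to-last error.  K is free in every model; A, m, D and the initial
condition G are optionally free, giving 16 models in four groups:

I   no m, no D     (K, KA, KG, KAG)
II  m, no D        (Km, KAm, KmG, KAmG)
III D, no m        (KD, KAD, KDG, KADG)
IV  m and D        (KmD, KAmD, KmDG, KAmDG)

When a parameter is not free it is fixed at A = 1, m = 0, D = 0; a fixed G is
set to the mean of the first five observed gains (see
:func:`initial_gain_estimate`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd
from numba import njit

PARAM_ORDER = ("K", "A", "m", "D", "G")
DIVERGENCE_BOUND = 1.0e6


@dataclass(frozen=True)
class ModelSpec:
    """Which of A, m, D, G are free parameters (K always is)."""

    free_A: bool
    free_m: bool
    free_D: bool
    free_G: bool

    @property
    def name(self) -> str:
        return "K" + "".join(
            letter
            for letter, on in zip("AmDG", (self.free_A, self.free_m, self.free_D, self.free_G))
            if on
        )

    @property
    def group(self) -> str:
        return {
            (False, False): "I",
            (True, False): "II",
            (False, True): "III",
            (True, True): "IV",
        }[(self.free_m, self.free_D)]

    @property
    def free_names(self) -> tuple[str, ...]:
        """Free parameters in canonical order, K first."""
        out = ["K"]
        for letter, on in zip("AmDG", (self.free_A, self.free_m, self.free_D, self.free_G)):
            if on:
                out.append(letter)
        return tuple(out)

    @property
    def n_free(self) -> int:
        return len(self.free_names)


def enumerate_model_specs() -> list[ModelSpec]:
    """All 16 model specs, ordered by group (I-IV) then by name."""
    specs = [
        ModelSpec(free_A=a, free_m=m, free_D=d, free_G=g)
        for a, m, d, g in product((False, True), repeat=4)
    ]
    group_rank = {"I": 0, "II": 1, "III": 2, "IV": 3}
    return sorted(specs, key=lambda sp: (group_rank[sp.group], sp.name))


def get_model_spec(name: str) -> ModelSpec:
    """Look up a spec by its canonical name (e.g. ``"KAmDG"``)."""
    for spec in enumerate_model_specs():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown model name {name!r}; valid names: "
                   f"{[s.name for s in enumerate_model_specs()]}")


@dataclass(frozen=True)
class GenerativeParams:
    """Values of the state-equation coefficients (gain units per trial for m,
    dimensionless rates otherwise)."""

    K: float
    A: float = 1.0
    m: float = 0.0
    D: float = 0.0
    G: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.K, self.A, self.m, self.D, self.G], dtype=float)

    def constrained(self, spec: ModelSpec) -> "GenerativeParams":
        """Copy with the parameters that *spec* fixes reset to their fixed
        values (A=1, m=0, D=0); G is left as given."""
        return replace(
            self,
            A=self.A if spec.free_A else 1.0,
            m=self.m if spec.free_m else 0.0,
            D=self.D if spec.free_D else 0.0,
        )


def initial_gain_estimate(g: np.ndarray | pd.Series, window: int = 5) -> float:
    """Proxy for the unknown initial internal state: mean of the first
    ``window`` observed gains (default 5)."""
    arr = np.asarray(g, dtype=float)
    if arr.size == 0:
        raise ValueError("empty gain series")
    if arr.size < window:
        raise ValueError(f"gain series has {arr.size} trials, needs >= {window}")
    return float(arr[:window].mean())


@njit(cache=True)
def _simulate_kernel(s, K, A, m, D, G, bound):  # pragma: no cover - jitted
    n = s.size
    x = np.empty(n)
    x[0] = G
    x_prev = G      # x(0) := x(1)
    s_prev = 0.0    # s(0) := 0
    unstable = False
    for i in range(n - 1):
        nxt = A * x[i] + K * (s[i] - x[i]) + m + D * (s_prev - x_prev)
        if np.abs(nxt) > bound:
            nxt = bound if nxt > 0 else -bound
            unstable = True
        s_prev = s[i]
        x_prev = x[i]
        x[i + 1] = nxt
    return x, unstable


@njit(cache=True)
def _sensitivity_kernel(s, K, A, m, D, G, bound):  # pragma: no cover - jitted
    """State trajectory plus d x(n) / d(K, A, m, D, G) by forward
    sensitivity recursions (the recursion is linear in the state, so the
    sensitivities obey the same homogeneous recursion with parameter-
    specific forcing)."""
    n = s.size
    x = np.empty(n)
    sens = np.zeros((n, 5))
    x[0] = G
    sens[0, 4] = 1.0
    x_prev = G
    s_prev = 0.0
    d_prev = np.zeros(5)
    d_prev[4] = 1.0  # x(0) = x(1) = G
    for i in range(n - 1):
        nxt = A * x[i] + K * (s[i] - x[i]) + m + D * (s_prev - x_prev)
        clipped = np.abs(nxt) > bound
        if clipped:
            nxt = bound if nxt > 0 else -bound
        for j in range(5):
            hom = (A - K) * sens[i, j] - D * d_prev[j]
            if j == 0:
                hom += s[i] - x[i]
            elif j == 1:
                hom += x[i]
            elif j == 2:
                hom += 1.0
            elif j == 3:
                hom += s_prev - x_prev
            sens[i + 1, j] = 0.0 if clipped else hom
        s_prev = s[i]
        x_prev = x[i]
        for j in range(5):
            d_prev[j] = sens[i, j]
        x[i + 1] = nxt
    return x, sens


def simulate_with_sensitivities(
    params: GenerativeParams, s: np.ndarray, bound: float = DIVERGENCE_BOUND
) -> tuple[np.ndarray, np.ndarray]:
    """Trajectory and its Jacobian with respect to (K, A, m, D, G)."""
    s = np.asarray(s, dtype=float)
    return _sensitivity_kernel(s, params.K, params.A, params.m, params.D, params.G, bound)


def simulate(
    spec: ModelSpec | None,
    params: GenerativeParams,
    trials: pd.DataFrame | np.ndarray,
    bound: float = DIVERGENCE_BOUND,
) -> tuple[np.ndarray, bool]:
    """Forward-simulate the hidden state x(n) driven by the stimulus gain.

    Parameters fixed by *spec* (if given) are enforced before simulation.
    Returns ``(x, unstable)``; a diverging trajectory is clamped at ±bound
    and flagged rather than raising, so optimizers can penalize it.
    """
    if spec is not None:
        params = params.constrained(spec)
    vals = params.as_array()
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite generative parameters")
    s = np.asarray(trials["s"] if isinstance(trials, pd.DataFrame) else trials, dtype=float)
    if s.size == 0:
        raise ValueError("empty trial series")
    x, unstable = _simulate_kernel(s, params.K, params.A, params.m, params.D, params.G, bound)
    return x, bool(unstable)


def self_consistent_initial_gain(
    params: GenerativeParams, s: np.ndarray, window: int = 5
) -> float:
    """Initial state G whose noise-free trajectory has first-``window`` mean
    equal to G itself.

    Models without a free G pin the initial state to the mean of the first
    five observed gains; a synthetic observer generated with this G satisfies
    that convention exactly, so noise-free fits can recover the truth.  The
    map G -> mean(x[:window]) is affine in G, so the fixed point is solved in
    closed form from one sensitivity run."""
    s = np.asarray(s, dtype=float)
    if s.size < window:
        raise ValueError("stimulus shorter than the averaging window")
    x0, sens = _sensitivity_kernel(s, params.K, params.A, params.m, params.D, 0.0,
                                   DIVERGENCE_BOUND)
    a = float(x0[:window].mean())
    b = float(sens[:window, 4].mean())
    if abs(1.0 - b) < 1e-12:
        raise ValueError("degenerate parameters: initial-state map has unit slope")
    return a / (1.0 - b)


def is_stable(K: float, A: float, D: float) -> bool:
    """Stability of the homogeneous recursion: both roots of
    ``r**2 - (A-K) r + D = 0`` strictly inside the unit circle."""
    roots = characteristic_roots(K, A, D)
    return bool(np.all(np.abs(roots) < 1.0))


def characteristic_roots(K: float, A: float, D: float) -> np.ndarray:
    """Roots of the characteristic polynomial ``r**2 - (A-K) r + D``
    (for D = 0 the single non-trivial root is A - K, plus a zero root)."""
    return np.roots([1.0, -(A - K), D])


def to_saccade_gain_state(x: np.ndarray, p: float) -> np.ndarray:
    """Convert the adaptation-gain state to saccade-gain coordinates,
    ``z = 1 + p*x``."""
    return 1.0 + p * np.asarray(x, dtype=float)
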