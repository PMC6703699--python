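"""Session designs and per-trial stimulus series for sinusoidal double-step
saccade adaptation.

A session is a sequence of blocks. Non-adaptation blocks carry no intra-
saccadic step (ISS); adaptation blocks displace the target during the saccade
by a sinusoidal function of the trial number, completing an integer number of
cycles per block.  All gains are dimensionless:

* stimulus gain      ``s(n) = sin(2*pi*f*n_block/N)`` on adaptation trials,
  0 elsewhere,
* disturbance gain   ``d(n) = p * s(n)`` with ``p = P / preTP``,
* target gain        ``t(n) = 1 + p * s(n)``,
* adaptation gain    ``g(n) = (SA(n) - preTP) / P`` for saccade amplitude SA.

The sinusoid restarts at phase zero at the first trial of every adaptation
block, so the mean of ``s`` over a full block vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NON_ADAPTATION = "non-adaptation"
ADAPTATION = "adaptation"

#: column schema of a serialized trial table (module io adds ``g``/``x_pred``)
TRIAL_COLUMNS = [
    "trial",
    "block",
    "block_type",
    "trial_in_block",
    "frequency_cpb",
    "s",
    "t",
    "d",
]


@dataclass(frozen=True)
class SessionDesign:
    """Block structure and stimulus constants of one experimental session.

    Parameters
    ----------
    block_lengths
        Trials per block, in presentation order.
    block_types
        ``"non-adaptation"`` or ``"adaptation"`` per block.
    frequencies
        Integer cycles per block (cpb), one entry per *adaptation* block.
    P
        Amplitude of the sinusoidal ISS in dva (default 2).
    preTP
        Pre-saccadic target amplitude in dva (default 8).
    adaptation_type
        Condition label, ``"two-way"`` or ``"global"``.
    constant
        Constant ISS component ``c`` in gain units; 0 in the sinusoidal
        paradigm and kept only for generality.
    """

    block_lengths: tuple[int, ...]
    block_types: tuple[str, ...]
    frequencies: tuple[int, ...]
    P: float = 2.0
    preTP: float = 8.0
    adaptation_type: str = "two-way"
    constant: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_lengths", tuple(int(b) for b in self.block_lengths))
        object.__setattr__(self, "block_types", tuple(self.block_types))
        if len(self.block_lengths) != len(self.block_types):
            raise ValueError("block_lengths and block_types differ in length")
        if any(b <= 0 for b in self.block_lengths):
            raise ValueError("all block lengths must be positive integers")
        bad = set(self.block_types) - {NON_ADAPTATION, ADAPTATION}
        if bad:
            raise ValueError(f"unknown block types: {sorted(bad)}")
        n_adapt = sum(bt == ADAPTATION for bt in self.block_types)
        freqs = tuple(self.frequencies)
        if len(freqs) != n_adapt:
            raise ValueError(
                f"{n_adapt} adaptation blocks but {len(freqs)} frequencies given"
            )
        for f in freqs:
            if float(f) != int(f) or f <= 0:
                raise ValueError(
                    "frequencies must be positive integers (integer cycles per block)"
                )
        object.__setattr__(self, "frequencies", tuple(int(f) for f in freqs))
        if self.preTP <= 0 or self.P <= 0:
            raise ValueError("preTP and P must be positive")

    @property
    def p(self) -> float:
        """Dimensionless ISS amplitude ratio ``P / preTP``."""
        return self.P / self.preTP

    @property
    def n_trials(self) -> int:
        return int(sum(self.block_lengths))


FREQ_FREQUENCIES = (1, 3, 6, 12, 24)
ORIG_FREQUENCIES = (3, 4, 6)


def freq_design(
    frequencies: tuple[int, ...] = FREQ_FREQUENCIES,
    adaptation_type: str = "two-way",
    pre_length: int = 75,
    adapt_length: int = 384,
) -> SessionDesign:
    """FREQ session: alternating non-adaptation (75 trials) and adaptation
    (384 trials) blocks, beginning and ending with a non-adaptation block."""
    lengths: list[int] = []
    types: list[str] = []
    for f in frequencies:
        lengths += [pre_length, adapt_length]
        types += [NON_ADAPTATION, ADAPTATION]
    lengths.append(pre_length)
    types.append(NON_ADAPTATION)
    return SessionDesign(
        tuple(lengths), tuple(types), tuple(frequencies), adaptation_type=adaptation_type
    )


def single_block_design(
    frequency: int,
    adaptation_type: str = "two-way",
    pre_length: int = 75,
    adapt_length: int = 384,
) -> SessionDesign:
    """One pre-adaptation block followed by one adaptation block; the unit
    on which individual fits are run (also used for ORIG-style sessions)."""
    return SessionDesign(
        (pre_length, adapt_length),
        (NON_ADAPTATION, ADAPTATION),
        (int(frequency),),
        adaptation_type=adaptation_type,
    )


def build_session(design: SessionDesign) -> pd.DataFrame:
    """Construct the per-trial stimulus table of a session.

    Returns a DataFrame with columns :data:`TRIAL_COLUMNS`: 1-based global
    trial index, block id, block type, 1-based within-block index, cpb
    frequency (NaN on non-adaptation blocks) and the gains ``s``, ``t``, ``d``.
    """
    rows_s: list[np.ndarray] = []
    block_ids: list[np.ndarray] = []
    types: list[np.ndarray] = []
    n_block: list[np.ndarray] = []
    freq_col: list[np.ndarray] = []
    freq_iter = iter(design.frequencies)
    for b, (length, btype) in enumerate(zip(design.block_lengths, design.block_types), start=1):
        idx = np.arange(1, length + 1, dtype=float)
        if btype == ADAPTATION:
            f = next(freq_iter)
            s = np.sin(2.0 * np.pi * f * idx / length)
            freq_col.append(np.full(length, float(f)))
        else:
            s = np.zeros(length)
            freq_col.append(np.full(length, np.nan))
        rows_s.append(s)
        block_ids.append(np.full(length, b, dtype=int))
        types.append(np.full(length, btype, dtype=object))
        n_block.append(idx)
    s = np.concatenate(rows_s)
    p = design.p
    d = p * s + design.constant
    out = pd.DataFrame(
        {
            "trial": np.arange(1, design.n_trials + 1),
            "block": np.concatenate(block_ids),
            "block_type": np.concatenate(types),
            "trial_in_block": np.concatenate(n_block).astype(int),
            "frequency_cpb": np.concatenate(freq_col),
            "s": s,
            "t": 1.0 + d,
            "d": d,
        }
    )
    out.attrs["p"] = p
    out.attrs["adaptation_type"] = design.adaptation_type
    return out


def target_gain(s: np.ndarray | float, p: float) -> np.ndarray | float:
    """Target gain ``t = 1 + p*s`` from stimulus gain and amplitude ratio."""
    if p < 0:
        raise ValueError("amplitude ratio p must be non-negative")
    return 1.0 + p * np.asarray(s) if np.ndim(s) else 1.0 + p * s


def adaptation_gain(SA: np.ndarray | float, preTP: float, P: float):
    """Adaptation gain ``g = (SA - preTP) / P`` from saccade amplitude (dva).

    Zero for a perfectly accurate saccade; 1 when the saccade overshoots by
    one full ISS amplitude.
    """
    if P == 0:
        raise ValueError("P = 0: adaptation-gain normalization undefined")
    if preTP <= 0:
        raise ValueError("preTP must be positive")
    return (np.asarray(SA, dtype=float) - preTP) / P


def saccade_gain(g: np.ndarray | float, preTP: float, P: float):
    """Inverse of :func:`adaptation_gain` expressed as a gain:
    ``SG = 1 + (P/preTP) * g``."""
    if preTP <= 0:
        raise ValueError("preTP must be positive")
    return 1.0 + (P / preTP) * np.asarray(g, dtype=float)


def adaptation_block_length(trials: pd.DataFrame) -> int:
    """Length N of the (first) adaptation block of a trial table."""
    mask = trials["block_type"] == ADAPTATION
    if not mask.any():
        raise ValueError("trial table contains no adaptation block")
    first = trials.loc[mask, "block"].iloc[0]
    return int((trials["block"] == first).sum())


def adaptation_onset_index(trials: pd.DataFrame) -> int:
    """0-based positional index of the first adaptation trial."""
    mask = (trials["block_type"] == ADAPTATION).to_numpy()
    if not mask.any():
        raise ValueError("trial table contains no adaptation block")
    return int(np.argmax(mask))
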