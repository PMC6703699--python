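"""Reading and writing trial tables, configs and fit reports.

Trial tables are tab-delimited text with the schema of
:data:`sinadapt.paradigm.TRIAL_COLUMNS`, optionally extended by observed
gain ``g``, latent state ``x`` and model prediction ``x_pred`` columns.
Numeric columns round-trip at full precision (shortest-repr floats).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .paradigm import ADAPTATION, NON_ADAPTATION, TRIAL_COLUMNS

OPTIONAL_COLUMNS = ["g", "x", "x_pred"]


class TrialTableError(ValueError):
    """Schema or content violation in a trial-table file."""


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table (with any optional columns present) as TSV."""
    cols = TRIAL_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in trials.columns]
    # shortest-repr floats round-trip exactly through read_csv
    trials.to_csv(path, sep="\t", index=False, columns=cols,
                  float_format=lambda v: repr(float(v)))


def read_trials(path) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Read and validate a trial table; returns ``(trials, g)`` with ``g``
    None when the file carries no gain column."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TrialTableError(f"{path}: file is empty") from None
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS + OPTIONAL_COLUMNS]
    if extra:
        raise TrialTableError(f"{path}: unexpected columns {extra}")
    if len(df) == 0:
        raise TrialTableError(f"{path}: table has no rows")
    numeric = ["trial", "block", "trial_in_block", "s", "t", "d"] + [
        c for c in OPTIONAL_COLUMNS if c in df.columns
    ]
    for c in numeric:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # 1-based + header line
            raise TrialTableError(f"{path}: non-numeric value in column {c!r} (line {row})")
        df[c] = vals
    bad_types = set(df["block_type"]) - {ADAPTATION, NON_ADAPTATION}
    if bad_types:
        raise TrialTableError(f"{path}: unknown block types {sorted(bad_types)}")
    off = df.loc[(df["block_type"] == NON_ADAPTATION) & (df["s"] != 0.0)]
    if len(off):
        row = int(off.index[0]) + 2
        raise TrialTableError(
            f"{path}: nonzero stimulus gain in a non-adaptation block (line {row})"
        )
    if not (df["trial"].to_numpy() == np.arange(1, len(df) + 1)).all():
        raise TrialTableError(f"{path}: trial index must run 1..{len(df)}")
    g = df["g"].to_numpy() if "g" in df.columns else None
    return df, g


def read_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_report(obj: dict, path) -> None:
    """Structured-text (YAML) report writer used for fit and selection
    reports; numpy scalars are converted to plain Python numbers."""

    def clean(v):
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.ndarray):
            return [clean(x) for x in v.tolist()]
        return v

    with open(path, "w") as fh:
        yaml.safe_dump(clean(obj), fh, sort_keys=False)
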