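"""CSV interchange and run configuration.

The quantification table is the contract between upstream peak
quantification (or the simulator) and the fitting pipeline: one row per
(protein, peptide, charge, time, experiment) with raw abundances A0..A5.
Output tables echo the run parameters in ``#``-prefixed provenance header
lines, which pandas skips on read.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd
import yaml

from .simulate import QUANT_COLUMNS

__all__ = [
    "read_quant_csv",
    "write_table_csv",
    "read_config",
    "QUANT_COLUMNS",
]

logger = logging.getLogger("isoturn")

_ABUNDANCE_COLS = ["A0", "A1", "A2", "A3", "A4", "A5"]
_KEY_COLS = ["peptide", "charge", "time", "experiment"]


def read_quant_csv(path) -> pd.DataFrame:
    """Read a quantification CSV, dropping malformed rows with a count.

    Rows with negative or non-numeric abundances are skipped (logged);
    duplicate (peptide, charge, time, experiment) keys keep the first
    occurrence.  A missing required column is a hard failure.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"quant CSV {path} lacks required column(s): {missing}")
    n_in = len(df)
    for col in _ABUNDANCE_COLS + ["time"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[_ABUNDANCE_COLS + ["time"]].isna().any(axis=1)
    bad |= (df[_ABUNDANCE_COLS] < 0).any(axis=1)
    bad |= df["time"] < 0
    if bad.any():
        logger.warning("skipped %d malformed row(s) in %s", int(bad.sum()), path)
        df = df[~bad]
    dups = df.duplicated(subset=_KEY_COLS, keep="first")
    if dups.any():
        logger.warning("dropped %d duplicate key row(s) in %s", int(dups.sum()), path)
        df = df[~dups]
    logger.info("read %d/%d rows from %s", len(df), n_in, path)
    return df.reset_index(drop=True)


def write_table_csv(df: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    """Write a CSV with optional ``# key: value`` provenance header lines."""
    with open(path, "w", newline="") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_config(path) -> dict:
    """Read a YAML run configuration (p_w, p_h, thresholds, table paths)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
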