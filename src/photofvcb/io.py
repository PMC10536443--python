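"""CSV writers and readers with run-metadata headers.

All files are comma-separated, dot-decimal, UTF-8, one header row, preceded
by ``#``-prefixed metadata comment lines (package version, seed, parameter
values).  Re-running with an identical configuration reproduces the numeric
columns byte for byte.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import Timecourse
from .errors import DomainError
from .params import KineticParameters

__all__ = [
    "write_timecourse",
    "write_sweep",
    "write_heatmap",
    "write_dataframe",
    "read_csv",
    "read_pam_table",
    "read_gas_exchange_table",
    "read_activity_table",
]

PAM_COLUMNS = {"par", "co2", "replicate", "y_i", "y_ii"}
GAS_COLUMNS = {"par", "co2", "replicate", "a_hv", "ci", "gs", "rd"}
ACTIVITY_COLUMNS = {"process", "temperature", "activity"}


def _metadata_lines(params: Optional[KineticParameters], seed: Optional[int],
                    extra: Optional[dict] = None) -> str:
    lines = [f"# photofvcb {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if params is not None:
        kv = ", ".join(f"{k}={v!r}" for k, v in dataclasses.asdict(params).items())
        lines.append(f"# parameters: {kv}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_dataframe(df: pd.DataFrame, path, params=None, seed=None, extra=None) -> Path:
    """Write a frame as CSV under a metadata comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_lines(params, seed, extra))
        df.to_csv(fh, index=False)
    return path


def write_timecourse(tc: Timecourse, path, params=None, seed=None) -> Path:
    """Write a protocol timecourse (time_s, Aj, Cc, Ci, rates, gm, limitation)."""
    return write_dataframe(tc.to_dataframe(), path, params, seed,
                           extra={"final_Aj": tc.final_Aj})


def write_sweep(df: pd.DataFrame, path, params=None, seed=None, option: str = "basic") -> Path:
    """Write a long-format sweep (temperature, par, option, final_aj)."""
    out = df.copy()
    out["option"] = option
    return write_dataframe(out, path, params, seed)


def write_heatmap(matrix: np.ndarray, grid_j, grid_c, path, params=None, seed=None) -> Path:
    """Write a final-Aj heatmap; rows are act_j values, columns act_c values."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(grid_j), len(grid_c)):
        raise DomainError("heatmap shape does not match the activity grids")
    df = pd.DataFrame(matrix, columns=[f"act_c={c:g}" for c in grid_c])
    df.insert(0, "act_j", list(grid_j))
    return write_dataframe(df, path, params, seed)


def read_csv(path) -> pd.DataFrame:
    """Read a package CSV, skipping ``#`` metadata lines (round-trip floats)."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def _read_table(path, required: set, kind: str) -> pd.DataFrame:
    df = read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise DomainError(
            f"{kind} table {path} is missing column(s): {', '.join(sorted(missing))}"
        )
    return df


def read_pam_table(path) -> pd.DataFrame:
    """Read a PAM table (par, co2, replicate, y_i, y_ii [, qn, pulse columns])."""
    return _read_table(path, PAM_COLUMNS, "PAM")


def read_gas_exchange_table(path) -> pd.DataFrame:
    """Read a gas-exchange table (par, co2, replicate, a_hv, ci, gs, rd)."""
    return _read_table(path, GAS_COLUMNS, "gas-exchange")


def read_activity_table(path) -> pd.DataFrame:
    """Read a temperature-activity table (process, temperature, activity)."""
    return _read_table(path, ACTIVITY_COLUMNS, "activity")
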