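"""File-format conventions shared by every stage.

All tabular output is UTF-8, tab-separated, header row, ``.`` decimal
separator, no thousands separators. Values that could not be corrected
against the internal standard are encoded as the literal string ``NC``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

NC_TOKEN = "NC"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame using the package's TSV dialect. NaN → ``NC``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # float_format=str round-trips doubles exactly (shortest repr)
    df.to_csv(path, sep="\t", index=False, na_rep=NC_TOKEN, float_format=str)
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (``NC`` → NaN)."""
    return pd.read_csv(
        path,
        sep="\t",
        na_values=[NC_TOKEN],
        keep_default_na=True,
        float_precision="round_trip",
        **kwargs,
    )


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)!r}")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Printed-table comparisons use this convention; internal values are never
    rounded.
    """
    return int(np.sign(x) * np.floor(abs(x) + 0.5))
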