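"""Reading and writing block data and result artifacts.

Input is strict CSV (comma separator, UTF-8, header row) with columns
``intensity,k,n`` — one row per block, one file per experimental condition.
Intensities are used exactly as given; any transformation (e.g. log
contrast) is the user's responsibility before writing the file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataValidationError
from .model import BlockDataset

__all__ = ["StudyConfig", "read_blocks", "write_blocks", "write_json"]

REQUIRED_COLUMNS = ("intensity", "k", "n")


@dataclass
class StudyConfig:
    """Resolved configuration of one analysis run, embedded in every output."""

    conditions: list[str]
    gamma: float = 0.5
    shared: str = "w"
    n_proposals: int = 25_000
    n_final: int = 2_000
    seed: int = 0
    out: str = "."

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise DataValidationError(f"gamma must be in [0, 1), got {self.gamma}")

    def as_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "gamma": self.gamma,
            "shared": self.shared,
            "n_proposals": self.n_proposals,
            "n_final": self.n_final,
            "seed": self.seed,
            "out": self.out,
        }


def read_blocks(path, condition_id: str | None = None) -> BlockDataset:
    """Read one condition's blocks from a CSV with columns intensity,k,n."""
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{path}: missing required column(s) {missing}; expected header "
            f"{','.join(REQUIRED_COLUMNS)}"
        )
    for row_idx, row in df.iterrows():
        if not np.isfinite(row["intensity"]):
            raise DataValidationError(f"{path}: row {row_idx}: non-finite intensity")
        if row["n"] < 1:
            raise DataValidationError(f"{path}: row {row_idx}: n must be >= 1")
        if not 0 <= row["k"] <= row["n"]:
            raise DataValidationError(
                f"{path}: row {row_idx}: k={row['k']} outside [0, n={row['n']}]"
            )
    return BlockDataset(
        condition_id=condition_id or path.stem,
        x=df["intensity"].to_numpy(dtype=float),
        k=df["k"].to_numpy(dtype=np.int64),
        n=df["n"].to_numpy(dtype=np.int64),
    )


def write_blocks(data: BlockDataset, path) -> None:
    """Write a BlockDataset back to the canonical CSV dialect."""
    pd.DataFrame({"intensity": data.x, "k": data.k, "n": data.n}).to_csv(
        path, index=False
    )


def write_json(obj: dict, path) -> None:
    """Serialize a result dictionary as pretty-printed JSON."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
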