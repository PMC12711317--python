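"""Observation container with per-variable domains and [0, 1] rescaling.

The fitting machinery works on the unit interval for continuous variables
and on {0, 1} for binary ones. :class:`Dataset` records the affine rescaling
applied to each continuous column so estimates can be mapped back to the
original scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"


@dataclass
class Dataset:
    """An n×p observation table rescaled to fitting domains.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Rescaled observations: continuous columns in [0, 1], binary in {0, 1}.
    kinds : list of str
        Per-column domain tag, ``"continuous"`` or ``"binary"``.
    columns : list of str
        Column names.
    ranges : ndarray of shape (p, 2)
        Original (min, max) per column used in the affine rescaling; for
        binary columns the row is (0, 1).
    """

    values: np.ndarray
    kinds: list[str]
    columns: list[str] = field(default_factory=list)
    ranges: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if len(self.kinds) != p:
            raise ValueError("one kind per column required")
        for kind in self.kinds:
            if kind not in (CONTINUOUS, BINARY):
                raise ValueError(f"unknown column kind: {kind!r}")
        if not self.columns:
            self.columns = [f"x{j + 1}" for j in range(p)]
        if self.ranges is None:
            self.ranges = np.column_stack([np.zeros(p), np.ones(p)])
        self.ranges = np.asarray(self.ranges, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("missing values are not supported")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, raw, kinds=None, columns=None) -> "Dataset":
        """Build from raw observations, rescaling continuous columns to [0, 1].

        ``kinds`` defaults to binary for {0,1}-valued columns and continuous
        otherwise.
        """
        raw = np.asarray(raw, dtype=float)
        n, p = raw.shape
        if kinds is None:
            kinds = [
                BINARY if set(np.unique(raw[:, j])) <= {0.0, 1.0} else CONTINUOUS
                for j in range(p)
            ]
        values = raw.copy()
        ranges = np.zeros((p, 2))
        for j, kind in enumerate(kinds):
            col = raw[:, j]
            if kind == BINARY:
                if not set(np.unique(col)) <= {0.0, 1.0}:
                    raise ValueError(f"binary column {j} must take values in {{0,1}}")
                ranges[j] = (0.0, 1.0)
            else:
                lo, hi = col.min(), col.max()
                if hi - lo < 1e-12:
                    name = columns[j] if columns else f"x{j + 1}"
                    raise ValueError(f"column {name!r} is constant")
                values[:, j] = (col - lo) / (hi - lo)
                ranges[j] = (lo, hi)
        return cls(values, list(kinds), list(columns or []), ranges)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kinds=None) -> "Dataset":
        return cls.from_array(df.to_numpy(dtype=float), kinds, list(df.columns))

    def to_original(self, values=None) -> np.ndarray:
        """Map rescaled values back to the original scale (inverse rescaling)."""
        v = self.values if values is None else np.asarray(values, dtype=float)
        out = v.copy()
        for j in range(self.p):
            lo, hi = self.ranges[j]
            out[:, j] = v[:, j] * (hi - lo) + lo
        return out

    def column_grid(self, j: int, num: int = 101) -> np.ndarray:
        """Evaluation grid for column j (unit grid or {0, 1})."""
        if self.kinds[j] == BINARY:
            return np.array([0.0, 1.0])
        return np.linspace(0.0, 1.0, num)


def read_table(path, sidecar=None) -> Dataset:
    """Read a CSV/TSV observation table with an optional type sidecar.

    The sidecar (JSON or YAML) maps column names to ``{"type": ...}`` entries
    or plain type strings. Unknown types raise before any computation.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    kinds = None
    if sidecar is not None:
        spec = _load_sidecar(Path(sidecar))
        kinds = []
        for name in df.columns:
            entry = spec.get(name, CONTINUOUS)
            kind = entry.get("type", CONTINUOUS) if isinstance(entry, dict) else entry
            if kind not in (CONTINUOUS, BINARY):
                raise ValueError(f"unknown column type {kind!r} for {name!r}")
            kinds.append(kind)
    return Dataset.from_dataframe(df, kinds)


def _load_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)
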