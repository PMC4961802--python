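"""Per-timestep, per-cell simulation record consumed by all scorers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]

_PER_CELL = ["com_x", "com_y", "vp", "dll", "notch", "vhat", "nhat",
             "strong", "signal_active", "deployed", "filo_count",
             "filo_len_total"]


@dataclass
class Trajectory:
    """Simulation record over the analysis window.

    All per-cell arrays have shape (T, n_cells); ``tip`` holds the tip-cell
    id per timestep and ``adj_mask`` a per-cell bitmask of 4-adjacent
    neighbour cells.  ``timesteps`` are the absolute simulation timesteps
    (strictly increasing; normally stabilization .. total-1).
    """

    timesteps: np.ndarray
    genotype: np.ndarray
    com_x: np.ndarray
    com_y: np.ndarray
    vp: np.ndarray
    dll: np.ndarray
    notch: np.ndarray
    vhat: np.ndarray
    nhat: np.ndarray
    strong: np.ndarray
    signal_active: np.ndarray
    deployed: np.ndarray
    filo_count: np.ndarray
    filo_len_total: np.ndarray
    tip: np.ndarray
    adj_mask: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.timesteps)
        if t.ndim != 1 or (np.diff(t) <= 0).any():
            raise ValueError("timesteps must be strictly increasing")
        T, n = np.asarray(self.com_x).shape
        if t.shape[0] != T:
            raise ValueError("timesteps length does not match record length")
        for name in _PER_CELL:
            arr = np.asarray(getattr(self, name))
            if arr.shape != (T, n):
                raise ValueError(f"field {name} has shape {arr.shape}, "
                                 f"expected {(T, n)}")
        if np.asarray(self.genotype).shape[0] != n:
            raise ValueError("genotype length does not match cell count")

    @property
    def n_steps(self) -> int:
        return self.timesteps.shape[0]

    @property
    def n_cells(self) -> int:
        return self.com_x.shape[1]

    def filo_mean_length(self) -> np.ndarray:
        """Mean filopodium length per cell-timestep (0 where no chains)."""
        with np.errstate(invalid="ignore"):
            out = np.where(self.filo_count > 0,
                           self.filo_len_total / np.maximum(self.filo_count,
                                                            1), 0.0)
        return out

    def adjacent(self, row: int, i: int, j: int) -> bool:
        """Were cells i and j in 4-contact at recorded row ``row``?"""
        return bool((int(self.adj_mask[row, i]) >> j) & 1)

    @classmethod
    def from_kernel(cls, rec, tip, adj_mask, genotype, record_from: int
                    ) -> "Trajectory":
        """Wrap the fused-kernel record block."""
        T = rec.shape[0]
        fields = {name: np.ascontiguousarray(rec[:, :, k], dtype=float)
                  for k, name in enumerate(_PER_CELL)}
        return cls(timesteps=np.arange(record_from, record_from + T),
                   genotype=np.asarray(genotype, dtype=np.int8),
                   tip=np.asarray(tip, dtype=np.int64),
                   adj_mask=np.asarray(adj_mask, dtype=np.int64), **fields)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format per-(timestep, cell) table; the file schema."""
        T, n = self.n_steps, self.n_cells
        out = {
            "timestep": np.repeat(self.timesteps, n),
            "cell": np.tile(np.arange(n), T),
            "genotype": np.tile(self.genotype, T),
        }
        for name in _PER_CELL:
            out[name] = getattr(self, name).reshape(-1)
        out["is_tip"] = (np.repeat(self.tip, n)
                         == np.tile(np.arange(n), T)).astype(np.int8)
        out["adj_mask"] = self.adj_mask.reshape(-1)
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls.from_dataframe(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Trajectory":
        steps = np.unique(df["timestep"].to_numpy())
        cells = np.unique(df["cell"].to_numpy())
        T, n = steps.shape[0], cells.shape[0]
        df = df.sort_values(["timestep", "cell"])
        if len(df) != T * n:
            raise ValueError("trajectory table is not a full "
                             "timestep x cell grid")
        fields = {name: df[name].to_numpy(dtype=float).reshape(T, n)
                  for name in _PER_CELL}
        genotype = df["genotype"].to_numpy()[:n].astype(np.int8)
        is_tip = df["is_tip"].to_numpy().reshape(T, n)
        tip = np.where(is_tip.any(axis=1), is_tip.argmax(axis=1), -1)
        adj = df["adj_mask"].to_numpy(dtype=np.int64).reshape(T, n)
        return cls(timesteps=steps, genotype=genotype, tip=tip,
                   adj_mask=adj, **fields)
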