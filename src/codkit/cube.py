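"""Draw-indexed containers for cause-specific and all-cause mortality estimates.

A :class:`DrawCube` holds cause-specific death (or YLL) estimates indexed by
location, year, age group, sex and cause, with an array of posterior draws per
cell.  An :class:`EnvelopeDraws` holds all-cause deaths on the same demographic
index without the cause dimension.  Both keep the index as a pandas DataFrame
and the draws as a dense ``(n_cells, n_draws)`` float array so the rescaling
and aggregation steps stay vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_KEYS = ["location", "year", "age", "sex"]


def _check(index: pd.DataFrame, draws: np.ndarray, keys: list[str]) -> None:
    missing = [k for k in keys if k not in index.columns]
    if missing:
        raise ValueError(f"index missing columns: {missing}")
    if draws.ndim != 2:
        raise ValueError("draws must be a 2-D (n_cells, n_draws) array")
    if len(index) != draws.shape[0]:
        raise ValueError(
            f"index has {len(index)} rows but draws has {draws.shape[0]}"
        )
    if np.any(draws < 0):
        raise ValueError("negative values in draws")


@dataclass
class DrawCube:
    """Cause-specific estimates: one row per (location, year, age, sex, cause)."""

    index: pd.DataFrame
    draws: np.ndarray

    keys = CELL_KEYS + ["cause"]

    def __post_init__(self) -> None:
        self.index = self.index.reset_index(drop=True)
        self.draws = np.asarray(self.draws, dtype=float)
        _check(self.index, self.draws, self.keys)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def copy(self) -> "DrawCube":
        return DrawCube(self.index.copy(), self.draws.copy())

    def cell_groups(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Factorise rows on the demographic cell (all keys except cause).

        Returns (group id per row, unique-cell DataFrame in group-id order).
        """
        mi = pd.MultiIndex.from_frame(self.index[CELL_KEYS])
        codes, uniques = pd.factorize(mi)
        cells = pd.DataFrame(list(uniques), columns=CELL_KEYS)
        return codes, cells

    def to_frame(self) -> pd.DataFrame:
        """Long/wide hybrid: index columns plus draw_0 ... draw_{N-1}."""
        cols = {f"draw_{i}": self.draws[:, i] for i in range(self.n_draws)}
        return pd.concat([self.index, pd.DataFrame(cols)], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DrawCube":
        draw_cols = [c for c in frame.columns if c.startswith("draw_")]
        draw_cols.sort(key=lambda c: int(c.split("_")[1]))
        return cls(frame[cls.keys].copy(), frame[draw_cols].to_numpy(float))

    def point_estimates(self) -> pd.DataFrame:
        """Mean and 95% UI per row (columns: mean, lower, upper)."""
        out = self.index.copy()
        out["mean"] = self.draws.mean(axis=1)
        out["lower"] = np.percentile(self.draws, 2.5, axis=1)
        out["upper"] = np.percentile(self.draws, 97.5, axis=1)
        return out


@dataclass
class EnvelopeDraws:
    """All-cause deaths: one row per (location, year, age, sex)."""

    index: pd.DataFrame
    draws: np.ndarray

    keys = CELL_KEYS

    def __post_init__(self) -> None:
        self.index = self.index.reset_index(drop=True)
        self.draws = np.asarray(self.draws, dtype=float)
        _check(self.index, self.draws, self.keys)
        mi = pd.MultiIndex.from_frame(self.index[CELL_KEYS])
        if mi.duplicated().any():
            raise ValueError("duplicate demographic cells in envelope")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def scaled(self, k: float) -> "EnvelopeDraws":
        return EnvelopeDraws(self.index.copy(), self.draws * k)
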