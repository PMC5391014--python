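"""Stimulus protocol: the 6x6 speller grid, flash groups, schedules and timing.

The row/column paradigm presents a rectangular character grid and intensifies
one full row or one full column at a time.  A *sequence* is one pass in which
every row and every column flashes exactly once (12 flashes for a 6x6 grid);
the attended character participates in exactly two flashes per sequence (its
row and its column).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

#: Default 36-cell grid, row-major: A-Z, digits 1-9, and the space cell.
#: The space doubles as the word separator required by the language model.
DEFAULT_GRID_CHARACTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ123456789 "


@dataclass(frozen=True)
class GridLayout:
    """A rectangular speller grid and its row/column flash groups.

    Groups ``0 .. n_rows-1`` are rows, groups ``n_rows .. n_rows+n_cols-1``
    are columns; every character belongs to exactly one of each.
    """

    characters: str = DEFAULT_GRID_CHARACTERS
    n_rows: int = 6
    n_cols: int = 6

    def __post_init__(self) -> None:
        if len(self.characters) != self.n_rows * self.n_cols:
            raise ValueError(
                f"grid needs {self.n_rows * self.n_cols} characters, "
                f"got {len(self.characters)}"
            )
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("grid characters must be unique")

    @property
    def n_groups(self) -> int:
        return self.n_rows + self.n_cols

    def char_index(self, char: str) -> int:
        idx = self.characters.find(char)
        if idx < 0:
            raise ValueError(f"character {char!r} not in grid")
        return idx

    def groups_of(self, char: str) -> tuple[int, int]:
        """Return the (row group, column group) containing ``char``."""
        idx = self.char_index(char)
        return idx // self.n_cols, self.n_rows + idx % self.n_cols

    def group_members(self, group: int) -> str:
        """Characters intensified when ``group`` flashes."""
        if not 0 <= group < self.n_groups:
            raise ValueError(f"group {group} out of range [0, {self.n_groups})")
        if group < self.n_rows:
            return self.characters[group * self.n_cols:(group + 1) * self.n_cols]
        col = group - self.n_rows
        return self.characters[col::self.n_cols]

    @functools.lru_cache(maxsize=8)
    def membership_matrix(self) -> np.ndarray:
        """Boolean (n_groups, n_characters) matrix: does group g contain char c.

        Cached per layout; treat the returned array as read-only.
        """
        m = np.zeros((self.n_groups, len(self.characters)), dtype=bool)
        for c, ch in enumerate(self.characters):
            row, col = self.groups_of(ch)
            m[row, c] = True
            m[col, c] = True
        return m


@dataclass(frozen=True)
class TimingModel:
    """Flash timing: SOA = flash duration + interstimulus interval (ms)."""

    soa_ms: float = 125.0
    flash_ms: float = 100.0
    isi_ms: float = 25.0
    inter_character_pause_ms: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.soa_ms - (self.flash_ms + self.isi_ms)) > 1e-9:
            raise ValueError("soa_ms must equal flash_ms + isi_ms")


def make_flash_schedule(
    n_sequences: int, seed: int, grid: GridLayout | None = None
) -> np.ndarray:
    """Concatenate ``n_sequences`` independent random permutations of the groups.

    Every group appears exactly once per sequence, so a fixed target receives
    exactly two target flashes in each sequence.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    grid = grid or GridLayout()
    rng = np.random.default_rng(seed)
    return np.concatenate(
        [rng.permutation(grid.n_groups) for _ in range(n_sequences)]
    )


def selection_time_seconds(n_flashes: int, timing: TimingModel | None = None) -> float:
    """Wall-clock seconds consumed by one selection of ``n_flashes`` flashes."""
    if n_flashes < 1:
        raise ValueError("n_flashes must be >= 1")
    timing = timing or TimingModel()
    return n_flashes * timing.soa_ms / 1000.0 + timing.inter_character_pause_ms / 1000.0
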