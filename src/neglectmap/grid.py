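"""Geometry of the 5x7 touch-screen target grid.

Targets are numbered 1..35 row-major: the left-top target is 1 and the
right-bottom target is 35.  Columns 1-3 (0-based 0-2) form the left
hemispace, column 4 (0-based 3) is the midline and belongs to neither
hemispace, columns 5-7 form the right hemispace.
"""

from __future__ import annotations

N_ROWS = 5
N_COLS = 7
N_TARGETS = N_ROWS * N_COLS

MID_COL = 3  # 0-based midline column

LEFT = -1
MID = 0
RIGHT = 1


def column_of(index: int) -> int:
    """0-based column of a 1-based target index."""
    if not 1 <= index <= N_TARGETS:
        raise ValueError(f"target index {index} outside 1..{N_TARGETS}")
    return (index - 1) % N_COLS


def row_of(index: int) -> int:
    """0-based row of a 1-based target index."""
    if not 1 <= index <= N_TARGETS:
        raise ValueError(f"target index {index} outside 1..{N_TARGETS}")
    return (index - 1) // N_COLS


def index_of(row: int, col: int) -> int:
    """1-based target index of a 0-based (row, col)."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"({row}, {col}) outside the {N_ROWS}x{N_COLS} grid")
    return row * N_COLS + col + 1


def hemispace(index: int) -> int:
    """LEFT (-1), MID (0) or RIGHT (+1) for a target index."""
    col = column_of(index)
    if col < MID_COL:
        return LEFT
    if col == MID_COL:
        return MID
    return RIGHT


def left_targets() -> list[int]:
    return [i for i in range(1, N_TARGETS + 1) if hemispace(i) == LEFT]


def right_targets() -> list[int]:
    return [i for i in range(1, N_TARGETS + 1) if hemispace(i) == RIGHT]


def reflect_vertical(index: int) -> int:
    """Mirror a target top-to-bottom (same column, flipped row)."""
    return index_of(N_ROWS - 1 - row_of(index), column_of(index))
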