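"""Lattice adjacency conventions shared by the synthetic generator and the
region-detection graph.

Two layouts are supported:

``square4``
    Rook adjacency on an integer grid: a spot at ``(r, c)`` is adjacent to
    ``(r±1, c)`` and ``(r, c±1)``.

``hex6``
    Hexagonal packing in "odd-r" offset coordinates: odd rows are shifted
    half a step to the right, giving every interior spot six neighbours.
    Arrays that store doubled column coordinates (every spot has constant
    ``(row + col)`` parity, as in Visium position tables) are detected and
    handled with the doubled-coordinate neighbour offsets instead.
"""

from __future__ import annotations

import numpy as np

LAYOUTS = ("square4", "hex6")

_SQUARE4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
# odd-r offset rows: neighbour offsets depend on row parity
_HEX_EVEN = ((0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0))
_HEX_ODD = ((0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1))
# doubled column convention (constant row+col parity)
_HEX_DOUBLED = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))


def _check_layout(layout: str) -> None:
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")


def _uses_doubled_cols(coords: np.ndarray) -> bool:
    parity = (coords[:, 0] + coords[:, 1]) % 2
    return bool(len(parity) > 1 and np.all(parity == parity[0]))


def neighbor_coords(r: int, c: int, layout: str, doubled: bool = False):
    """Candidate neighbour coordinates of ``(r, c)`` under ``layout``."""
    _check_layout(layout)
    if layout == "square4":
        offsets = _SQUARE4
    elif doubled:
        offsets = _HEX_DOUBLED
    else:
        offsets = _HEX_ODD if r % 2 else _HEX_EVEN
    return [(r + dr, c + dc) for dr, dc in offsets]


def adjacent_pairs(coords: np.ndarray, layout: str) -> np.ndarray:
    """Index pairs ``(i, j)`` with ``i < j`` of lattice-adjacent spots.

    Parameters
    ----------
    coords
        Integer array of shape ``(M, 2)`` holding ``(row, col)`` per spot.
    layout
        Adjacency convention, ``"square4"`` or ``"hex6"``.
    """
    _check_layout(layout)
    coords = np.asarray(coords)
    doubled = layout == "hex6" and _uses_doubled_cols(coords)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    pairs = []
    for i, (r, c) in enumerate(coords):
        for nb in neighbor_coords(int(r), int(c), layout, doubled):
            j = index.get(nb)
            if j is not None and i < j:
                pairs.append((i, j))
    if not pairs:
        return np.empty((0, 2), dtype=np.intp)
    return np.asarray(sorted(pairs), dtype=np.intp)
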