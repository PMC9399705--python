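"""Hexagonal cell lattices and their signalling neighbourhoods.

Cells sit on an ``n_rows x n_cols`` hexagonal grid.  Rows index the
dorsoventral axis; in two dimensions even rows (1-based counting, as the
model equations are written) are shifted right by half a cell width, so a
single column (``n_cols == 1``) reduces to a zig-zag chain of cells.

Each cell signals to two classes of neighbours:

* *proximal* neighbours -- cells in direct membrane contact (the first
  hexagonal ring; 2 in a single column, 6 for an interior 2-D cell);
* *distal* neighbours -- second-ring cells reached by signalling
  protrusions (2 in a single column, 4 for an interior 2-D cell).

The lattice is finite with hard boundaries: edge cells simply have fewer
neighbours, and the lateral-inhibition input (an average over the
neighbour set) renormalises accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LatticeSpec",
    "NeighbourMap",
    "build_lattice",
    "coupling_weight",
    "weight_matrix",
    "edge_table",
]

# Row/column offsets of the first hexagonal ring.  Offsets differ with row
# parity because even rows (0-based odd) are shifted right by half a cell.
_PROXIMAL_UNSHIFTED = ((-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0))
_PROXIMAL_SHIFTED = ((-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1))

# Default distal set: the second-ring cells two rows up/down the
# dorsoventral axis.  Rows i +/- 2 share the parity (and half-cell shift) of
# row i, so these offsets are parity independent, and with n_cols == 1 the
# set reduces to the cells two above and two below.  The flanking pair is
# chosen so the neighbour relation stays symmetric (offsets closed under
# negation).  Alternative protrusion geometries can be supplied through
# ``LatticeSpec.distal_offsets``.
_DISTAL_DEFAULT = ((-2, 0), (2, 0), (-2, 1), (2, -1))


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the simulated cell sheet.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions (rows run dorsoventrally).
    include_distal
        Whether protrusion-mediated second-ring signalling is present.
    distal_offsets
        Optional override of the distal (row, col) offsets.  Must be
        closed under negation so the neighbour relation is symmetric.
    """

    n_rows: int
    n_cols: int = 1
    include_distal: bool = True
    distal_offsets: tuple[tuple[int, int], ...] = _DISTAL_DEFAULT

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        offs = {tuple(o) for o in self.distal_offsets}
        if {(-r, -c) for r, c in offs} != offs:
            raise ValueError(
                "distal_offsets must be closed under negation "
                "(symmetric neighbour relation)"
            )

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def flat_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col


@dataclass
class NeighbourMap:
    """Per-cell proximal and distal neighbour sets (flat cell indices)."""

    spec: LatticeSpec
    proximal: list[np.ndarray] = field(repr=False)
    distal: list[np.ndarray] = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.spec.n_cells

    def neighbour_counts(self, cell: int) -> tuple[int, int]:
        return len(self.proximal[cell]), len(self.distal[cell])


def _collect(spec: LatticeSpec, row: int, col: int, offsets) -> np.ndarray:
    out = []
    for dr, dc in offsets:
        r, c = row + dr, col + dc
        if 0 <= r < spec.n_rows and 0 <= c < spec.n_cols:
            out.append(spec.flat_index(r, c))
    return np.array(sorted(out), dtype=np.intp)


def build_lattice(spec: LatticeSpec) -> NeighbourMap:
    """Precompute the neighbour sets of every cell on the lattice."""
    proximal: list[np.ndarray] = []
    distal: list[np.ndarray] = []
    empty = np.array([], dtype=np.intp)
    for row in range(spec.n_rows):
        # 0-based odd rows are the 1-based even (shifted) rows.
        prox_offsets = _PROXIMAL_SHIFTED if row % 2 else _PROXIMAL_UNSHIFTED
        for col in range(spec.n_cols):
            proximal.append(_collect(spec, row, col, prox_offsets))
            if spec.include_distal:
                distal.append(_collect(spec, row, col, spec.distal_offsets))
            else:
                distal.append(empty)
    return NeighbourMap(spec=spec, proximal=proximal, distal=distal)


def coupling_weight(kind: str, eps_ratio: float) -> float:
    """Signalling weight of a neighbour: 1 if proximal, eps_d/eps_p if distal."""
    if eps_ratio < 0:
        raise ValueError("eps_ratio must be non-negative")
    if kind == "proximal":
        return 1.0
    if kind == "distal":
        return float(eps_ratio)
    raise ValueError(f"unknown neighbour kind {kind!r}")


def weight_matrix(nmap: NeighbourMap, eps_ratio: float,
                  norm: str = "capacity") -> np.ndarray:
    """Dense matrix ``W`` such that ``W @ p`` is the averaged neighbour input.

    Row ``i`` holds weight ``eps / |N|`` for each neighbour of cell ``i``,
    where ``eps`` is 1 for proximal and ``eps_ratio`` for distal
    neighbours.  With ``norm="capacity"`` (default) the denominator is the
    full contact count of the hexagonal geometry -- 6 proximal plus 4
    distal when protrusions are included -- for every cell: a single-column
    strip or a boundary cell is treated as embedded in surrounding tissue
    whose unsimulated contacts contribute no signal, so missing neighbours
    dilute rather than renormalise the input.  ``norm="count"`` divides by
    each cell's realised neighbour count instead.  Cells without
    neighbours (1x1 lattice) get an all-zero row.
    """
    if eps_ratio < 0:
        raise ValueError("eps_ratio must be non-negative")
    if norm not in ("capacity", "count"):
        raise ValueError(f"unknown normalisation {norm!r}")
    capacity = 6 + (4 if nmap.spec.include_distal else 0)
    n = nmap.n_cells
    w = np.zeros((n, n))
    for i in range(n):
        prox, dist = nmap.proximal[i], nmap.distal[i]
        total = capacity if norm == "capacity" else len(prox) + len(dist)
        if total == 0:
            continue
        w[i, prox] = 1.0 / total
        w[i, dist] = eps_ratio / total
    return w


def edge_table(nmap: NeighbourMap, eps_ratio: float = 1.0) -> pd.DataFrame:
    """Geometry export: one row per directed signalling edge."""
    rows = []
    for i in range(nmap.n_cells):
        for kind, nbrs in (("proximal", nmap.proximal[i]), ("distal", nmap.distal[i])):
            for j in nbrs:
                rows.append(
                    {
                        "cell_i": i,
                        "cell_j": int(j),
                        "kind": kind,
                        "weight": coupling_weight(kind, eps_ratio),
                    }
                )
    return pd.DataFrame(rows, columns=["cell_i", "cell_j", "kind", "weight"])
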