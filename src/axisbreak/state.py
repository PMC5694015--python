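"""Embryo state: four species on a ring of marginal-zone cells.

The marginal zone is modelled as a 1-D closed ring of ``n_cells`` cells;
cell ``i`` sits at angle ``theta_i = 2*pi*i / n_cells``.  Fragmentation
experiments seal the ring into arcs: cuts are inter-cell boundaries, where
cut position ``c`` severs the edge between cells ``c - 1`` and ``c``
(indices mod ``n_cells``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellState", "EmbryoState"]

SPECIES = ("B", "V", "FB", "FV")


@dataclass(frozen=True)
class CellState:
    """Single-cell snapshot: extracellular BMP4 (B) and Vg1 (V) plus the
    intracellular factors F_B and F_V, all dimensionless and non-negative."""

    B: float
    V: float
    FB: float
    FV: float

    def __post_init__(self) -> None:
        for name in SPECIES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value}")

    def as_array(self) -> np.ndarray:
        return np.array([self.B, self.V, self.FB, self.FV], dtype=float)


@dataclass
class EmbryoState:
    """Per-cell concentrations of the four species on a ring or on arcs.

    ``cuts`` empty means a closed ring; otherwise the sorted cut boundaries
    partition the index set into sealed arcs (paracrine windows truncate at
    arc ends).
    """

    B: np.ndarray
    V: np.ndarray
    FB: np.ndarray
    FV: np.ndarray
    cuts: tuple[int, ...] = ()
    time: float = 0.0
    _arcs: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, s), dtype=float) for s in SPECIES]
        n = arrays[0].shape[0]
        for s, a in zip(SPECIES, arrays):
            if a.ndim != 1 or a.shape[0] != n:
                raise ValueError(f"species arrays must be 1-D of equal length ({s})")
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise ValueError(f"{s} must be finite and non-negative everywhere")
            setattr(self, s, a)
        if n < 3:
            raise ValueError(f"need at least 3 cells, got {n}")
        cuts = tuple(sorted(int(c) % n for c in self.cuts))
        if len(set(cuts)) != len(self.cuts):
            raise ValueError(f"duplicate or aliased cut positions: {self.cuts}")
        self.cuts = cuts
        if self.time < 0:
            raise ValueError("time must be non-negative")
        self._arcs = None

    # -- geometry -----------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.B.shape[0]

    @property
    def is_ring(self) -> bool:
        return len(self.cuts) == 0

    @property
    def angles(self) -> np.ndarray:
        """Angular position of each cell, theta_i = 2 pi i / n."""
        return 2.0 * np.pi * np.arange(self.n_cells) / self.n_cells

    @property
    def arcs(self) -> list[np.ndarray]:
        """Index arrays of the sealed arcs (the whole ring if uncut).

        Each arc runs from one cut boundary to the next, in ring order; a
        single cut yields one open arc covering all cells.
        """
        if self._arcs is None:
            n = self.n_cells
            if not self.cuts:
                self._arcs = [np.arange(n)]
            else:
                cuts = list(self.cuts)
                arcs = []
                for start, nxt in zip(cuts, cuts[1:] + [cuts[0] + n]):
                    length = nxt - start
                    arcs.append(np.arange(start, start + length) % n)
                self._arcs = arcs
        return self._arcs

    # -- access -------------------------------------------------------------

    def species(self, name: str) -> np.ndarray:
        if name not in SPECIES:
            raise ValueError(f"unknown species {name!r}; expected one of {SPECIES}")
        return getattr(self, name)

    def cell(self, i: int) -> CellState:
        return CellState(self.B[i], self.V[i], self.FB[i], self.FV[i])

    def stacked(self) -> np.ndarray:
        """(4, n) array in species order B, V, FB, FV."""
        return np.stack([self.B, self.V, self.FB, self.FV])

    def copy(self) -> "EmbryoState":
        return EmbryoState(
            self.B.copy(), self.V.copy(), self.FB.copy(), self.FV.copy(),
            cuts=self.cuts, time=self.time,
        )

    @classmethod
    def homogeneous(
        cls, n_cells: int, base: tuple[float, float, float, float],
        cuts: tuple[int, ...] = (), time: float = 0.0,
    ) -> "EmbryoState":
        """Uniform state with every cell at the quadruple ``base``."""
        b, v, fb, fv = (float(x) for x in base)
        ones = np.ones(n_cells)
        return cls(b * ones, v * ones, fb * ones, fv * ones, cuts=cuts, time=time)

    @classmethod
    def from_stacked(
        cls, values: np.ndarray, cuts: tuple[int, ...] = (), time: float = 0.0,
    ) -> "EmbryoState":
        return cls(values[0], values[1], values[2], values[3], cuts=cuts, time=time)
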