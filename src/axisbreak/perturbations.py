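"""In-silico counterparts of the embryological manipulations.

Beads and transfected-cell pellets are constant-rate ligand sources over a
footprint of cells (a reservoir releasing ligand, not a concentration
clamp, so the dynamics stay smooth); knockdowns scale the production term
of an intracellular factor by ``1 - efficiency`` (antisense/morpholino
semantics); fragmentation seals the ring into arcs at a scheduled time.
All perturbations act over half-open time windows ``[t_on, t_off)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Perturbation",
    "make_bead",
    "make_pellet",
    "make_knockdown",
    "make_fragmentation",
    "footprint",
]

KINDS = ("bead", "pellet", "knockdown", "fragmentation")
LIGANDS = ("B", "V")
FACTORS = ("FB", "FV")


def footprint(center: int, radius: int, n_cells: int) -> np.ndarray:
    """Cell indices within ``radius`` of ``center`` on a ring of ``n_cells``."""
    return (np.arange(center - radius, center + radius + 1) % n_cells).astype(int)


@dataclass(frozen=True)
class Perturbation:
    """One graft / knockdown / fragmentation event.

    ``strength`` is a source rate (concentration/time) for bead and pellet,
    and the knockdown efficiency in [0, 1] for knockdown; it is unused for
    fragmentation, which carries its cut boundaries in ``cuts``.
    """

    kind: str
    target: str = "B"           # ligand (B/V) or factor (FB/FV)
    center: int = 0             # cell index
    radius: int = 3             # extent in cells on each side of center
    strength: float = 0.0
    t_on: float = 0.0
    t_off: float = np.inf
    cuts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind in ("bead", "pellet") and self.target not in LIGANDS:
            raise ValueError(f"{self.kind} target must be a ligand in {LIGANDS}, got {self.target!r}")
        if self.kind == "knockdown":
            if self.target not in FACTORS:
                raise ValueError(f"knockdown target must be a factor in {FACTORS}, got {self.target!r}")
            if not 0.0 <= self.strength <= 1.0:
                raise ValueError(f"knockdown efficiency must be in [0, 1], got {self.strength}")
        elif self.kind != "fragmentation" and self.strength < 0:
            raise ValueError(f"source strength must be non-negative, got {self.strength}")
        if self.radius < 0:
            raise ValueError(f"radius must be non-negative, got {self.radius}")
        if not self.t_on < self.t_off:
            raise ValueError(f"need t_on < t_off, got [{self.t_on}, {self.t_off})")
        if self.kind == "fragmentation" and len(self.cuts) < 1:
            raise ValueError("fragmentation requires at least one cut position")

    def active(self, t: float) -> bool:
        return self.t_on <= t < self.t_off

    def check_extent(self, n_cells: int) -> None:
        if 2 * self.radius + 1 > n_cells:
            raise ValueError(
                f"perturbation footprint 2*{self.radius}+1 exceeds lattice of {n_cells} cells"
            )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "target": self.target, "center": int(self.center),
            "radius": int(self.radius), "strength": float(self.strength),
            "t_on": float(self.t_on),
            "t_off": float(self.t_off) if np.isfinite(self.t_off) else None,
            "cuts": list(self.cuts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Perturbation":
        d = dict(d)
        if d.get("t_off") is None:
            d["t_off"] = np.inf
        d["cuts"] = tuple(d.get("cuts", ()))
        return cls(**d)


def make_bead(center: int, ligand: str, strength: float, radius: int = 3,
              t_on: float = 0.0, t_off: float = np.inf) -> Perturbation:
    """A ligand-soaked bead: constant source ``strength`` for ``ligand`` in
    all cells within ``radius`` of ``center`` during [t_on, t_off)."""
    return Perturbation("bead", target=ligand, center=center, radius=radius,
                        strength=strength, t_on=t_on, t_off=t_off)


def make_pellet(center: int, strength: float, radius: int = 3,
                t_on: float = 0.0, t_off: float = np.inf) -> Perturbation:
    """A pellet of Vg1-secreting cells: a bead fixed to the V ligand."""
    return Perturbation("pellet", target="V", center=center, radius=radius,
                        strength=strength, t_on=t_on, t_off=t_off)


def make_knockdown(factor: str, center: int, radius: int, efficiency: float,
                   t_on: float = 0.0, t_off: float = np.inf) -> Perturbation:
    """Scale the production of ``factor`` ('FB' or 'FV') by
    ``1 - efficiency`` in the covered cells during the window."""
    return Perturbation("knockdown", target=factor, center=center, radius=radius,
                        strength=efficiency, t_on=t_on, t_off=t_off)


def make_fragmentation(cuts, t_on: float = 0.0) -> Perturbation:
    """Seal the ring into arcs at the given inter-cell boundaries at t_on."""
    return Perturbation("fragmentation", target="B", cuts=tuple(int(c) for c in cuts),
                        t_on=t_on, t_off=np.inf)


def assemble_fields(perturbations, t: float, n_cells: int):
    """Source and production-scale fields from the perturbations active at
    time ``t`` (zero-order hold within an integration step).

    Returns ``(src_B, src_V, scale_FB, scale_FV)``; entries are ``None``
    when no active perturbation touches them.  Disjoint sources sum;
    overlapping knockdowns compose multiplicatively.
    """
    src_B = src_V = scale_FB = scale_FV = None
    for p in perturbations:
        if p.kind == "fragmentation" or not p.active(t):
            continue
        p.check_extent(n_cells)
        idx = footprint(p.center, p.radius, n_cells)
        if p.kind in ("bead", "pellet"):
            if p.target == "B":
                if src_B is None:
                    src_B = np.zeros(n_cells)
                src_B[idx] += p.strength
            else:
                if src_V is None:
                    src_V = np.zeros(n_cells)
                src_V[idx] += p.strength
        else:  # knockdown
            if p.target == "FB":
                if scale_FB is None:
                    scale_FB = np.ones(n_cells)
                scale_FB[idx] *= 1.0 - p.strength
            else:
                if scale_FV is None:
                    scale_FV = np.ones(n_cells)
                scale_FV[idx] *= 1.0 - p.strength
    return src_B, src_V, scale_FB, scale_FV
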