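"""Seeded initialization, time integration, and trajectory recording.

Integration is a fixed-step classical 4th-order Runge–Kutta scheme: simple,
bit-reproducible, and adequate for these smooth bounded dynamics (adaptive
stepping was rejected to keep trajectories byte-identical across reruns).
Perturbation source fields are held constant within each step (zero-order
hold, sampled at the step's start time); optional intrinsic noise is applied
after each step as multiplicative lognormal factors ``exp(sigma_dyn *
sqrt(dt) * z)``, which preserves non-negativity without reflection tricks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import rhs
from .params import ModelParameters
from .perturbations import Perturbation, assemble_fields
from .state import EmbryoState

logger = logging.getLogger(__name__)

__all__ = ["TrajectoryRecord", "initialize", "integrate", "apply_fragmentation",
           "IntegrationError"]

#: any field exceeding this aborts the run as numerically unstable
INSTABILITY_CAP = 1e6
#: convergence criterion on the residual max |rhs|
CONVERGENCE_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the fixed-step scheme blows up (dt too large)."""


@dataclass
class TrajectoryRecord:
    """Time-stamped snapshots from one seeded run."""

    params: ModelParameters
    seed: int
    times: list[float] = field(default_factory=list)
    snapshots: list[EmbryoState] = field(default_factory=list)
    events: list[Perturbation] = field(default_factory=list)
    converged: bool = False
    final_residual: float = np.inf

    def append(self, state: EmbryoState) -> None:
        if self.times and state.time <= self.times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        self.times.append(state.time)
        self.snapshots.append(state.copy())

    @property
    def final(self) -> EmbryoState:
        return self.snapshots[-1]


def initialize(
    params: ModelParameters,
    seed: int,
    base: tuple[float, float, float, float],
    cuts: tuple[int, ...] = (),
) -> EmbryoState:
    """Near-homogeneous initial state.

    Every cell's four fields are set to ``base * exp(sigma_init * z)`` with
    independent standard-normal ``z`` from the seeded generator — the
    unavoidable cell-to-cell variability around the ubiquitous-expression
    stage.  ``sigma_init = 0`` yields the exactly homogeneous state.
    """
    base = np.asarray(base, dtype=float)
    if base.shape != (4,):
        raise ValueError("base must be a quadruple (B, V, FB, FV)")
    if np.any(base < 0):
        raise ValueError("base state must be non-negative")
    n = params.n_cells
    if params.sigma_init == 0:
        values = np.repeat(base[:, None], n, axis=1)
    else:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((4, n))
        values = base[:, None] * np.exp(params.sigma_init * z)
    return EmbryoState.from_stacked(values, cuts=cuts, time=0.0)


def apply_fragmentation(state: EmbryoState, cut_positions) -> EmbryoState:
    """Seal the ring (or further divide arcs) at inter-cell boundaries.

    Cell contents are unchanged at the instant of cutting; only the
    paracrine topology changes.  Cut position ``c`` severs the edge between
    cells ``c - 1`` and ``c``.
    """
    cuts = [int(c) % state.n_cells for c in cut_positions]
    if len(set(cuts)) != len(cuts):
        raise ValueError(f"duplicate cut positions: {cut_positions}")
    for c in cut_positions:
        if not 0 <= int(c) < state.n_cells and not -state.n_cells <= int(c):
            raise ValueError(f"cut position {c} out of range")
    merged = tuple(sorted(set(state.cuts) | set(cuts)))
    return EmbryoState(state.B.copy(), state.V.copy(), state.FB.copy(),
                       state.FV.copy(), cuts=merged, time=state.time)


def integrate(
    state: EmbryoState,
    params: ModelParameters,
    perturbations: list[Perturbation] | None = None,
    t_end: float = 500.0,
    dt: float = 0.01,
    record_every: float = 1.0,
    seed: int = 0,
) -> TrajectoryRecord:
    """Advance the system to ``t_end`` (or convergence) and record snapshots.

    Convergence is declared when ``max |rhs| < 1e-6`` with the currently
    active sources — but never while a future perturbation window is still
    pending, so scheduled events always fire.  Fragmentation events reseal
    the topology at their onset time.  Output is bit-reproducible for fixed
    inputs and seed.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    if record_every <= 0:
        raise ValueError("record_every must be positive")
    perturbations = list(perturbations or [])
    rng = np.random.default_rng(seed) if params.sigma_dyn > 0 else None

    record = TrajectoryRecord(params=params, seed=seed, events=perturbations)
    state = state.copy()
    t0 = state.time
    n_steps = int(round((t_end - t0) / dt))
    if n_steps < 1:
        raise ValueError("t_end must exceed the state's current time by at least dt")
    record_stride = max(1, int(round(record_every / dt)))

    # fragmentations fire at the first step boundary >= t_on
    pending_frag = sorted((p for p in perturbations if p.kind == "fragmentation"),
                          key=lambda p: p.t_on)
    for p in perturbations:
        if p.kind != "fragmentation" and p.t_off <= t0:
            logger.info("perturbation %s window ended before start; inert", p)

    for p in pending_frag:
        if p.t_on <= t0:
            state = apply_fragmentation(state, p.cuts)
    pending_frag = [p for p in pending_frag if p.t_on > t0]

    record.append(state)
    last_horizon = max((p.t_on for p in perturbations), default=-np.inf)

    from .model import _rhs_stacked

    y = state.stacked()
    cuts, arcs, is_ring = state.cuts, state.arcs, state.is_ring
    n_cells = state.n_cells

    for step in range(1, n_steps + 1):
        t = t0 + (step - 1) * dt
        while pending_frag and pending_frag[0].t_on <= t:
            state = apply_fragmentation(
                EmbryoState.from_stacked(y, cuts=cuts, time=t),
                pending_frag[0].cuts)
            pending_frag = pending_frag[1:]
            cuts, arcs, is_ring = state.cuts, state.arcs, state.is_ring
        fields = assemble_fields(perturbations, t, n_cells)
        src_B, src_V, scale_FB, scale_FV = fields

        def f(z: np.ndarray) -> np.ndarray:
            return _rhs_stacked(np.clip(z, 0.0, None), params, arcs, is_ring,
                                src_B, src_V, scale_FB, scale_FV)

        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y1 = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

        if not np.all(np.isfinite(y1)) or np.max(y1) > INSTABILITY_CAP:
            bad = np.argwhere(~np.isfinite(y1) | (y1 > INSTABILITY_CAP))
            sp, cell = ("B", "V", "FB", "FV")[bad[0][0]], int(bad[0][1])
            raise IntegrationError(
                f"integration unstable at t={t + dt:.4f}: species {sp}, cell {cell} "
                f"exceeded {INSTABILITY_CAP:g}; reduce dt={dt}"
            )
        neg = float(-y1.min())
        if neg > 1e-9:
            warnings.warn(
                f"clamped negative field of magnitude {neg:.3e} at "
                f"t={t + dt:.4f}", RuntimeWarning, stacklevel=2,
            )
        y = np.clip(y1, 0.0, None)
        if rng is not None:
            y = y * np.exp(params.sigma_dyn * np.sqrt(dt) * rng.standard_normal(y.shape))

        at_record = (step % record_stride == 0) or step == n_steps
        if at_record:
            t_now = t0 + step * dt
            state = EmbryoState.from_stacked(y, cuts=cuts, time=t_now)
            record.append(state)
            fields_now = assemble_fields(perturbations, t_now, n_cells)
            residual = rhs(state, params, *fields_now).max_abs()
            record.final_residual = residual
            no_pending = not pending_frag and t_now >= last_horizon
            if residual < CONVERGENCE_TOL and no_pending and rng is None:
                record.converged = True
                break

    return record
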