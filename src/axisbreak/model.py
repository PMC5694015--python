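"""Core dynamics of the BMP4–Vg1 paracrine network.

Every cell of the marginal-zone ring runs the same four-variable system.
Cells do not sense ligand in their own well only: the *perceived* signal
``S`` of each ligand is the mean over the paracrine window (graph distance
<= coupling_radius, truncated at sealed cuts).  The per-cell right-hand
side is

    dFB/dt = alpha_B * act(S_B; K_BB) * inh(S_V; K_VB)            - delta_F * FB
    dFV/dt = alpha_V * inh(S_B; K_hi)
             * [ act(S_V; K_VV) + c_BV * act(S_B; K_lo) ]         - delta_F * FV
    dB/dt  = beta_B * FB - delta_B * B + src_B
    dV/dt  = beta_V * FV - delta_V * V + src_V

with ``act``/``inh`` Hill activation/inhibition at shared exponent ``n``.
The network encodes: BMP4 induces its own transcription factor F_B; Vg1
represses F_B; Vg1 renews itself through F_V; and BMP4 acts on F_V as a
band-pass — intermediate perceived BMP4 (inside the (K_lo, K_hi) band)
induces F_V while high BMP4 suppresses it.  The band-pass term is what lets
one ligand source both extinguish Vg1 underneath it and ignite Vg1 in its
flanks, and it pins the boundary between the mature BMP4 and Vg1 domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize

from .params import ModelParameters
from .state import EmbryoState

__all__ = [
    "hill_act",
    "hill_inh",
    "perceived_signal",
    "windowed_mean",
    "rhs",
    "Derivatives",
    "homogeneous_steady_states",
    "launch_state",
]


# ---------------------------------------------------------------------------
# Hill terms

def _check_hill_args(x, K, n) -> None:
    if np.any(np.asarray(x) < 0):
        raise ValueError("Hill input concentration must be non-negative")
    if not np.all(np.asarray(K) > 0):
        raise ValueError("Hill constant K must be strictly positive")
    if not np.all(np.asarray(n) >= 1):
        raise ValueError("Hill exponent must be >= 1")


def hill_act(x, K, n):
    """Hill activation ``x^n / (K^n + x^n)``, a fraction in [0, 1]."""
    _check_hill_args(x, K, n)
    x = np.asarray(x, dtype=float)
    # compute via (x/K)^n for scale robustness
    u = (x / K) ** n
    return u / (1.0 + u)


def hill_inh(x, K, n):
    """Hill inhibition ``K^n / (K^n + x^n) = 1 - hill_act(x, K, n)``."""
    _check_hill_args(x, K, n)
    x = np.asarray(x, dtype=float)
    u = (x / K) ** n
    return 1.0 / (1.0 + u)


def hill_act_deriv(x, K, n):
    """d/dx of ``hill_act`` in closed form: n K^n x^(n-1) / (K^n + x^n)^2."""
    _check_hill_args(x, K, n)
    x = np.asarray(x, dtype=float)
    u = (x / K) ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        # n/x * u/(1+u)^2; at x == 0 the derivative is 0 for n > 1, n/K for n == 1
        d = np.where(x > 0, n * u / (np.where(x > 0, x, 1.0) * (1.0 + u) ** 2), 0.0)
    if n == 1:
        d = np.where(x == 0, 1.0 / K, d)
    return d


# ---------------------------------------------------------------------------
# Paracrine perception

@lru_cache(maxsize=32)
def _ring_offsets(n: int, r: int) -> tuple[np.ndarray, ...]:
    """Gather indices for offsets -r..r on a ring of n cells."""
    base = np.arange(n)
    return tuple((base + m) % n for m in range(-r, r + 1))


def _ring_window_mean(values: np.ndarray, r: int) -> np.ndarray:
    # symmetric pairwise accumulation so the result is bitwise equivariant
    # under both rotation and reflection of the ring
    if r == 0:
        return values.copy()
    idx = _ring_offsets(values.shape[0], r)
    acc = values.copy()
    for m in range(1, r + 1):
        acc += values[idx[r + m]] + values[idx[r - m]]
    return acc / (2 * r + 1)


def _arc_window_mean(values: np.ndarray, r: int) -> np.ndarray:
    """Mean over the window truncated at arc ends (mean of available cells)."""
    m = values.shape[0]
    if r == 0:
        return values.copy()
    cs = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(m)
    lo = np.maximum(idx - r, 0)
    hi = np.minimum(idx + r, m - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def windowed_mean(values: np.ndarray, r: int, arcs: list[np.ndarray], is_ring: bool) -> np.ndarray:
    """Window mean of ``values`` respecting topology (wrap on a ring,
    truncation at sealed arc ends)."""
    if r < 0:
        raise ValueError("coupling radius must be non-negative")
    values = np.asarray(values, dtype=float)
    if is_ring:
        return _ring_window_mean(values, r)
    out = np.empty_like(values)
    for arc in arcs:
        out[arc] = _arc_window_mean(values[arc], r)
    return out


def perceived_signal(state: EmbryoState, species: str, r: int) -> np.ndarray:
    """Per-cell perceived ligand level: mean of ``species`` over the
    paracrine window of radius ``r`` around each cell."""
    if species not in ("B", "V"):
        raise ValueError(f"perceived signal is defined for ligands 'B'/'V', got {species!r}")
    return windowed_mean(state.species(species), r, state.arcs, state.is_ring)


# ---------------------------------------------------------------------------
# Right-hand side

@dataclass(frozen=True)
class Derivatives:
    """Per-cell time derivatives of (B, V, FB, FV)."""

    dB: np.ndarray
    dV: np.ndarray
    dFB: np.ndarray
    dFV: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.stack([self.dB, self.dV, self.dFB, self.dFV])

    def max_abs(self) -> float:
        return float(max(np.abs(self.dB).max(), np.abs(self.dV).max(),
                         np.abs(self.dFB).max(), np.abs(self.dFV).max()))


def _hill_act_raw(x: np.ndarray, K: float, n: float) -> np.ndarray:
    u = (x / K) ** n
    return u / (1.0 + u)


def _rhs_stacked(
    y: np.ndarray,
    params: ModelParameters,
    arcs: list[np.ndarray],
    is_ring: bool,
    src_B: np.ndarray | None = None,
    src_V: np.ndarray | None = None,
    scale_FB: np.ndarray | None = None,
    scale_FV: np.ndarray | None = None,
) -> np.ndarray:
    """Right-hand side on a raw (4, n) array (B, V, FB, FV rows).

    Validation-free integrator hot path; ``rhs`` is the checked public
    wrapper around it.
    """
    p = params
    B, V, FB, FV = y
    SB = windowed_mean(B, p.coupling_radius, arcs, is_ring)
    SV = windowed_mean(V, p.coupling_radius, arcs, is_ring)
    nH = p.hill_exponent

    aSB = _hill_act_raw(SB, p.K_BB, nH)
    iSV = 1.0 / (1.0 + (SV / p.K_VB) ** nH)
    prod_FB = p.alpha_B * aSB * iSV
    iSB = 1.0 / (1.0 + (SB / p.K_hi) ** nH)
    prod_FV = p.alpha_V * iSB * (
        _hill_act_raw(SV, p.K_VV, nH) + p.c_BV * _hill_act_raw(SB, p.K_lo, nH)
    )
    if scale_FB is not None:
        prod_FB = prod_FB * scale_FB
    if scale_FV is not None:
        prod_FV = prod_FV * scale_FV

    out = np.empty_like(y)
    out[0] = p.beta_B * FB - p.delta_B * B
    out[1] = p.beta_V * FV - p.delta_V * V
    out[2] = prod_FB - p.delta_F * FB
    out[3] = prod_FV - p.delta_F * FV
    if src_B is not None:
        out[0] += src_B
    if src_V is not None:
        out[1] += src_V
    return out


def rhs(
    state: EmbryoState,
    params: ModelParameters,
    src_B: np.ndarray | None = None,
    src_V: np.ndarray | None = None,
    scale_FB: np.ndarray | None = None,
    scale_FV: np.ndarray | None = None,
) -> Derivatives:
    """Evaluate the model right-hand side.

    ``src_B``/``src_V`` are per-cell ligand source rates (bead and pellet
    grafts); ``scale_FB``/``scale_FV`` multiply the production terms of the
    intracellular factors (knockdowns use ``1 - efficiency``).
    """
    n = state.n_cells
    for name, arr in (("src_B", src_B), ("src_V", src_V),
                      ("scale_FB", scale_FB), ("scale_FV", scale_FV)):
        if arr is not None and np.shape(arr) != (n,):
            raise ValueError(f"{name} must have shape ({n},), got {np.shape(arr)}")
    if src_B is not None and np.any(src_B < 0):
        raise ValueError("ligand sources must be non-negative")
    if src_V is not None and np.any(src_V < 0):
        raise ValueError("ligand sources must be non-negative")

    d = _rhs_stacked(state.stacked(), params, state.arcs, state.is_ring,
                     src_B, src_V, scale_FB, scale_FV)
    return Derivatives(dB=d[0], dV=d[1], dFB=d[2], dFV=d[3])


# ---------------------------------------------------------------------------
# Homogeneous fixed points

def _uniform_rhs(q: np.ndarray, p: ModelParameters) -> np.ndarray:
    """RHS of the uniform (single-cell, S = own ligand level) system."""
    B, V, FB, FV = q
    nH = p.hill_exponent
    B, V = max(B, 0.0), max(V, 0.0)
    prod_FB = p.alpha_B * hill_act(B, p.K_BB, nH) * hill_inh(V, p.K_VB, nH)
    prod_FV = p.alpha_V * hill_inh(B, p.K_hi, nH) * (
        hill_act(V, p.K_VV, nH) + p.c_BV * hill_act(B, p.K_lo, nH)
    )
    return np.array([
        p.beta_B * FB - p.delta_B * B,
        p.beta_V * FV - p.delta_V * V,
        prod_FB - p.delta_F * FB,
        prod_FV - p.delta_F * FV,
    ])


@lru_cache(maxsize=64)
def homogeneous_steady_states(params: ModelParameters) -> tuple[tuple[float, float, float, float], ...]:
    """All non-negative uniform fixed points found by multi-start root search.

    Starts from the zero state, a 14x14 log-spaced (B, V) grid over
    [1e-3, 10]^2 with the factor levels set consistent with the ligand
    balance equations, plus a coarse 4-D corner grid; duplicate roots are
    merged at relative tolerance 1e-6 and each returned root satisfies
    ``max |rhs| < 1e-10``.  The zero state is always included (production
    vanishes at zero for n > 1).  Sorted by B* ascending.
    """
    grid = np.geomspace(1e-3, 10.0, 14)
    starts = [np.zeros(4)]
    for b in grid:
        for v in grid:
            # FB, FV start consistent with the ligand balance equations
            starts.append(np.array([b, v, b * params.delta_B / params.beta_B,
                                    v * params.delta_V / params.beta_V]))
    # full 4-D corners add robustness for stiff parameter sets
    coarse = np.geomspace(1e-3, 10.0, 6)
    for b in coarse[::2]:
        for v in coarse[::2]:
            for fb in coarse[::3]:
                for fv in coarse[::3]:
                    starts.append(np.array([b, v, fb, fv]))

    roots: list[np.ndarray] = [np.zeros(4)]
    for x0 in starts:
        sol = optimize.root(_uniform_rhs, x0, args=(params,), method="hybr")
        if not sol.success:
            continue
        q = sol.x
        if np.any(q < -1e-12):
            continue
        q = np.clip(q, 0.0, None)
        if np.max(np.abs(_uniform_rhs(q, params))) >= 1e-10:
            continue
        scale = np.maximum(np.linalg.norm(q), 1.0)
        if any(np.linalg.norm(q - r) <= 1e-6 * scale for r in roots):
            continue
        roots.append(q)
    roots.sort(key=lambda q: q[0])
    return tuple(tuple(float(x) for x in q) for q in roots)


def launch_state(params: ModelParameters) -> tuple[float, float, float, float]:
    """The 'both-on' uniform fixed point used as the pre-stage-X launch
    condition.

    The ubiquitous-expression stage is a state with both ligands expressed
    that the dynamics can leave: among the fixed points with B* and V* both
    on, prefer the *linearly unstable* ones (largest leading growth rate
    over wavenumbers; the pattern must be able to grow out of it), breaking
    ties toward the largest min(B*, V*).

    Raises ``ValueError`` if the parameter set has no both-on fixed point
    (such a set cannot represent the ubiquitous-expression stage).
    """
    from .stability import mode_spectrum  # deferred: stability imports this module

    states = homogeneous_steady_states(params)
    both_on = [q for q in states if q[0] > 1e-6 and q[1] > 1e-6]
    if not both_on:
        raise ValueError("no uniform fixed point with both BMP4 and Vg1 on; "
                         "parameter set cannot model the pre-patterning stage")
    specs = {q: mode_spectrum(params, q) for q in both_on}
    patterning = [q for q in both_on
                  if specs[q].max_growth_rate > 1e-9 and specs[q].most_unstable_k >= 1]
    unstable = [q for q in both_on if specs[q].max_growth_rate > 1e-9]
    pool = patterning or unstable or both_on
    return max(pool, key=lambda q: min(q[0], q[1]))
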