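"""Idealized circular expression profiles with known ground truth.

These emulate the qualitative expression states seen in early blastodiscs —
ubiquitous (uniform), a single polarized domain (unimodal), two antipodal
domains (bipolar), several axes (k-modal) — so the pattern metrics and the
experiment predicates can be tested without running the simulator.  Bumps
are von-Mises shaped: smooth, circular-native, with an exact centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import EmbryoState

__all__ = ["FixtureSpec", "generate_profile", "generate_state", "bipolar_state"]

KINDS = ("uniform", "unimodal", "bipolar", "k_modal", "step_block")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic circular profile.

    ``kappa`` is the von-Mises concentration (larger = narrower bump);
    ``block_halfwidth`` (cells) applies to ``step_block`` only.  For
    ``bipolar`` the profile holds one bump at ``center`` — pair two specs
    with centers ``separation`` apart via :func:`generate_state`.  For
    ``k_modal``, ``k`` equispaced bumps starting at ``center``.
    """

    kind: str
    n_cells: int = 100
    amplitude: float = 1.0
    baseline: float = 0.0
    center: float = 0.0          # radians
    kappa: float = 8.0
    k: int = 1
    block_halfwidth: int = 5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1 for k_modal fixtures")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _bump(theta: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """Von-Mises-shaped bump normalized to peak 1 at theta = mu."""
    return np.exp(kappa * (np.cos(theta - mu) - 1.0))


def generate_profile(spec: FixtureSpec) -> tuple[np.ndarray, dict]:
    """Generate a per-cell profile plus its ground truth.

    Returns ``(values, truth)`` where ``truth`` holds the number of
    domains and their centroid angles as constructed.
    """
    n = spec.n_cells
    theta = 2.0 * np.pi * np.arange(n) / n
    centers: list[float] = []
    if spec.kind == "uniform":
        values = np.full(n, spec.baseline, dtype=float)
    elif spec.kind == "step_block":
        values = np.full(n, spec.baseline, dtype=float)
        c = int(round(spec.center / (2.0 * np.pi) * n)) % n
        idx = (np.arange(c - spec.block_halfwidth, c + spec.block_halfwidth + 1) % n)
        values[idx] += spec.amplitude
        centers = [2.0 * np.pi * c / n]
    else:
        if spec.kind in ("unimodal", "bipolar"):
            centers = [spec.center % (2.0 * np.pi)]
        else:  # k_modal
            centers = [(spec.center + 2.0 * np.pi * j / spec.k) % (2.0 * np.pi)
                       for j in range(spec.k)]
        values = np.full(n, spec.baseline, dtype=float)
        for mu in centers:
            values += spec.amplitude * _bump(theta, mu, spec.kappa)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = np.clip(values + spec.noise_sd * rng.standard_normal(n), 0.0, None)
    truth = {"n_domains": len(centers), "centroids": centers}
    return values, truth


def generate_state(
    spec_B: FixtureSpec,
    spec_V: FixtureSpec,
    factor_rule: float = 1.0,
) -> EmbryoState:
    """Build a full :class:`EmbryoState` from two profile specs.

    The intracellular factors are set proportional to their ligands
    (``FB = factor_rule * B``, ``FV = factor_rule * V``) — sufficient for
    testing pattern predicates, which read the ligand fields.
    """
    if spec_B.n_cells != spec_V.n_cells:
        raise ValueError("B and V specs must agree on n_cells")
    B, _ = generate_profile(spec_B)
    V, _ = generate_profile(spec_V)
    return EmbryoState(B, V, factor_rule * B, factor_rule * V)


def bipolar_state(
    n_cells: int = 100,
    separation: float = np.pi,
    amplitude: float = 1.0,
    kappa: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EmbryoState:
    """Convenience: antipodal (by default) B and V bumps, the idealized
    stage-X pattern.  The default kappa gives broad complementary gradients
    (strongly anticorrelated), not narrow spots."""
    spec_B = FixtureSpec("unimodal", n_cells=n_cells, amplitude=amplitude,
                         center=0.0, kappa=kappa, noise_sd=noise_sd, seed=seed)
    spec_V = FixtureSpec("unimodal", n_cells=n_cells, amplitude=amplitude,
                         center=separation, kappa=kappa, noise_sd=noise_sd, seed=seed + 1)
    return generate_state(spec_B, spec_V)
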