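"""Model parameters for the BMP4–Vg1 paracrine ring model.

The model is fully dimensionless: time is measured in units of the
intracellular factor lifetime (1/delta_F) and concentrations are scaled to
the Hill constants, so no mapping to hours or protein concentrations is
attempted.  The committed defaults are the parameter set certified by the
calibration sweep in :mod:`axisbreak.battery` against the qualitative
behaviours the model must reproduce (symmetry breaking, bead paradox,
knockdown, fragmentation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = ["ModelParameters", "load_params", "save_params"]


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the paracrine BMP4–Vg1 network on a ring of cells.

    Parameters
    ----------
    n_cells
        Number of cells in the marginal-zone ring.
    coupling_radius
        Paracrine range ``r`` in cells: each cell perceives the mean ligand
        level over the ``2r + 1`` cells within graph distance ``r``.
    hill_exponent
        Cooperativity ``n`` shared by every Hill term (``n >= 1``).
    alpha_B, alpha_V
        Maximal production rates of the intracellular factors F_B and F_V.
    beta_B, beta_V
        Ligand secretion rates per unit of intracellular factor.
    delta_F, delta_B, delta_V
        First-order decay rates of the factors and of the two ligands.
    K_BB
        Half-activation of F_B production by perceived BMP4.
    K_VB
        Half-inhibition of F_B production by perceived Vg1.
    K_VV
        Half-activation of F_V production by perceived Vg1
        (Vg1 self-renewal).
    K_lo, K_hi
        Lower/upper half-saturation of the biphasic BMP4 -> F_V response:
        perceived BMP4 inside the (K_lo, K_hi) band induces F_V, above
        K_hi it suppresses it.  Requires ``K_lo < K_hi``.
    c_BV
        Weight of the band-pass BMP4 -> F_V cross-induction.
    sigma_init
        Relative (lognormal) amplitude of the initial per-cell perturbation
        around the homogeneous launch state.
    sigma_dyn
        Amplitude of optional intrinsic multiplicative noise during
        integration (0 gives deterministic ODE dynamics).
    """

    n_cells: int = 100
    coupling_radius: int = 10
    hill_exponent: float = 6.0
    alpha_B: float = 3.233135888955244
    alpha_V: float = 0.9432649969804745
    beta_B: float = 1.2176672943851108
    beta_V: float = 0.1788605171464307
    delta_F: float = 1.0
    delta_B: float = 4.348482451543753
    delta_V: float = 0.41593543120255383
    K_BB: float = 0.49218012892278307
    K_VB: float = 0.2636171721271673
    K_VV: float = 0.21206378039154036
    K_lo: float = 1.0110964819740043
    K_hi: float = 6.225557218160376
    c_BV: float = 1.0553893245337183
    sigma_init: float = 0.02
    sigma_dyn: float = 0.0

    def __post_init__(self) -> None:
        if int(self.n_cells) != self.n_cells or self.n_cells < 3:
            raise ValueError(f"n_cells must be an integer >= 3, got {self.n_cells}")
        if int(self.coupling_radius) != self.coupling_radius or self.coupling_radius < 0:
            raise ValueError(
                f"coupling_radius must be a non-negative integer, got {self.coupling_radius}"
            )
        if 2 * self.coupling_radius + 1 > self.n_cells:
            raise ValueError(
                "coupling window exceeds ring: need 2*coupling_radius + 1 <= n_cells "
                f"(got r={self.coupling_radius}, n={self.n_cells})"
            )
        if not self.hill_exponent >= 1:
            raise ValueError(f"hill_exponent must be >= 1, got {self.hill_exponent}")
        for name in (
            "alpha_B", "alpha_V", "beta_B", "beta_V",
            "delta_F", "delta_B", "delta_V",
            "K_BB", "K_VB", "K_VV", "K_lo", "K_hi",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for name in ("c_BV", "sigma_init", "sigma_dyn"):
            value = getattr(self, name)
            if not value >= 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if not self.K_lo < self.K_hi:
            raise ValueError(
                f"band-pass ill-formed: require K_lo < K_hi (got K_lo/K_hi = "
                f"{self.K_lo}/{self.K_hi})"
            )

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        """Build parameters from a flat mapping.

        Unknown keys are rejected; missing keys fall back to the committed
        defaults with a logged notice.
        """
        field_names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - field_names
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = field_names - set(data)
        if missing:
            logger.info("parameters %s missing from config; using defaults", sorted(missing))
        return cls(**data)


def load_params(path: str | Path) -> ModelParameters:
    """Load :class:`ModelParameters` from a flat JSON key-value file."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a JSON object of parameter keys")
    return ModelParameters.from_dict(data)


def save_params(params: ModelParameters, path: str | Path) -> None:
    """Write parameters as a flat JSON object (round-trips with load)."""
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
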