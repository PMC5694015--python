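"""Linear stability of uniform states on the ring.

Because the paracrine coupling is a circulant window mean, the Jacobian of
the full 4N system block-diagonalises over discrete wavenumbers
k = 0 .. floor(N/2): each mode sees the single-cell Jacobian with every
derivative that flows through a perceived signal multiplied by the window
transfer factor

    g(k) = (1 / (2r + 1)) * sum_{|m| <= r} cos(2 pi k m / N).

The per-mode leading eigenvalue real parts say how the homogeneous state
loses stability — either at k = 0 (a bistable launch state whose noisy
breakup coarsens into domains) or at some k >= 1 (direct mode selection).
Hill derivatives are evaluated in closed form; finite differences are kept
as the test oracle only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import hill_act, hill_act_deriv, hill_inh, _uniform_rhs
from .params import ModelParameters

__all__ = ["ModeSpectrum", "mode_spectrum", "window_transfer", "uniform_jacobian_parts"]


def window_transfer(k: int | np.ndarray, r: int, n_cells: int) -> np.ndarray:
    """Transfer factor of the (2r+1)-cell window mean at wavenumber k."""
    k = np.asarray(k, dtype=float)
    m = np.arange(-r, r + 1)
    return np.cos(2.0 * np.pi * np.outer(k, m) / n_cells).mean(axis=1).squeeze()


def uniform_jacobian_parts(params: ModelParameters, state4) -> tuple[np.ndarray, np.ndarray]:
    """Split the single-cell Jacobian at a uniform state into the local part
    and the part acting through perceived signals.

    Variable order is (B, V, FB, FV).  Returns ``(J_local, J_signal)``; the
    per-mode matrix is ``J_local + g(k) * J_signal``.
    """
    B, V, FB, FV = (float(x) for x in state4)
    p = params
    n = p.hill_exponent

    aB = hill_act(B, p.K_BB, n)
    iV = hill_inh(V, p.K_VB, n)
    iB_hi = hill_inh(B, p.K_hi, n)
    aV = hill_act(V, p.K_VV, n)
    aB_lo = hill_act(B, p.K_lo, n)

    d_aB = hill_act_deriv(B, p.K_BB, n)
    d_iV = -hill_act_deriv(V, p.K_VB, n)
    d_iB_hi = -hill_act_deriv(B, p.K_hi, n)
    d_aV = hill_act_deriv(V, p.K_VV, n)
    d_aB_lo = hill_act_deriv(B, p.K_lo, n)

    J_local = np.array([
        [-p.delta_B, 0.0, p.beta_B, 0.0],
        [0.0, -p.delta_V, 0.0, p.beta_V],
        [0.0, 0.0, -p.delta_F, 0.0],
        [0.0, 0.0, 0.0, -p.delta_F],
    ])
    # production terms respond to the *perceived* ligands
    dFB_dSB = p.alpha_B * d_aB * iV
    dFB_dSV = p.alpha_B * aB * d_iV
    dFV_dSB = p.alpha_V * (d_iB_hi * (aV + p.c_BV * aB_lo) + iB_hi * p.c_BV * d_aB_lo)
    dFV_dSV = p.alpha_V * iB_hi * d_aV
    J_signal = np.zeros((4, 4))
    J_signal[2, 0] = dFB_dSB
    J_signal[2, 1] = dFB_dSV
    J_signal[3, 0] = dFV_dSB
    J_signal[3, 1] = dFV_dSV
    return J_local, J_signal


@dataclass(frozen=True)
class ModeSpectrum:
    """Leading growth rate per wavenumber around a uniform fixed point."""

    steady_state: tuple[float, float, float, float]
    wavenumbers: np.ndarray
    growth_rates: np.ndarray

    @property
    def most_unstable_k(self) -> int:
        return int(self.wavenumbers[int(np.argmax(self.growth_rates))])

    @property
    def max_growth_rate(self) -> float:
        return float(self.growth_rates.max())

    def mode_matrix(self, params: ModelParameters, k: int) -> np.ndarray:
        J_local, J_signal = uniform_jacobian_parts(params, self.steady_state)
        g = window_transfer(k, params.coupling_radius, params.n_cells)
        return J_local + float(g) * J_signal


def mode_spectrum(params: ModelParameters, state4) -> ModeSpectrum:
    """Per-wavenumber leading growth rates around a uniform fixed point.

    ``state4`` must be a verified uniform fixed point (residual of the
    uniform system below 1e-8).
    """
    q = np.asarray(state4, dtype=float)
    residual = np.max(np.abs(_uniform_rhs(q, params)))
    if residual >= 1e-8:
        raise ValueError(
            f"state is not a uniform fixed point (residual {residual:.2e} >= 1e-8)"
        )
    J_local, J_signal = uniform_jacobian_parts(params, q)
    ks = np.arange(params.n_cells // 2 + 1)
    rates = np.empty(ks.size)
    for i, k in enumerate(ks):
        g = float(window_transfer(int(k), params.coupling_radius, params.n_cells))
        eigs = np.linalg.eigvals(J_local + g * J_signal)
        rates[i] = eigs.real.max()
    return ModeSpectrum(steady_state=tuple(float(x) for x in q),
                        wavenumbers=ks, growth_rates=rates)
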