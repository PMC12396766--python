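"""Closed-form reference solutions used to verify the solver.

These are independent analytic results (Hagen–Poiseuille, Womersley);
nothing in the numerical path uses them.
"""

from __future__ import annotations

import numpy as np
from scipy.special import jv

__all__ = ["poiseuille_profile", "poiseuille_wss", "womersley_solution"]


def poiseuille_profile(r, radius_m, v_mean):
    """Fully developed laminar tube profile u(r) = 2 v_mean (1 - r^2/R^2)."""
    return 2.0 * v_mean * (1.0 - (np.asarray(r) / radius_m) ** 2)


def poiseuille_wss(q_m3s, radius_m, mu=4e-3):
    """Wall shear stress 4 mu Q / (pi R^3) of laminar tube flow."""
    return 4.0 * mu * q_m3s / (np.pi * radius_m**3)


def womersley_solution(radius_m, mean_gradient, osc_gradient, omega,
                       rho=1040.0, mu=4e-3):
    """Pulsatile tube flow for pressure gradient G0 + G1 cos(wt).

    Returns ``(u(r, t), alpha)``: the superposition of the steady
    Poiseuille solution and the oscillatory Womersley (Bessel-function)
    solution, and the Womersley number alpha = R sqrt(w/nu).
    """
    nu = mu / rho
    alpha = radius_m * np.sqrt(omega / nu)
    beta = 1j**1.5 * alpha

    def u(r, t):
        r = np.asarray(r)
        steady = mean_gradient / (4 * mu) * (radius_m**2 - r**2)
        osc = np.real(
            1j * osc_gradient / (rho * omega)
            * (1 - jv(0, beta * r / radius_m) / jv(0, beta))
            * np.exp(1j * omega * t)
        )
        return steady + osc

    return u, alpha
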