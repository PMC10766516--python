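"""Working variables of the nonseparable functional form.

Per spin channel sigma the polynomial in the exchange-like term runs over

* ``v_sigma = omega_x rho_sigma^(1/3) / (1 + omega_x rho_sigma^(1/3))`` --
  a bounded monotone transform of the density,
* ``u_sigma = gamma_x s_sigma^2 / (1 + gamma_x s_sigma^2)`` with the reduced
  spin gradient ``s_sigma = |grad rho_sigma| / rho_sigma^(4/3)``,
* ``w_sigma = (tau_sigma^unif - tau_sigma) / (tau_sigma^unif + tau_sigma)``
  with ``tau_sigma^unif = (3/10)(6 pi^2)^(2/3) rho_sigma^(5/3)`` the
  uniform-gas kinetic-energy density,

while the correlation series use the total-density analogue
``w(rho, tau)`` built from ``tau^unif = (3/10)(3 pi^2)^(2/3) rho^(5/3)``.

The constants gamma_x and omega_x are not defaulted in code: they are read
from the shipped ingredient-constants file (``cf22d.xc.params.default_ingredient_constants``),
into which the published values of the parent functional family were
transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..units import DENSITY_FLOOR
from ..density import DensityIngredients
from .lsda import eps_x_lsda, eps_c_lsda
from .pbe import h_pbe, PBE_BETA, PBE_GAMMA

__all__ = ["IngredientFunctions", "WorkingVariables", "working_variables"]

_CTAU_SPIN = 0.3 * (6.0 * np.pi**2) ** (2.0 / 3.0)
_CTAU_TOTAL = 0.3 * (3.0 * np.pi**2) ** (2.0 / 3.0)


@dataclass(frozen=True)
class IngredientFunctions:
    """Configuration of the ingredient functions entering the descriptors.

    Parameters
    ----------
    gamma_x, omega_x : float
        Constants of the bounded u/v transforms (dimensionless and
        bohr-dimensioned respectively); supplied by the ingredient-constants
        file, never defaulted here.
    correlation : str
        LSDA correlation parameterization, ``"pw92"`` or ``"vwn5"``.
    pbe_beta, pbe_gamma : float
        Constants of the PBE gradient correction.
    floor : float
        Vacuum threshold on the spin densities.
    """

    gamma_x: float
    omega_x: float
    correlation: str = "pw92"
    pbe_beta: float = PBE_BETA
    pbe_gamma: float = PBE_GAMMA
    floor: float = DENSITY_FLOOR

    def __post_init__(self) -> None:
        if self.gamma_x <= 0 or self.omega_x <= 0:
            raise ValueError("gamma_x and omega_x must be positive")

    def eps_x(self, rho_sigma: np.ndarray) -> np.ndarray:
        return eps_x_lsda(rho_sigma)

    def eps_c(self, rho_a: np.ndarray, rho_b: np.ndarray) -> np.ndarray:
        return eps_c_lsda(rho_a, rho_b, self.correlation, self.floor)

    def h_pbe(self, rho_a, rho_b, grad_rho) -> np.ndarray:
        return h_pbe(
            rho_a, rho_b, grad_rho,
            parameterization=self.correlation,
            beta=self.pbe_beta, gamma=self.pbe_gamma, floor=self.floor,
        )

    def u_x(self, s_sigma: np.ndarray) -> np.ndarray:
        g = self.gamma_x * s_sigma**2
        return g / (1.0 + g)

    def v_x(self, rho_sigma: np.ndarray) -> np.ndarray:
        t = self.omega_x * np.cbrt(rho_sigma)
        return t / (1.0 + t)


@dataclass(frozen=True)
class WorkingVariables:
    """Per-point working variables for both spin channels."""

    s_a: np.ndarray
    s_b: np.ndarray
    u_a: np.ndarray
    u_b: np.ndarray
    v_a: np.ndarray
    v_b: np.ndarray
    w_a: np.ndarray
    w_b: np.ndarray
    w_total: np.ndarray


def _w_from(tau_unif: np.ndarray, tau: np.ndarray, ok: np.ndarray) -> np.ndarray:
    den = tau_unif + tau
    den = np.where(den > 0, den, 1.0)
    return np.where(ok, (tau_unif - tau) / den, 0.0)


def working_variables(ing: DensityIngredients, funcs: IngredientFunctions) -> WorkingVariables:
    """Evaluate s, u, v, w for each spin and w for the total density.

    Zero-density points take the rho -> 0 limits: s = u = v = w = 0.
    """
    out = {}
    for sig, rho, grad, tau in (
        ("a", ing.rho_a, ing.grad_a, ing.tau_a),
        ("b", ing.rho_b, ing.grad_b, ing.tau_b),
    ):
        if np.any(rho < 0) or np.any(tau < 0):
            raise ValueError("densities and kinetic-energy densities must be non-negative")
        ok = rho > funcs.floor
        rho_s = np.where(ok, rho, 1.0)
        s = np.where(ok, grad / rho_s ** (4.0 / 3.0), 0.0)
        tau_unif = _CTAU_SPIN * rho_s ** (5.0 / 3.0)
        out["s_" + sig] = s
        out["u_" + sig] = np.where(ok, funcs.u_x(s), 0.0)
        out["v_" + sig] = np.where(ok, funcs.v_x(rho), 0.0)
        out["w_" + sig] = _w_from(tau_unif, np.where(ok, tau, 0.0), ok)
    rho_t = ing.rho
    ok_t = rho_t > funcs.floor
    tau_unif_t = _CTAU_TOTAL * np.where(ok_t, rho_t, 1.0) ** (5.0 / 3.0)
    out["w_total"] = _w_from(tau_unif_t, np.where(ok_t, ing.tau, 0.0), ok_t)
    return WorkingVariables(**out)
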