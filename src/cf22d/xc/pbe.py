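"""PBE gradient correction to the correlation energy.

H^PBE(rho_a, rho_b, |grad rho|) is the standard gradient correction with
beta = 0.066725 and gamma = (1 - ln 2) / pi^2; both constants are exposed so
variants can be configured.
"""

from __future__ import annotations

import numpy as np

from .lsda import eps_c_lsda

__all__ = ["h_pbe", "PBE_BETA", "PBE_GAMMA"]

PBE_BETA = 0.066725
PBE_GAMMA = (1.0 - np.log(2.0)) / np.pi**2


def h_pbe(
    rho_a: np.ndarray,
    rho_b: np.ndarray,
    grad_rho: np.ndarray,
    parameterization: str = "pw92",
    beta: float = PBE_BETA,
    gamma: float = PBE_GAMMA,
    floor: float = 1e-30,
) -> np.ndarray:
    """Gradient correction per electron (hartree); 0 in vacuum."""
    rho_a = np.asarray(rho_a, float)
    rho_b = np.asarray(rho_b, float)
    grad_rho = np.asarray(grad_rho, float)
    rho = rho_a + rho_b
    ok = rho > floor
    rho_s = np.where(ok, rho, 1.0)
    zeta = np.clip(np.where(ok, (rho_a - rho_b) / rho_s, 0.0), -1.0, 1.0)
    phi = 0.5 * ((1.0 + zeta) ** (2.0 / 3.0) + (1.0 - zeta) ** (2.0 / 3.0))
    kf = (3.0 * np.pi**2 * rho_s) ** (1.0 / 3.0)
    ks = np.sqrt(4.0 * kf / np.pi)
    t2 = (grad_rho / (2.0 * phi * ks * rho_s)) ** 2
    ec = eps_c_lsda(rho_a, rho_b, parameterization, floor)
    gp3 = gamma * phi**3
    # A -> infinity as ec -> 0-; work through expm1 and take limits explicitly
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        A = beta / gamma / np.expm1(np.clip(-ec / gp3, 1e-300, 500.0))
        x = A * t2
        q = beta / gamma * t2 * (1.0 + x) / (1.0 + x + x * x)
        # for A t^2 >> 1 the rational factor tends to 1/A, i.e. q -> expm1(-ec/(g p^3))
        q_lim = beta / gamma / A
        q = np.where(x > 1e12, q_lim, q)
        q = np.where(np.isfinite(q), q, 0.0)
    H = gp3 * np.log1p(q)
    return np.where(ok, H, 0.0)
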