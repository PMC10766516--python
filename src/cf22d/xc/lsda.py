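"""Local spin-density ingredient functions.

Spin-resolved Dirac/Slater exchange energy density per electron and the
uniform-electron-gas correlation energy per electron in either the
Perdew-Wang 1992 (default) or the VWN5 parameterization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["eps_x_lsda", "eps_c_lsda", "CORRELATION_PARAMETERIZATIONS"]

# eps_x,sigma = -(3/2) (3/(4 pi))^(1/3) rho_sigma^(1/3); with the rho_sigma
# prefactor this integrates to the spin-scaled LSDA exchange energy.
_CX = 1.5 * (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def eps_x_lsda(rho_sigma: np.ndarray) -> np.ndarray:
    """Spin-resolved LSDA exchange energy per electron (hartree)."""
    return -_CX * np.cbrt(rho_sigma)


def _rs_zeta(rho_a: np.ndarray, rho_b: np.ndarray, floor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rho = rho_a + rho_b
    ok = rho > floor
    rho_safe = np.where(ok, rho, 1.0)
    rs = (3.0 / (4.0 * np.pi * rho_safe)) ** (1.0 / 3.0)
    zeta = np.where(ok, (rho_a - rho_b) / rho_safe, 0.0)
    zeta = np.clip(zeta, -1.0, 1.0)
    return rs, zeta, ok


def _f_zeta(zeta: np.ndarray) -> np.ndarray:
    return ((1.0 + zeta) ** (4.0 / 3.0) + (1.0 - zeta) ** (4.0 / 3.0) - 2.0) / (
        2.0 ** (4.0 / 3.0) - 2.0
    )


_FPP0 = 4.0 / (9.0 * (2.0 ** (1.0 / 3.0) - 1.0))  # f''(0)


# --- Perdew-Wang 1992 -------------------------------------------------------

_PW92 = {
    # A, alpha1, beta1, beta2, beta3, beta4
    "ec0": (0.031091, 0.21370, 7.5957, 3.5876, 1.6382, 0.49294),
    "ec1": (0.015545, 0.20548, 14.1189, 6.1977, 3.3662, 0.62517),
    "mac": (0.016887, 0.11125, 10.357, 3.6231, 0.88026, 0.49671),
}


def _pw92_g(rs: np.ndarray, p: tuple[float, ...]) -> np.ndarray:
    A, a1, b1, b2, b3, b4 = p
    srs = np.sqrt(rs)
    den = 2.0 * A * (b1 * srs + b2 * rs + b3 * rs * srs + b4 * rs * rs)
    return -2.0 * A * (1.0 + a1 * rs) * np.log1p(1.0 / den)


def _eps_c_pw92(rs: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    ec0 = _pw92_g(rs, _PW92["ec0"])
    ec1 = _pw92_g(rs, _PW92["ec1"])
    alc = -_pw92_g(rs, _PW92["mac"])  # spin stiffness
    f = _f_zeta(zeta)
    z4 = zeta**4
    return ec0 + alc * f / _FPP0 * (1.0 - z4) + (ec1 - ec0) * f * z4


# --- VWN5 -------------------------------------------------------------------

_VWN5 = {
    # A, b, c, x0
    "para": (0.0310907, 3.72744, 12.9352, -0.10498),
    "ferro": (0.01554535, 7.06042, 18.0578, -0.32500),
    "stiff": (-1.0 / (6.0 * np.pi**2), 1.13107, 13.0045, -0.00475840),
}


def _vwn_eps(rs: np.ndarray, p: tuple[float, ...]) -> np.ndarray:
    A, b, c, x0 = p
    x = np.sqrt(rs)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    Q = np.sqrt(4.0 * c - b * b)
    atn = np.arctan(Q / (2.0 * x + b))
    return A * (
        np.log(x * x / X)
        + 2.0 * b / Q * atn
        - b * x0 / X0 * (np.log((x - x0) ** 2 / X) + 2.0 * (b + 2.0 * x0) / Q * atn)
    )


def _eps_c_vwn5(rs: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    ep = _vwn_eps(rs, _VWN5["para"])
    ef = _vwn_eps(rs, _VWN5["ferro"])
    al = _vwn_eps(rs, _VWN5["stiff"])
    f = _f_zeta(zeta)
    z4 = zeta**4
    return ep + al * f / _FPP0 * (1.0 - z4) + (ef - ep) * f * z4


CORRELATION_PARAMETERIZATIONS = {"pw92": _eps_c_pw92, "vwn5": _eps_c_vwn5}


def eps_c_lsda(
    rho_a: np.ndarray,
    rho_b: np.ndarray,
    parameterization: str = "pw92",
    floor: float = 1e-30,
) -> np.ndarray:
    """LSDA correlation energy per electron (hartree); 0 in vacuum."""
    try:
        fn = CORRELATION_PARAMETERIZATIONS[parameterization]
    except KeyError:
        raise ValueError(
            f"unknown correlation parameterization {parameterization!r}; "
            f"choose from {sorted(CORRELATION_PARAMETERIZATIONS)}"
        ) from None
    rs, zeta, ok = _rs_zeta(np.asarray(rho_a, float), np.asarray(rho_b, float), floor)
    return np.where(ok, fn(rs, zeta), 0.0)
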