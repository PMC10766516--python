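"""Damped C6 pair-sum dispersion energy and dimer curves.

E_disp = -1/2 sum_{A != B} C6^AB / r_AB^6 * f_d6(r_AB), implemented as a
plain sum over unordered pairs (the 1/2 corrects ordered-pair double
counting).  Distances are converted angstrom -> bohr inside the r^-6
kernel so C6 in hartree*bohr^6 yields hartree; the damping function runs on
the angstrom scale of the R0 tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..units import BOHR_PER_ANGSTROM
from .geometry import GeometrySpec
from .cn import CoordinationModel, coordination_numbers
from .c6 import C6Provider, pair_key
from .damping import damping_factor

__all__ = ["DispersionParams", "dispersion_energy", "dimer_curve"]

#: pairs beyond this separation (angstrom) contribute < 1e-15 of a typical
#: term and are skipped.
DEFAULT_CUTOFF = 50.0

#: final range parameter of the trained functional (dimensionless multiplier
#: of the angstrom-scale cutoff radii).
DEFAULT_SR6 = 1.53


@dataclass(frozen=True)
class DispersionParams:
    """Range scaling s_r6, pair cutoff radii R0 (angstrom), C6 provider."""

    sr6: float
    r0_table: Mapping[tuple[str, str], float]
    c6_provider: C6Provider
    cn_model: CoordinationModel | None = None
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.sr6 <= 0:
            raise ValueError("sr6 must be positive")
        norm = {}
        for (a, b), v in self.r0_table.items():
            if v <= 0:
                raise ValueError(f"R0({a},{b}) must be positive")
            norm[pair_key(a, b)] = float(v)
        object.__setattr__(self, "r0_table", norm)

    def r0(self, a: str, b: str) -> float:
        try:
            return self.r0_table[pair_key(a, b)]
        except KeyError:
            raise KeyError(f"no R0 entry for pair ({a}, {b})") from None

    def with_sr6(self, sr6: float) -> "DispersionParams":
        return DispersionParams(sr6, self.r0_table, self.c6_provider, self.cn_model, self.cutoff)


def dispersion_energy(geom: GeometrySpec, params: DispersionParams) -> float:
    """Damped pair-sum dispersion energy (hartree); 0 for a single atom."""
    n = geom.n_atoms
    if n == 1:
        return 0.0
    if params.cn_model is not None:
        cn = coordination_numbers(geom, params.cn_model)
    else:
        cn = np.zeros(n)
    d = geom.distance_matrix()
    e = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            r = d[a, b]
            if r > params.cutoff:
                continue
            sa, sb = geom.symbols[a], geom.symbols[b]
            c6 = params.c6_provider.c6(sa, sb, float(cn[a]), float(cn[b]))
            f = damping_factor(r, params.r0(sa, sb), params.sr6)
            r_bohr = r * BOHR_PER_ANGSTROM
            e -= c6 / r_bohr**6 * f
    return e


def dimer_curve(
    fragment_a: GeometrySpec,
    fragment_b: GeometrySpec,
    separations,
    params: DispersionParams,
    axis=(0.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Inter-fragment dispersion of a rigid-fragment displacement scan.

    Fragment B is displaced along ``axis`` (unit-normalised) by each
    separation increment (angstrom) from its reference position.  The
    reported value is the interaction contribution
    E(dimer) - E(A) - E(B), so it decays to zero at large separation;
    the returned frame has columns ``separation`` and ``e_disp`` (hartree).
    """
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("axis must be a nonzero vector")
    axis = axis / nrm
    e_a = dispersion_energy(fragment_a, params)
    e_b = dispersion_energy(fragment_b, params)
    rows = []
    for sep in separations:
        dimer = fragment_a.merged(fragment_b.translated(axis * float(sep)))
        na = fragment_a.n_atoms
        inter = dimer.distance_matrix()[:na, na:]
        if inter.min() < 0.5:
            raise ValueError(f"fragment clash at separation {sep} (r < 0.5 angstrom)")
        rows.append((float(sep), dispersion_energy(dimer, params) - e_a - e_b))
    return pd.DataFrame(rows, columns=["separation", "e_disp"])
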