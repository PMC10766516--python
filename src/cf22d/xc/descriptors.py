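"""Descriptor integrals: the energy as a linear form in the coefficients.

With the working variables fixed by the density, every trainable coefficient
multiplies one quadrature integral:

* ``d_a[(i,j,k)] = sum_sigma int rho_sigma eps_x,sigma^LSDA v_sigma^i
  u_sigma^j w_sigma^k``  (40 terms),
* ``d_b[i] = int rho eps_C^LSDA w(rho,tau)^i``  (9 terms),
* ``d_c[i] = int rho H^PBE w(rho,tau)^i``  (9 terms),

plus one slot for the supplied single-determinant exchange energy.  The
total gradient norm entering H^PBE is taken as ``|grad rho_a| + |grad
rho_b|`` (exact whenever the spin gradients are parallel, in particular for
closed shells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grids import QuadratureGrid
from ..density import DensityIngredients
from .indices import enumerate_a_indices, N_A_TERMS, N_B_TERMS, N_C_TERMS
from .working import IngredientFunctions, working_variables

__all__ = ["DescriptorVector", "descriptor_integrals"]


@dataclass(frozen=True)
class DescriptorVector:
    """The 40 + 9 + 9 descriptor integrals plus the HF-exchange slot.

    ``d_a`` follows the canonical lexicographic (i, j, k) order of
    :func:`cf22d.xc.indices.enumerate_a_indices`.  All entries in hartree.
    ``e_hf`` may be NaN while unset.
    """

    d_a: np.ndarray
    d_b: np.ndarray
    d_c: np.ndarray
    e_hf: float = float("nan")

    def __post_init__(self) -> None:
        for name, n in (("d_a", N_A_TERMS), ("d_b", N_B_TERMS), ("d_c", N_C_TERMS)):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            object.__setattr__(self, name, arr)

    def with_e_hf(self, e_hf: float) -> "DescriptorVector":
        return DescriptorVector(self.d_a, self.d_b, self.d_c, float(e_hf))

    def stacked(self) -> np.ndarray:
        """(e_hf/100, d_a, d_b, d_c) as one length-59 design row.

        The first entry is scaled so it multiplies X directly.
        """
        if not np.isfinite(self.e_hf):
            raise ValueError("e_hf is unset")
        return np.concatenate([[self.e_hf / 100.0], self.d_a, self.d_b, self.d_c])


def descriptor_integrals(
    grid: QuadratureGrid,
    ing: DensityIngredients,
    funcs: IngredientFunctions,
) -> DescriptorVector:
    """Quadrature of all descriptor integrands over the grid."""
    if grid.size != ing.size:
        raise ValueError("grid and ingredients are not aligned")
    wv = working_variables(ing, funcs)
    w = grid.weights

    d_a = np.zeros(N_A_TERMS)
    for rho, eps, vv, uu, ww in (
        (ing.rho_a, funcs.eps_x(ing.rho_a), wv.v_a, wv.u_a, wv.w_a),
        (ing.rho_b, funcs.eps_x(ing.rho_b), wv.v_b, wv.u_b, wv.w_b),
    ):
        base = w * rho * eps
        # cumulative powers, reused across the 40 terms
        vpow = {i: vv**i for i in range(4)}
        upow = {j: uu**j for j in range(4)}
        wpow = {k: ww**k for k in range(6)}
        for idx, (i, j, k) in enumerate(enumerate_a_indices()):
            d_a[idx] += float(np.sum(base * vpow[i] * upow[j] * wpow[k]))

    rho_t = ing.rho
    grad_t = ing.grad_a + ing.grad_b
    ec = funcs.eps_c(ing.rho_a, ing.rho_b)
    hp = funcs.h_pbe(ing.rho_a, ing.rho_b, grad_t)
    wt_pow = {i: wv.w_total**i for i in range(9)}
    d_b = np.array([float(np.sum(w * rho_t * ec * wt_pow[i])) for i in range(N_B_TERMS)])
    d_c = np.array([float(np.sum(w * rho_t * hp * wt_pow[i])) for i in range(N_C_TERMS)])
    return DescriptorVector(d_a, d_b, d_c)
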