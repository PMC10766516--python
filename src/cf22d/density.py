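"""Analytic Gaussian density ingredients.

Species are described by normalised s-type Gaussian orbitals, one per shell,
with fixed per-spin occupations.  From those the six ingredient arrays the
functional needs -- rho_sigma, |grad rho_sigma| and the kinetic-energy
densities tau_sigma -- follow in closed form, so the functional can be
evaluated and trained without an electronic-structure code.

tau uses the Minnesota-family convention tau_sigma = 1/2 sum_i
|grad psi_{i,sigma}|^2 (see :data:`cf22d.units.TAU_CONVENTION_FACTOR`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .grids import QuadratureGrid
from .units import TAU_CONVENTION_FACTOR

__all__ = [
    "GaussianShellSpec",
    "DensityIngredients",
    "gaussian_ingredients",
    "write_ingredient_file",
    "read_ingredient_file",
]


@dataclass(frozen=True)
class GaussianShellSpec:
    """One normalised s-Gaussian orbital with per-spin occupations."""

    center: tuple[float, float, float]  # bohr
    exponent: float  # bohr^-2
    occupation: tuple[float, float]  # electrons (up, down)

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("Gaussian exponent must be positive")
        if min(self.occupation) < 0:
            raise ValueError("occupations must be non-negative")

    @property
    def norm(self) -> float:
        """Normalisation constant of exp(-alpha r^2) so that <phi|phi> = 1."""
        return (2.0 * self.exponent / np.pi) ** 0.75


@dataclass(frozen=True)
class DensityIngredients:
    """Per-point density features aligned to a quadrature grid.

    All quantities in atomic units: densities bohr^-3, gradient norms
    bohr^-4, kinetic-energy densities hartree*bohr^-3.
    """

    rho_a: np.ndarray
    rho_b: np.ndarray
    grad_a: np.ndarray
    grad_b: np.ndarray
    tau_a: np.ndarray
    tau_b: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("rho_a", "rho_b", "grad_a", "grad_b", "tau_a", "tau_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("ingredient arrays must share one grid")
            arrays[name] = arr
        for name in ("rho_a", "rho_b", "tau_a", "tau_b"):
            if np.any(arrays[name] < 0):
                raise ValueError(f"{name} must be non-negative everywhere")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    @property
    def size(self) -> int:
        return self.rho_a.shape[0]

    @property
    def rho(self) -> np.ndarray:
        return self.rho_a + self.rho_b

    @property
    def tau(self) -> np.ndarray:
        return self.tau_a + self.tau_b

    def electron_count(self, grid: QuadratureGrid) -> float:
        return grid.integrate(self.rho)


def gaussian_ingredients(
    shells: Sequence[GaussianShellSpec] | Iterable[GaussianShellSpec],
    grid: QuadratureGrid,
) -> DensityIngredients:
    """Evaluate the analytic ingredients of a set of Gaussian shells.

    Each shell contributes an independently occupied orbital, so
    rho_sigma = sum_s occ_s,sigma phi_s^2 and the gradient is the norm of the
    summed density-gradient vector (orbital cross terms vanish because the
    orbitals are treated as separately occupied).
    """
    shells = list(shells)
    if not shells:
        raise ValueError("at least one shell is required")
    pts = grid.points
    n = pts.shape[0]
    rho = np.zeros((2, n))
    grad_vec = np.zeros((2, n, 3))
    tau = np.zeros((2, n))
    for sh in shells:
        d = pts - np.asarray(sh.center, dtype=float)
        r2 = np.einsum("ij,ij->i", d, d)
        phi2 = sh.norm**2 * np.exp(-2.0 * sh.exponent * r2)
        # grad(phi^2) = -4 alpha (r - R) phi^2 ; |grad phi|^2 = 4 alpha^2 r^2 phi^2
        gphi2 = -4.0 * sh.exponent * d * phi2[:, None]
        tphi = TAU_CONVENTION_FACTOR * 4.0 * sh.exponent**2 * r2 * phi2
        for s in (0, 1):
            occ = sh.occupation[s]
            if occ == 0.0:
                continue
            rho[s] += occ * phi2
            grad_vec[s] += occ * gphi2
            tau[s] += occ * tphi
    grad = np.linalg.norm(grad_vec, axis=2)
    return DensityIngredients(rho[0], rho[1], grad[0], grad[1], tau[0], tau[1])


# ---------------------------------------------------------------------------
# Columnar grid-ingredient files:
#   x y z weight rho_a rho_b grad_a grad_b tau_a tau_b   (atomic units)
# '#' lines are comments.  Values are written with 17 significant digits so
# read(write(x)) is bit-identical.
# ---------------------------------------------------------------------------

_COLUMNS = "x y z weight rho_a rho_b grad_a grad_b tau_a tau_b"


def write_ingredient_file(path, grid: QuadratureGrid, ing: DensityIngredients) -> None:
    if grid.size != ing.size:
        raise ValueError("grid and ingredients are not aligned")
    data = np.column_stack(
        [grid.points, grid.weights, ing.rho_a, ing.rho_b, ing.grad_a, ing.grad_b, ing.tau_a, ing.tau_b]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_COLUMNS}\n")
        for row in data:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_ingredient_file(path) -> tuple[QuadratureGrid, DensityIngredients]:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 10:
        raise ValueError(f"expected 10 columns ({_COLUMNS}), got {data.shape[1]}")
    grid = QuadratureGrid(data[:, :3], data[:, 3])
    ing = DensityIngredients(*(data[:, i] for i in range(4, 10)))
    return grid, ing
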