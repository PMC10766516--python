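"""Smooth atomic coordination numbers.

CN_A = sum_{B != A} 1 / (1 + exp(-k1 (k2 (R_A + R_B) / r_AB - 1))) with
covalent radii R and the published counting constants k1 = 16 and
k2 = 4/3.  The count is smooth in the geometry, non-negative, and decays to
zero as all neighbours recede.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import GeometrySpec

__all__ = ["CoordinationModel", "coordination_numbers"]


@dataclass(frozen=True)
class CoordinationModel:
    """Covalent radii (angstrom) and counting-function constants."""

    covalent_radii: Mapping[str, float]
    k1: float = 16.0
    k2: float = 4.0 / 3.0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.covalent_radii.values()):
            raise ValueError("covalent radii must be positive")

    def radius(self, element: str) -> float:
        try:
            return self.covalent_radii[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} missing from the covalent-radii table"
            ) from None


def coordination_numbers(geom: GeometrySpec, model: CoordinationModel) -> np.ndarray:
    """Coordination number per atom."""
    n = geom.n_atoms
    cn = np.zeros(n)
    if n == 1:
        return cn
    radii = np.array([model.radius(s) for s in geom.symbols])
    d = geom.distance_matrix()
    rsum = radii[:, None] + radii[None, :]
    with np.errstate(over="ignore"):
        counts = 1.0 / (1.0 + np.exp(-model.k1 * (model.k2 * rsum / np.where(d > 0, d, 1.0) - 1.0)))
    np.fill_diagonal(counts, 0.0)
    return counts.sum(axis=1)
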