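"""C6 coefficient providers.

Two interchangeable providers supply the pair coefficient
C6^AB(CN_A, CN_B) in hartree*bohr^6:

* :class:`FixedPairC6` -- a symmetric per-pair table, ignoring coordination
  numbers (fixtures and tests);
* :class:`InterpolatedC6` -- Gaussian-weighted interpolation over reference
  (CN, C6) points, the environment-dependent scheme of the D3 family, with
  the weight width k3 = 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np

__all__ = ["C6Provider", "FixedPairC6", "InterpolatedC6", "pair_key"]


def pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class C6Provider(Protocol):
    def c6(self, elem_a: str, elem_b: str, cn_a: float, cn_b: float) -> float: ...


@dataclass(frozen=True)
class FixedPairC6:
    """Symmetric pair table; CN arguments are accepted and ignored."""

    table: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        norm = {}
        for (a, b), v in self.table.items():
            if v < 0:
                raise ValueError(f"C6({a},{b}) must be non-negative")
            norm[pair_key(a, b)] = float(v)
        object.__setattr__(self, "table", norm)

    def c6(self, elem_a: str, elem_b: str, cn_a: float = 0.0, cn_b: float = 0.0) -> float:
        try:
            return self.table[pair_key(elem_a, elem_b)]
        except KeyError:
            raise KeyError(f"no C6 entry for pair ({elem_a}, {elem_b})") from None


@dataclass(frozen=True)
class InterpolatedC6:
    """Gaussian-weighted interpolation over reference (CN, C6) points.

    ``ref_cn[element]`` lists the reference coordination numbers; for each
    pair the matrix ``ref_c6[(A, B)][i, j]`` is the coefficient at
    (CN_A^i, CN_B^j).  The interpolated value is

        C6(CN_A, CN_B) = sum_ij C6_ij L_ij / sum_ij L_ij,
        L_ij = exp(-k3 [(CN_A - CN_A^i)^2 + (CN_B - CN_B^j)^2]).
    """

    ref_cn: Mapping[str, Sequence[float]]
    ref_c6: Mapping[tuple[str, str], np.ndarray]
    k3: float = 4.0

    def c6(self, elem_a: str, elem_b: str, cn_a: float, cn_b: float) -> float:
        key = pair_key(elem_a, elem_b)
        if key not in self.ref_c6:
            raise KeyError(f"no C6 reference data for pair ({elem_a}, {elem_b})")
        c6ref = np.asarray(self.ref_c6[key], dtype=float)
        # the stored matrix is laid out (first element of key, second element)
        cn_first, cn_second = (cn_a, cn_b) if (elem_a, elem_b) == key else (cn_b, cn_a)
        cns_i = np.asarray(self.ref_cn[key[0]], dtype=float)
        cns_j = np.asarray(self.ref_cn[key[1]], dtype=float)
        if c6ref.shape != (cns_i.size, cns_j.size):
            raise ValueError(f"C6 reference matrix for {key} has wrong shape")
        L = np.exp(
            -self.k3
            * (
                (cn_first - cns_i)[:, None] ** 2
                + (cn_second - cns_j)[None, :] ** 2
            )
        )
        z = L.sum()
        if z <= 0:
            raise ValueError(f"degenerate interpolation weights for pair {key}")
        return float((c6ref * L).sum() / z)
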