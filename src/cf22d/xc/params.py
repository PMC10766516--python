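"""Trainable parameters and flat parameter files.

The trainable state is X (percent single-determinant exchange), the 40
a-coefficients in canonical (i, j, k) order, the 9 b- and 9 c-coefficients,
and the dispersion range parameter s_r,6.  Parameter files are flat
``key value`` text (keys ``X``, ``a_i_j_k``, ``b_i``, ``c_i``, ``sr6``)
written with full round-trip precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .indices import enumerate_a_indices, N_A_TERMS, N_B_TERMS, N_C_TERMS
from .descriptors import DescriptorVector
from .working import IngredientFunctions

__all__ = [
    "XCParameters",
    "assemble_energy",
    "read_parameter_file",
    "write_parameter_file",
    "default_ingredient_constants",
]


@dataclass(frozen=True)
class XCParameters:
    """X (0-100 scale), a (40), b (9), c (9)."""

    x: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        for name, n in (("a", N_A_TERMS), ("b", N_B_TERMS), ("c", N_C_TERMS)):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            object.__setattr__(self, name, arr)

    @classmethod
    def zeros(cls) -> "XCParameters":
        return cls(0.0, np.zeros(N_A_TERMS), np.zeros(N_B_TERMS), np.zeros(N_C_TERMS))

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "XCParameters":
        theta = np.asarray(theta, dtype=float)
        n = 1 + N_A_TERMS + N_B_TERMS + N_C_TERMS
        if theta.shape != (n,):
            raise ValueError(f"parameter vector must have length {n}")
        return cls(
            float(theta[0]),
            theta[1 : 1 + N_A_TERMS],
            theta[1 + N_A_TERMS : 1 + N_A_TERMS + N_B_TERMS],
            theta[1 + N_A_TERMS + N_B_TERMS :],
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.x], self.a, self.b, self.c])

    def a_coefficient(self, i: int, j: int, k: int) -> float:
        return float(self.a[enumerate_a_indices().index((i, j, k))])


def assemble_energy(params: XCParameters, desc: DescriptorVector) -> float:
    """E_DF = (X/100) e_hf + a.d_a + b.d_b + c.d_c  (hartree).

    Exactly linear in all 59 parameters for fixed descriptors.
    """
    if not np.isfinite(desc.e_hf):
        raise ValueError("descriptor e_hf is unset")
    return float(params.to_vector() @ desc.stacked())


# ---------------------------------------------------------------------------
# flat parameter files
# ---------------------------------------------------------------------------

def write_parameter_file(path, params: XCParameters, sr6: float | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"X {float(params.x)!r}\n")
        for (i, j, k), v in zip(enumerate_a_indices(), params.a):
            fh.write(f"a_{i}_{j}_{k} {float(v)!r}\n")
        for i, v in enumerate(params.b):
            fh.write(f"b_{i} {float(v)!r}\n")
        for i, v in enumerate(params.c):
            fh.write(f"c_{i} {float(v)!r}\n")
        if sr6 is not None:
            fh.write(f"sr6 {float(sr6)!r}\n")


def read_parameter_file(path) -> tuple[XCParameters, float | None]:
    """Parse a flat parameter file; validates the full 40/9/9 index set."""
    entries: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                key, val = line.split()
                entries[key] = float(val)
            except ValueError:
                raise ValueError(f"malformed parameter line {lineno}: {line!r}") from None
    a = np.empty(N_A_TERMS)
    for idx, (i, j, k) in enumerate(enumerate_a_indices()):
        key = f"a_{i}_{j}_{k}"
        if key not in entries:
            raise ValueError(f"missing coefficient {key}")
        a[idx] = entries.pop(key)
    b = np.empty(N_B_TERMS)
    c = np.empty(N_C_TERMS)
    for arr, tag, n in ((b, "b", N_B_TERMS), (c, "c", N_C_TERMS)):
        for i in range(n):
            key = f"{tag}_{i}"
            if key not in entries:
                raise ValueError(f"missing coefficient {key}")
            arr[i] = entries.pop(key)
    if "X" not in entries:
        raise ValueError("missing coefficient X")
    x = entries.pop("X")
    sr6 = entries.pop("sr6", None)
    if entries:
        raise ValueError(f"unrecognised parameter keys: {sorted(entries)}")
    return XCParameters(x, a, b, c), sr6


def default_ingredient_constants() -> IngredientFunctions:
    """Ingredient functions with the transcribed family constants.

    Reads the shipped ``ingredient_constants.json`` (gamma_x, omega_x and the
    PBE-correction constants) rather than hard-coding the values.
    """
    text = resources.files("cf22d.data").joinpath("ingredient_constants.json").read_text()
    cfg = json.loads(text)
    return IngredientFunctions(
        gamma_x=cfg["gamma_x"],
        omega_x=cfg["omega_x"],
        correlation=cfg.get("correlation", "pw92"),
        pbe_beta=cfg.get("pbe_beta", 0.066725),
        pbe_gamma=cfg.get("pbe_gamma", (1.0 - float(np.log(2.0))) / float(np.pi) ** 2),
    )
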