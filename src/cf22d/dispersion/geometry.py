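"""Molecular geometries and standard XYZ files (angstrom)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GeometrySpec", "read_xyz", "write_xyz"]


@dataclass(frozen=True)
class GeometrySpec:
    """Element symbols and Cartesian coordinates in angstrom."""

    symbols: tuple[str, ...]
    coords: np.ndarray  # (n, 3), angstrom

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        symbols = tuple(str(s) for s in self.symbols)
        if len(symbols) < 1:
            raise ValueError("geometry needs at least one atom")
        if coords.shape != (len(symbols), 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(symbols) > 1:
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
            np.fill_diagonal(d, np.inf)
            if d.min() < 1e-6:
                raise ValueError("two atoms closer than 1e-6 angstrom")
        object.__setattr__(self, "symbols", symbols)
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise distances in angstrom."""
        return np.linalg.norm(self.coords[:, None, :] - self.coords[None, :, :], axis=2)

    def translated(self, shift) -> "GeometrySpec":
        return GeometrySpec(self.symbols, self.coords + np.asarray(shift, dtype=float))

    def merged(self, other: "GeometrySpec") -> "GeometrySpec":
        return GeometrySpec(self.symbols + other.symbols, np.vstack([self.coords, other.coords]))


def read_xyz(path) -> GeometrySpec:
    """Read a standard 2-header-line XYZ file."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ValueError("truncated XYZ file")
    n = int(lines[0].split()[0])
    body = [ln.split() for ln in lines[2 : 2 + n] if ln.strip()]
    if len(body) != n:
        raise ValueError(f"XYZ header declares {n} atoms, found {len(body)}")
    symbols = [f[0] for f in body]
    coords = np.array([[float(f[1]), float(f[2]), float(f[3])] for f in body])
    return GeometrySpec(tuple(symbols), coords)


def write_xyz(path, geom: GeometrySpec, comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{geom.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in zip(geom.symbols, geom.coords):
            fh.write(f"{sym} {x:.17g} {y:.17g} {z:.17g}\n")
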