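"""Dispersion parameter data files.

Plain-text files with three sections::

    [covalent_radii]
    H 0.32                      # element  radius_angstrom
    [r0]
    H C 2.50                    # pair cutoff radius R0^AB, angstrom
    [c6_reference]
    cn C 0.0 1.0 2.0 4.0        # reference coordination numbers of C
    c6 H C 0 1 8.1              # C6 (hartree*bohr^6) at (CN_H[0], CN_C[1])

The shipped ``synthetic_d3_fixture.dat`` covers H, C, N, O, Si and Ar with
synthetic (physically plausible, not published) coefficients; see its
header.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .cn import CoordinationModel
from .c6 import FixedPairC6, InterpolatedC6, pair_key

__all__ = ["read_dispersion_data", "load_fixture_data", "fixed_table_from_interpolated"]


def read_dispersion_data(text: str) -> tuple[CoordinationModel, dict, InterpolatedC6]:
    """Parse a dispersion data file into model objects."""
    radii: dict[str, float] = {}
    r0: dict[tuple[str, str], float] = {}
    ref_cn: dict[str, list[float]] = {}
    c6_entries: dict[tuple[str, str], dict[tuple[int, int], float]] = {}
    section = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            if section not in ("covalent_radii", "r0", "c6_reference"):
                raise ValueError(f"unknown section [{section}] at line {lineno}")
            continue
        if section == "covalent_radii":
            elem, val = line.split()
            radii[elem] = float(val)
        elif section == "r0":
            a, b, val = line.split()
            r0[pair_key(a, b)] = float(val)
        elif section == "c6_reference":
            fields = line.split()
            if fields[0] == "cn":
                ref_cn[fields[1]] = [float(v) for v in fields[2:]]
            elif fields[0] == "c6":
                _, a, b, i, j, val = fields
                key = pair_key(a, b)
                ij = (int(i), int(j)) if (a, b) == key else (int(j), int(i))
                c6_entries.setdefault(key, {})[ij] = float(val)
            else:
                raise ValueError(f"unrecognised c6_reference record at line {lineno}")
        else:
            raise ValueError(f"data before any section header at line {lineno}")
    ref_c6 = {}
    for key, entries in c6_entries.items():
        ni, nj = len(ref_cn[key[0]]), len(ref_cn[key[1]])
        mat = np.full((ni, nj), np.nan)
        for (i, j), v in entries.items():
            mat[i, j] = v
        if np.any(np.isnan(mat)):
            raise ValueError(f"incomplete C6 reference matrix for pair {key}")
        ref_c6[key] = mat
    return CoordinationModel(radii), r0, InterpolatedC6(ref_cn, ref_c6)


def fixed_table_from_interpolated(provider: InterpolatedC6, cn: float = 0.0) -> FixedPairC6:
    """Freeze an interpolated provider into a fixed pair table at one CN."""
    table = {
        key: provider.c6(key[0], key[1], cn, cn) for key in provider.ref_c6
    }
    return FixedPairC6(table)


def load_fixture_data() -> tuple[CoordinationModel, dict, InterpolatedC6]:
    """Load the shipped synthetic H/C/N/O/Si/Ar fixture table."""
    text = resources.files("cf22d.data").joinpath("synthetic_d3_fixture.dat").read_text()
    return read_dispersion_data(text)
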