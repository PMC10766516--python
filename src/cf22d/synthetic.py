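"""Synthetic species pools, planted-parameter databases and dimer scans.

Everything here is a pure function of (spec, seed): Gaussian-shell species
with analytically known density ingredients stand in for real molecules,
and reference values are generated from a planted parameter vector through
the same prediction path the trainer uses, optionally with i.i.d. Gaussian
noise.  That makes end-to-end recovery tests exact: training on a noiseless
planted database must return the planted parameters.

The default condition set emulates the organisation of the real training
collection at desk scale: a pool of ~90 species, data sets of 10-40
reactions grouped into the four ground-state property classes, per-set
inverse weights, and validation sets carrying a reference panel statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import BOHR_PER_ANGSTROM
from .grids import build_grid
from .density import GaussianShellSpec, gaussian_ingredients
from .xc.descriptors import DescriptorVector, descriptor_integrals
from .xc.params import XCParameters, default_ingredient_constants
from .xc.indices import N_A_TERMS, N_B_TERMS, N_C_TERMS, N_DF_PARAMS
from .database import Database, DataSet, ReactionRecord, SpeciesEntry
from .dispersion.geometry import GeometrySpec
from .dispersion.energy import DispersionParams, dispersion_energy
from .dispersion.datafile import load_fixture_data

__all__ = ["SyntheticSpec", "SpeciesPool", "make_species_pool", "make_database",
           "make_dimer_scan", "default_dispersion_params", "random_parameters"]

_ELEMENTS = ("H", "C", "N", "O")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of a synthetic experiment.

    The defaults are the package's desk-scale emulation of the real
    training conditions; they are not tuned per test.
    """

    n_species: int = 90
    max_shells: int = 3
    n_sets: int = 8
    set_size: int = 25
    classes: tuple[str, ...] = ("BH", "NC", "IE", "TC")
    roles: tuple[str, ...] = ("training",)
    noise_sigma: float = 0.0  # kcal/mol
    inverse_weight_rule: str = "uniform"  # or "panel"
    panel_factor: float = 2.0
    hard_set_bias: float = 0.0  # kcal/mol systematic bias on "hard" sets
    hard_sets: tuple[str, ...] = ()
    radial_count: int = 40
    angular_count: int = 50
    exponent_range: tuple[float, float] = (0.08, 12.0)
    e_hf_range: tuple[float, float] = (-8.0, -0.2)  # hartree
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_size < 1 or self.n_species < 2:
            raise ValueError("sizes must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass(frozen=True)
class SpeciesPool:
    entries: dict
    condition_number: float

    def design_matrix(self) -> np.ndarray:
        return np.vstack([sp.descriptors.stacked() for sp in self.entries.values()])


def random_parameters(rng: np.random.Generator, scale: float = 0.5) -> XCParameters:
    """A smooth random parameter vector (planted truth for recovery tests)."""
    x = float(rng.uniform(10.0, 60.0))
    a = rng.normal(scale=scale, size=N_A_TERMS)
    b = rng.normal(scale=scale, size=N_B_TERMS)
    c = rng.normal(scale=scale, size=N_C_TERMS)
    return XCParameters(x, a, b, c)


def default_dispersion_params(sr6: float = 1.53) -> DispersionParams:
    """Dispersion parameters backed by the shipped synthetic fixture table."""
    cn_model, r0, provider = load_fixture_data()
    return DispersionParams(sr6, r0, provider, cn_model)


def _random_species(rng: np.random.Generator, spec: SyntheticSpec, funcs, sid: str) -> SpeciesEntry:
    n_shells = int(rng.integers(1, spec.max_shells + 1))
    lo, hi = spec.exponent_range
    symbols = []
    centers_ang = []
    shells = []
    for s in range(n_shells):
        center_ang = rng.uniform(-0.9, 0.9, size=3) if n_shells > 1 else np.zeros(3)
        # keep centres separated so geometries remain valid
        while any(np.linalg.norm(center_ang - c) < 0.25 for c in centers_ang):
            center_ang = rng.uniform(-1.2, 1.2, size=3)
        centers_ang.append(center_ang)
        symbols.append(str(rng.choice(_ELEMENTS)))
        alpha = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if rng.random() < 0.7:
            occ = float(rng.uniform(0.2, 2.0))
            occupation = (occ, occ)
        else:
            occupation = (float(rng.uniform(0.2, 2.0)), float(rng.uniform(0.0, 1.5)))
        shells.append(
            GaussianShellSpec(tuple(center_ang * BOHR_PER_ANGSTROM), alpha, occupation)
        )
    centers_bohr = np.array([sh.center for sh in shells])
    grid = build_grid(centers_bohr, spec.radial_count, spec.angular_count)
    ing = gaussian_ingredients(shells, grid)
    desc = descriptor_integrals(grid, ing, funcs)
    e_hf = float(rng.uniform(*spec.e_hf_range))
    geom = GeometrySpec(tuple(symbols), np.array(centers_ang))
    return SpeciesEntry(sid, desc.with_e_hf(e_hf), geom)


def make_species_pool(spec: SyntheticSpec, funcs=None, max_retries: int = 3) -> SpeciesPool:
    """Reproducible species pool whose descriptor matrix has full rank.

    The 58 density-descriptor columns (a/b/c integrals) must be linearly
    independent across the pool; the condition number of the column-scaled
    matrix is reported.  Rank deficiency after retries raises with advice.
    """
    funcs = funcs or default_ingredient_constants()
    for attempt in range(max_retries):
        rng = np.random.default_rng((spec.seed, attempt))
        entries = {
            f"sp{i:03d}": _random_species(rng, spec, funcs, f"sp{i:03d}")
            for i in range(spec.n_species)
        }
        M = np.vstack([sp.descriptors.stacked()[1:] for sp in entries.values()])
        scale = np.linalg.norm(M, axis=0)
        scale[scale == 0] = 1.0
        Ms = M / scale
        rank = np.linalg.matrix_rank(Ms)
        if rank == N_A_TERMS + N_B_TERMS + N_C_TERMS:
            cond = float(np.linalg.cond(Ms))
            return SpeciesPool(entries, cond)
    raise RuntimeError(
        "descriptor matrix is rank-deficient after retries; "
        "increase n_species or vary shells (wider exponent range, more shells)"
    )


def _planted_prediction(entry_rows, disp, record, theta_vec) -> float:
    from .units import KCALMOL_PER_HARTREE

    total = 0.0
    for sid, nu in record.species.items():
        total += nu * (float(entry_rows[sid] @ theta_vec) + disp.get(sid, 0.0))
    return total * KCALMOL_PER_HARTREE


def make_database(
    spec: SyntheticSpec,
    pool: SpeciesPool,
    planted: XCParameters,
    sr6: float = 1.53,
    dispersion: DispersionParams | None = None,
) -> Database:
    """Reaction database whose references are planted-model predictions.

    References go through the same prediction path the trainer uses (so a
    noiseless database is exactly fittable), plus optional Gaussian noise
    and, for sets named in ``spec.hard_sets``, a systematic bias that makes
    them planted "hard" validation sets.  Validation sets carry a panel
    statistic equal to the planted-model MUE scaled by ``panel_factor``
    (floored at 0.1 kcal/mol so noiseless promotions are still decidable).
    """
    rng = np.random.default_rng((spec.seed, 104729))
    sids = list(pool.entries.keys())
    entry_rows = {sid: sp.descriptors.stacked() for sid, sp in pool.entries.items()}
    disp_cache = {}
    if dispersion is not None:
        dp = dispersion.with_sr6(sr6)
        for sid, sp in pool.entries.items():
            disp_cache[sid] = (
                0.0 if sp.geometry is None else dispersion_energy(sp.geometry, dp)
            )
    theta_vec = planted.to_vector()

    datasets = []
    for n in range(spec.n_sets):
        set_id = f"set{n:02d}"
        role = spec.roles[n % len(spec.roles)]
        klass = spec.classes[n % len(spec.classes)]
        bias = spec.hard_set_bias if set_id in spec.hard_sets else 0.0
        records = []
        noiseless_errors = []
        for _ in range(spec.set_size):
            k = int(rng.integers(2, 5))
            chosen = rng.choice(len(sids), size=k, replace=False)
            coeffs = {}
            for idx in chosen:
                coeffs[sids[idx]] = float(rng.choice((-2.0, -1.0, 1.0, 2.0)))
            clean = _planted_prediction(entry_rows, disp_cache, ReactionRecord(coeffs, 0.0), theta_vec)
            noise = float(rng.normal(scale=spec.noise_sigma)) if spec.noise_sigma > 0 else 0.0
            records.append(ReactionRecord(coeffs, clean + noise + bias))
            # the panel statistic emulates well-performing reference
            # functionals, which do not share the planted bias
            noiseless_errors.append(noise)
        planted_mue = float(np.mean(np.abs(noiseless_errors)))
        if spec.inverse_weight_rule == "uniform":
            inv_w = 1.0
        elif spec.inverse_weight_rule == "panel":
            inv_w = max(planted_mue, 0.1)
        else:
            raise ValueError(f"unknown inverse weight rule {spec.inverse_weight_rule!r}")
        panel = None
        if role == "validation":
            panel = max(planted_mue, 0.1) * spec.panel_factor
        datasets.append(
            DataSet(set_id, tuple(records), inv_w, role, klass, panel)
        )
    return Database(pool.entries, tuple(datasets))


def make_dimer_scan(
    elements: tuple[str, str],
    sr6_star: float,
    separations,
    noise_sigma: float = 0.0,
    seed: int = 0,
    dispersion: DispersionParams | None = None,
) -> tuple[Database, pd.DataFrame]:
    """Dispersion-only dimer data set for range-parameter recovery.

    Each separation (angstrom) becomes a species whose descriptors are all
    zero (so the density-functional term contributes nothing) with the
    planted damped-dispersion energy at ``sr6_star`` as its reference
    value.  Returns the database and the noiseless curve.
    """
    dp = (dispersion or default_dispersion_params()).with_sr6(sr6_star)
    rng = np.random.default_rng(seed)
    zero_desc = DescriptorVector(
        np.zeros(N_A_TERMS), np.zeros(N_B_TERMS), np.zeros(N_C_TERMS), 0.0
    )
    species = {}
    records = []
    curve_rows = []
    from .units import KCALMOL_PER_HARTREE

    for i, sep in enumerate(separations):
        sid = f"dimer{i:03d}"
        geom = GeometrySpec(elements, np.array([[0.0, 0.0, 0.0], [0.0, 0.0, float(sep)]]))
        e_disp = dispersion_energy(geom, dp)
        species[sid] = SpeciesEntry(sid, zero_desc, geom)
        ref = e_disp * KCALMOL_PER_HARTREE
        if noise_sigma > 0:
            ref += float(rng.normal(scale=noise_sigma))
        records.append(ReactionRecord({sid: 1.0}, ref, relative=False))
        curve_rows.append((float(sep), e_disp))
    ds = DataSet("dimer_scan", tuple(records), 1.0, "training", "NC")
    curve = pd.DataFrame(curve_rows, columns=["separation", "e_disp"])
    return Database(species, (ds,)), curve
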