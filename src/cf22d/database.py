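"""Reaction databases: species, records, data sets, JSON manifests.

A database couples named species (each carrying a descriptor vector, a
supplied single-determinant exchange energy and optionally a geometry for
the dispersion term) with data sets of reactions.  Each reaction is a
stoichiometric map over species with a reference value in kcal/mol; each
data set carries an inverse weight, a role (training/validation/test), a
property class and optionally the reference-panel statistic used by the
promotion rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .xc.descriptors import DescriptorVector
from .dispersion.geometry import GeometrySpec, read_xyz

__all__ = ["ReactionRecord", "DataSet", "SpeciesEntry", "Database",
           "read_manifest", "write_manifest"]

ROLES = ("training", "validation", "test")
PROPERTY_CLASSES = ("BH", "NC", "IE", "TC", "EE", "MS", "DM", "TM")


@dataclass(frozen=True)
class ReactionRecord:
    """Signed stoichiometric map and a reference value (kcal/mol)."""

    species: Mapping[str, float]
    reference_kcal: float
    relative: bool = True

    def __post_init__(self) -> None:
        sp = {str(k): float(v) for k, v in self.species.items()}
        if not sp:
            raise ValueError("a record needs at least one species")
        if self.relative and len(sp) < 2 and all(v == 0 for v in sp.values()):
            raise ValueError("a relative-energy record needs >= 2 species or nonzero coefficients")
        object.__setattr__(self, "species", sp)


@dataclass(frozen=True)
class DataSet:
    """A named set of reactions sharing a role and inverse weight."""

    id: str
    records: tuple[ReactionRecord, ...]
    inverse_weight: float
    role: str
    property_class: str
    reference_mue_mean: float | None = None  # panel statistic, kcal/mol

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"data set {self.id!r} is empty")
        if self.inverse_weight <= 0:
            raise ValueError(f"data set {self.id!r}: inverse weight must be positive")
        if self.role not in ROLES:
            raise ValueError(f"data set {self.id!r}: unknown role {self.role!r}")
        if self.property_class not in PROPERTY_CLASSES:
            raise ValueError(
                f"data set {self.id!r}: unknown property class {self.property_class!r}"
            )
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def size(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SpeciesEntry:
    """Descriptors (with e_hf set) and optional geometry of one species."""

    id: str
    descriptors: DescriptorVector
    geometry: GeometrySpec | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.descriptors.e_hf):
            raise ValueError(f"species {self.id!r}: e_hf is unset")


@dataclass(frozen=True)
class Database:
    """Species pool plus an ordered collection of data sets."""

    species: Mapping[str, SpeciesEntry]
    datasets: tuple[DataSet, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", dict(self.species))
        ids = [ds.id for ds in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate data-set ids in database")
        for ds in self.datasets:
            for rec in ds.records:
                for sid in rec.species:
                    if sid not in self.species:
                        raise KeyError(
                            f"data set {ds.id!r} references unknown species {sid!r}"
                        )
        object.__setattr__(self, "datasets", tuple(self.datasets))

    def by_role(self, role: str) -> tuple[DataSet, ...]:
        return tuple(ds for ds in self.datasets if ds.role == role)

    def dataset(self, set_id: str) -> DataSet:
        for ds in self.datasets:
            if ds.id == set_id:
                return ds
        raise KeyError(f"no data set {set_id!r}")

    def with_role(self, set_id: str, role: str, inverse_weight: float | None = None) -> "Database":
        """A copy with one data set reassigned (used by promotion)."""
        new = []
        for ds in self.datasets:
            if ds.id == set_id:
                kwargs = {"role": role}
                if inverse_weight is not None:
                    kwargs["inverse_weight"] = inverse_weight
                ds = replace(ds, **kwargs)
            new.append(ds)
        return Database(self.species, tuple(new))


# ---------------------------------------------------------------------------
# JSON manifests.  Species descriptors may be inline (arrays) or deferred to
# a grid-ingredient file; geometries may be inline or an XYZ path relative to
# the manifest.
# ---------------------------------------------------------------------------

def _species_to_json(sp: SpeciesEntry) -> dict:
    d = sp.descriptors
    out = {
        "e_hf": d.e_hf,
        "descriptors": {"d_a": d.d_a.tolist(), "d_b": d.d_b.tolist(), "d_c": d.d_c.tolist()},
    }
    if sp.geometry is not None:
        out["geometry"] = {
            "symbols": list(sp.geometry.symbols),
            "coords": sp.geometry.coords.tolist(),
        }
    return out


def write_manifest(path, db: Database) -> None:
    doc = {
        "species": {sid: _species_to_json(sp) for sid, sp in sorted(db.species.items())},
        "datasets": [
            {
                "id": ds.id,
                "role": ds.role,
                "class": ds.property_class,
                "inverse_weight": ds.inverse_weight,
                "reference_mue_mean": ds.reference_mue_mean,
                "records": [
                    {
                        "species": rec.species,
                        "reference_kcal": rec.reference_kcal,
                        "relative": rec.relative,
                    }
                    for rec in ds.records
                ],
            }
            for ds in ds_list(db)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False), encoding="utf-8")


def ds_list(db: Database) -> tuple[DataSet, ...]:
    return db.datasets


def _species_from_json(sid: str, obj: dict, base: Path, funcs=None) -> SpeciesEntry:
    geom = None
    if "geometry" in obj:
        g = obj["geometry"]
        geom = GeometrySpec(tuple(g["symbols"]), np.asarray(g["coords"], dtype=float))
    elif "xyz" in obj:
        geom = read_xyz(base / obj["xyz"])
    if "descriptors" in obj:
        d = obj["descriptors"]
        desc = DescriptorVector(
            np.asarray(d["d_a"], float), np.asarray(d["d_b"], float), np.asarray(d["d_c"], float),
            float(obj["e_hf"]),
        )
    elif "grid" in obj:
        from .density import read_ingredient_file
        from .xc.descriptors import descriptor_integrals
        from .xc.params import default_ingredient_constants

        grid, ing = read_ingredient_file(base / obj["grid"])
        desc = descriptor_integrals(grid, ing, funcs or default_ingredient_constants())
        desc = desc.with_e_hf(float(obj["e_hf"]))
    else:
        raise ValueError(f"species {sid!r}: neither inline descriptors nor a grid file")
    return SpeciesEntry(sid, desc, geom)


def read_manifest(path, funcs=None) -> Database:
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    species = {
        sid: _species_from_json(sid, obj, path.parent, funcs)
        for sid, obj in doc["species"].items()
    }
    datasets = []
    for ds in doc["datasets"]:
        records = tuple(
            ReactionRecord(r["species"], float(r["reference_kcal"]), bool(r.get("relative", True)))
            for r in ds["records"]
        )
        datasets.append(
            DataSet(
                ds["id"], records, float(ds["inverse_weight"]), ds["role"], ds["class"],
                None if ds.get("reference_mue_mean") is None else float(ds["reference_mue_mean"]),
            )
        )
    return Database(species, tuple(datasets))
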