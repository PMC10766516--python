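"""Database-composition registries.

A registry records how a benchmark collection is organised: sub-databases
with a declared size, member data sets with per-role counts, and property
classes.  It validates the arithmetic (declared sizes equal the sum of
member sizes; role counts sum to set sizes) and renders summary tables.

Two compositions ship with the package, transcribed from the printed
organisation of the consolidated benchmark collection this functional was
trained on: the full collection (``ddb22``) and the initial optimisation
split (``initial_optimization``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["MemberSet", "SubDatabase", "DatabaseRegistry", "load_registry",
           "load_shipped_registry", "registry_report"]


@dataclass(frozen=True)
class MemberSet:
    id: str
    size: int
    n_train: int
    n_test: int
    property_class: str = ""
    n_sets: int = 1  # number of underlying data sets this row aggregates

    def __post_init__(self) -> None:
        if self.size < 0 or self.n_train < 0 or self.n_test < 0:
            raise ValueError(f"{self.id}: counts must be non-negative")
        if self.n_train + self.n_test != self.size:
            raise ValueError(
                f"member {self.id!r}: role counts {self.n_train}+{self.n_test} "
                f"do not sum to size {self.size}"
            )


@dataclass(frozen=True)
class SubDatabase:
    name: str
    unit: str
    declared_size: int
    members: tuple[MemberSet, ...]

    def __post_init__(self) -> None:
        total = sum(m.size for m in self.members)
        if total != self.declared_size:
            raise ValueError(
                f"sub-database {self.name!r}: declared size {self.declared_size} "
                f"!= sum of member sizes {total}"
            )

    @property
    def n_train(self) -> int:
        return sum(m.n_train for m in self.members)

    @property
    def n_test(self) -> int:
        return sum(m.n_test for m in self.members)


@dataclass(frozen=True)
class DatabaseRegistry:
    name: str
    sub_databases: tuple[SubDatabase, ...]

    def __post_init__(self) -> None:
        ids = [m.id for sd in self.sub_databases for m in sd.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate member set ids across sub-databases: {dupes}")

    @property
    def total(self) -> int:
        return sum(sd.declared_size for sd in self.sub_databases)

    def sub_database(self, name: str) -> SubDatabase:
        for sd in self.sub_databases:
            if sd.name == name:
                return sd
        raise KeyError(f"no sub-database {name!r}")


def load_registry(source) -> DatabaseRegistry:
    """Build a validated registry from a JSON manifest (path or dict)."""
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        doc = source
    subs = []
    for sd in doc.get("sub_databases", []):
        members = tuple(
            MemberSet(
                m["id"], int(m["size"]), int(m["n_train"]), int(m["n_test"]),
                m.get("class", ""), int(m.get("n_sets", 1)),
            )
            for m in sd["members"]
        )
        subs.append(SubDatabase(sd["name"], sd.get("unit", "kcal/mol"), int(sd["size"]), members))
    return DatabaseRegistry(doc.get("name", ""), tuple(subs))


def load_shipped_registry(name: str) -> DatabaseRegistry:
    """Load one of the shipped compositions (``ddb22``, ``initial_optimization``)."""
    fname = {"ddb22": "ddb22_registry.json",
             "initial_optimization": "initial_optimization_registry.json"}
    if name not in fname:
        raise KeyError(f"unknown shipped registry {name!r}; available: {sorted(fname)}")
    text = resources.files("cf22d.data").joinpath(fname[name]).read_text()
    return load_registry(json.loads(text))


def registry_report(registry: DatabaseRegistry) -> pd.DataFrame:
    """Per-sub-database totals and role splits, deterministic order."""
    rows = []
    for sd in registry.sub_databases:
        rows.append(
            {
                "sub_database": sd.name,
                "unit": sd.unit,
                "n_sets": sum(m.n_sets for m in sd.members),
                "size": sd.declared_size,
                "n_train": sd.n_train,
                "n_test": sd.n_test,
                "classes": ",".join(sorted({m.property_class for m in sd.members if m.property_class})),
            }
        )
    rows.append(
        {
            "sub_database": "TOTAL",
            "unit": "",
            "n_sets": sum(r["n_sets"] for r in rows),
            "size": registry.total,
            "n_train": sum(r["n_train"] for r in rows),
            "n_test": sum(r["n_test"] for r in rows),
            "classes": "",
        }
    )
    return pd.DataFrame(rows)
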