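"""Benchmark statistics: MUE, RMSE, MoM and the WTMAD aggregates.

The weighted total mean absolute deviations combine per-set MADs across a
benchmark collection:

* WTMAD-2 weights each set by its size and by the ratio of the collection's
  overall mean absolute reference energy to the set's own mean absolute
  reference energy;
* WTMAD-1 weights each set by its size and a bin weight keyed to the
  magnitude of its reference energies.

The literature constants of the GMTKN55 scheme (overall mean |dE| and the
bin thresholds/weights) are shipped as a preset, not hard-coded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SetSummary", "mue", "rmse", "mom", "wtmad1", "wtmad2",
    "BinScheme", "load_wtmad_preset", "summaries_from_frame",
]


@dataclass(frozen=True)
class SetSummary:
    """Per-set statistics feeding the weighted aggregates (kcal/mol)."""

    set_id: str
    n: int
    mad: float
    mean_abs_ref: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.set_id}: set size must be >= 1")
        if self.mad < 0 or self.mean_abs_ref < 0:
            raise ValueError(f"{self.set_id}: statistics must be non-negative")


def mue(errors) -> float:
    """Mean unsigned error."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error vector")
    return float(np.mean(np.abs(errors)))


def rmse(errors) -> float:
    """Root-mean-square error."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error vector")
    return float(np.sqrt(np.mean(errors**2)))


def mom(set_mads) -> float:
    """Mean of per-set MADs (unweighted)."""
    set_mads = np.asarray(set_mads, dtype=float)
    if set_mads.size == 0:
        raise ValueError("no set summaries")
    return float(np.mean(set_mads))


def wtmad2(summaries: Sequence[SetSummary], overall_mean_abs: float) -> float:
    """Size- and magnitude-weighted MAD aggregate.

    sum_i N_i (overall/|dE|_i) MAD_i / sum_i N_i.
    """
    if not summaries:
        raise ValueError("no set summaries")
    num = 0.0
    den = 0.0
    for s in summaries:
        if s.mean_abs_ref <= 0:
            raise ValueError(f"{s.set_id}: mean absolute reference must be positive")
        num += s.n * (overall_mean_abs / s.mean_abs_ref) * s.mad
        den += s.n
    return num / den


@dataclass(frozen=True)
class BinScheme:
    """Magnitude bins [(lo, hi, weight), ...] for WTMAD-1.

    Bins are half-open [lo, hi); a set belongs to the bin containing its
    mean absolute reference value.
    """

    bins: tuple[tuple[float, float, float], ...]

    def weight(self, mean_abs_ref: float) -> float:
        for lo, hi, w in self.bins:
            if lo <= mean_abs_ref < hi:
                return w
        raise ValueError(f"mean |dE| = {mean_abs_ref} falls outside every bin")


def wtmad1(summaries: Sequence[SetSummary], scheme: BinScheme) -> float:
    """Size- and bin-weighted MAD aggregate: sum_i N_i w_i MAD_i / sum_i N_i."""
    if not summaries:
        raise ValueError("no set summaries")
    num = sum(s.n * scheme.weight(s.mean_abs_ref) * s.mad for s in summaries)
    den = sum(s.n for s in summaries)
    return num / den


def load_wtmad_preset(name: str = "gmtkn55") -> dict:
    """Shipped literature preset: overall mean |dE| and the WTMAD-1 bins."""
    text = resources.files("cf22d.data").joinpath("wtmad_presets.json").read_text()
    presets = json.loads(text)
    if name not in presets:
        raise KeyError(f"unknown WTMAD preset {name!r}; available: {sorted(presets)}")
    p = presets[name]
    bins = tuple(
        (float(lo), math.inf if hi is None else float(hi), float(w)) for lo, hi, w in p["bins"]
    )
    return {"overall_mean_abs": float(p["overall_mean_abs"]), "bin_scheme": BinScheme(bins)}


def summaries_from_frame(frame: pd.DataFrame) -> list[SetSummary]:
    """Build summaries from a frame with columns set_id, N, MAD, mean_abs_ref."""
    return [
        SetSummary(str(r.set_id), int(r.N), float(r.MAD), float(r.mean_abs_ref))
        for r in frame.itertuples(index=False)
    ]
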