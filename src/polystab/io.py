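"""Configuration parsing, tidy output writers, and synthetic map fixtures.

Run configurations are flat YAML/JSON mappings; unknown keys are rejected so
typos never silently fall back to defaults.  Outputs are tab-separated tidy
tables (period decimal separator, header row) plus a JSON manifest of every
resolved parameter and scalar diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .maps import ChromosomeTable

__all__ = [
    "FixtureMapSpec",
    "make_fixture_chromosome_table",
    "RunConfig",
    "read_config",
    "write_tidy",
    "read_tidy",
    "write_manifest",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for schema violations in run configuration files."""


@dataclass(frozen=True)
class FixtureMapSpec:
    """Deterministic toy chromosome table: ``n_chromosomes`` chromosomes
    covering ``total_morgans`` of genetic map, with physical lengths either
    equal or proportional to ``bp_profile``."""

    n_chromosomes: int
    total_morgans: float
    bp_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.total_morgans <= 0.0:
            raise ValueError("total genetic length must be positive")
        if self.bp_profile is not None and len(self.bp_profile) != self.n_chromosomes:
            raise ValueError("bp_profile length must match n_chromosomes")

    @classmethod
    def preset(cls, name: str) -> "FixtureMapSpec":
        """'low-recombination': few long chromosomes with short genetic maps
        (strong LD regime, rbar_h << 1/2, in the spirit of a Drosophila-like
        genome); 'high-recombination': many chromosomes with long maps
        (rbar_h near 1/2, human-like)."""
        if name == "low-recombination":
            return cls(n_chromosomes=3, total_morgans=0.9,
                       bp_profile=(25e6, 30e6, 28e6))
        if name == "high-recombination":
            return cls(n_chromosomes=20, total_morgans=32.0)
        raise ValueError(f"unknown preset {name!r}")


def make_fixture_chromosome_table(spec: FixtureMapSpec) -> ChromosomeTable:
    """Build the deterministic toy chromosome table described by ``spec``.
    Genetic length is split across chromosomes in proportion to physical
    length, so locus placement and map construction stay consistent."""
    if spec.bp_profile is None:
        bp = np.full(spec.n_chromosomes, 1e7)
    else:
        bp = np.asarray(spec.bp_profile, dtype=float)
    cm = 100.0 * spec.total_morgans * bp / bp.sum()
    ids = tuple(f"chr{i + 1}" for i in range(spec.n_chromosomes))
    return ChromosomeTable(ids, bp, cm)


_CONFIG_KEYS = {
    "L", "alpha", "p0", "VS", "VS_over_Vg0", "VE", "N",
    "generations", "replicates", "seed", "map", "assort",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated flat run configuration (see the config-file dialect in the
    README).  Exactly one of ``VS`` and ``VS_over_Vg0`` is set."""

    L: int
    alpha: Any
    p0: Any
    N: int
    generations: int
    replicates: int = 1
    seed: int = 0
    VS: float | None = None
    VS_over_Vg0: float | None = None
    VE: float = 0.0
    map: str | None = None
    assort: dict | None = None

    def architecture(self, rng: np.random.Generator | None = None):
        from .model import TraitArchitecture

        alpha = self.alpha
        p0 = self.p0
        if isinstance(p0, dict):
            if rng is None:
                raise ConfigError("a seeded rng is required for distribution specs")
            p0 = _draw(p0, self.L, rng)
        if isinstance(alpha, dict):
            if rng is None:
                raise ConfigError("a seeded rng is required for distribution specs")
            alpha = _draw(alpha, self.L, rng)
        alpha = np.broadcast_to(np.asarray(alpha, float), (self.L,)).copy()
        p0 = np.broadcast_to(np.asarray(p0, float), (self.L,)).copy()
        return TraitArchitecture(alpha, p0)

    def selection_width(self, Vg0: float) -> float:
        return self.VS if self.VS is not None else self.VS_over_Vg0 * Vg0


def _draw(spec: dict, L: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec.get("dist")
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size=L)
    if kind == "normal":
        return rng.normal(spec["mean"], spec["sd"], size=L)
    raise ConfigError(f"unknown distribution spec {spec!r}")


def read_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML/JSON run configuration.  All schema
    violations are reported together, each naming the failing key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    problems: list[str] = []
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        problems.append(f"unknown keys: {', '.join(unknown)}")
    for key in ("L", "alpha", "p0", "N", "generations"):
        if key not in raw:
            problems.append(f"missing required key: {key}")
    if ("VS" in raw) == ("VS_over_Vg0" in raw):
        problems.append("exactly one of VS and VS_over_Vg0 must be given")
    for key in ("L", "N", "generations", "replicates"):
        if key in raw and (not isinstance(raw[key], int) or raw[key] < 1):
            problems.append(f"{key}: must be a positive integer")
    for key in ("VS", "VS_over_Vg0"):
        if raw.get(key) is not None and raw[key] <= 0:
            problems.append(f"{key}: must be positive")
    if raw.get("VE", 0.0) < 0:
        problems.append("VE: must be non-negative")
    if "assort" in raw and raw["assort"] is not None:
        a = raw["assort"]
        if not isinstance(a, dict) or set(a) != {"h2", "rho"}:
            problems.append("assort: must be a mapping with keys h2 and rho")
    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))
    return RunConfig(**{k: raw[k] for k in raw})


def write_tidy(path: str | Path, records: pd.DataFrame) -> None:
    """Write a tidy table as TSV: tab delimiter, header row, period decimal
    separator, no index — locale-independent and round-trippable."""
    records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tidy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, **entries: Any) -> None:
    """JSON manifest of resolved parameters and scalar diagnostics."""
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return asdict(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=default)
        fh.write("\n")
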