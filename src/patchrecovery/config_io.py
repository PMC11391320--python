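"""Configuration files, registries on disk, and CSV network readers.

Configs and registries are flat YAML or JSON (chosen by extension);
adjacency matrices and biomass vectors are plain CSV.  Loading is
strict: unknown keys are rejected by name, and every parameter passes
through the same dataclass invariants as programmatic construction, so
an out-of-range value (``L_max = 1.5``) fails with a message naming the
violated constraint rather than propagating silently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .recolonization import PatchNetwork
from .registry import ParameterRegistry
from .scenarios import MANAGEMENT_ACTIONS, MODELS

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "load_registry",
    "save_registry",
    "read_adjacency_csv",
    "read_biomass_csv",
    "network_from_files",
]


def _read_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _write_structured(data: dict, path: Path) -> None:
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass(frozen=True)
class RunConfig:
    """Validated run specification for a scenario grid.

    Axes are lists (factorial product); ``species = None`` means every
    species in the registry.  ``registry`` is a path to a registry file
    or the literal ``"fixture"`` for the bundled placeholder registry.
    """

    registry: str = "fixture"
    species: Sequence[str] | None = None
    models: Sequence[str] = MODELS
    n_connected: Sequence[int] = tuple(range(1, 11))
    light_fractions: Sequence[float] = (1.0, 0.5, 0.25)
    managements: Sequence[str] = ("none",)
    fraction: float = 0.5
    mode: str = "analytic"
    n_reps: int = 100_000
    seed: int = 0
    max_years: float = 200.0
    time_mode: str = "continuous"

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}; valid: {MODELS}")
        for a in self.managements:
            if a not in MANAGEMENT_ACTIONS:
                raise ValueError(
                    f"unknown management {a!r}; valid: {MANAGEMENT_ACTIONS}"
                )
        if any(n < 0 for n in self.n_connected):
            raise ValueError("n_connected values must be >= 0")
        if any(not 0 < lf <= 1 for lf in self.light_fractions):
            raise ValueError("light_fractions must lie in (0, 1]")
        if not 0 < self.fraction < 1:
            raise ValueError(f"fraction must lie in (0, 1), got {self.fraction}")
        if self.mode not in ("analytic", "simulate"):
            raise ValueError(f"mode must be 'analytic' or 'simulate', got {self.mode!r}")
        if self.time_mode not in ("continuous", "annual"):
            raise ValueError(f"unknown time_mode {self.time_mode!r}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if not self.max_years > 0:
            raise ValueError(f"max_years must be positive, got {self.max_years}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("species", "models", "n_connected", "light_fractions", "managements"):
            if out[key] is not None:
                out[key] = list(out[key])
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected with a message naming the key; every field
    is validated against its invariant.
    """
    path = Path(path)
    data = _read_structured(path)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)} in {path}; valid keys: "
            f"{sorted(valid)}"
        )
    for key in ("models", "n_connected", "light_fractions", "managements", "species"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    _write_structured(config.to_dict(), Path(path))


def load_registry(path: str | Path) -> ParameterRegistry:
    """Load a parameter registry from YAML or JSON."""
    return ParameterRegistry.from_dict(_read_structured(Path(path)))


def save_registry(registry: ParameterRegistry, path: str | Path) -> None:
    _write_structured(registry.to_dict(), Path(path))


def read_adjacency_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square 0/1 adjacency matrix with a header row of patch ids."""
    df = pd.read_csv(path)
    ids = [str(c) for c in df.columns]
    Q = df.to_numpy(dtype=float)
    if Q.shape[0] != Q.shape[1]:
        raise ValueError(
            f"adjacency matrix in {path} is {Q.shape[0]}x{Q.shape[1]}, expected square"
        )
    return Q, ids


def read_biomass_csv(path: str | Path) -> pd.Series:
    """Read a (patch_id, biomass) CSV into a Series indexed by patch id."""
    df = pd.read_csv(path)
    expected = {"patch_id", "biomass"}
    if set(df.columns) != expected:
        raise ValueError(
            f"biomass file {path} must have columns {sorted(expected)}, "
            f"got {list(df.columns)}"
        )
    return pd.Series(
        df["biomass"].to_numpy(dtype=float), index=df["patch_id"].astype(str)
    )


def network_from_files(
    adjacency_path: str | Path,
    biomass_path: str | Path,
    disturbed_id: str,
) -> PatchNetwork:
    """Assemble a :class:`PatchNetwork` from adjacency + biomass CSVs."""
    Q, ids = read_adjacency_csv(adjacency_path)
    biomass = read_biomass_csv(biomass_path)
    missing = [i for i in ids if i not in biomass.index]
    if missing:
        raise ValueError(f"patches {missing} have no biomass entry in {biomass_path}")
    if disturbed_id not in ids:
        raise ValueError(f"disturbed patch {disturbed_id!r} not among patch ids {ids}")
    vec = biomass.loc[ids].to_numpy()
    return PatchNetwork(Q=Q, biomass=vec, disturbed_index=ids.index(disturbed_id))
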