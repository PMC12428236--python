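"""Run configuration: one dataclass carrying every tunable parameter.

Loaded from YAML or JSON so batch runs are reproducible; every CLI command
accepts ``--config``. Units are µm unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # --- geometry ---
    spacing: tuple[float, float, float] = (0.5, 0.172, 0.172)  # (dz, dy, dx) µm
    # --- segmentation ---
    denoise_sigma_um: float = 0.0  # Gaussian pre-filter before Otsu; 0 = off (raw histogram)
    connectivity: int = 26  # {6, 18, 26}; 26 keeps thin diagonal processes whole
    min_object_voxels: int = 50  # noise filter: smallest object kept after thresholding
    interior_min: float = 0.8  # completeness criterion: min fraction of voxels off the stack faces
    # size gate, either as explicit voxel counts or as cell ids picked from the
    # ranked object-size table (ids win if both are set)
    gate_min_voxels: int | None = None
    gate_max_voxels: int | None = None
    gate_smallest_cell_id: int | None = None
    gate_largest_cell_id: int | None = None
    # --- morphometry ---
    prune_length_um: float = 2.0  # spur branches shorter than this are removed
    soma_fraction: float = 0.5  # soma = distance-transform values >= fraction * max
    sholl_step_um: float = 5.0
    sholl_max_radius_um: float = 50.0
    # --- clustering ---
    k: int = 3
    seed: int = 0
    n_init: int = 10
    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int | None = None  # PCs fed to UMAP; None = all
    cluster_space: str = "umap"  # or "pca"
    alpha: float = 0.05

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["spacing"] = list(d["spacing"])
        return d


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file plus overrides."""
    values: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        loaded = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if loaded:
            values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "spacing" in values:
        values["spacing"] = tuple(float(s) for s in values["spacing"])
    return PipelineConfig(**values)
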