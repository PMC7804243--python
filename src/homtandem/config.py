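"""Pipeline configuration: one YAML file, CLI-flag overrides, sidecar echo.

Defaults mirror the processing choices the pipeline is built around:
5 ppm m/z tolerance, 0.1% relative-intensity floor, C/H/O analytes with
at most two nitrogen atoms from the adduct, electron-inclusive anion
masses.  Every output gets a ``<output>.meta.json`` sidecar echoing the
configuration verbatim, so a run is reproducible from its artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .formula import EnumerationBounds

__all__ = ["PipelineConfig", "write_sidecar"]


@dataclass(frozen=True)
class PipelineConfig:
    tolerance_ppm: float = 5.0
    intensity_floor: float = 0.001
    include_electron: bool = True
    c_bounds: tuple[int, int] = (0, 25)
    h_bounds: tuple[int, int] = (0, 45)
    n_bounds: tuple[int, int] = (0, 2)
    o_bounds: tuple[int, int] = (0, 20)
    rdbe_range: tuple[float, float] = (-0.5, 20.0)
    similarity_mode: str = "product_ions"
    mask_threshold: float = 0.2  # display only, never used for clustering
    include_scrambling: bool = False
    deprotonated_weight: float = 0.5
    seed: int = 0

    def bounds(self) -> EnumerationBounds:
        return EnumerationBounds(c=self.c_bounds, h=self.h_bounds,
                                 n=self.n_bounds, o=self.o_bounds,
                                 rdbe_range=self.rdbe_range,
                                 tolerance_ppm=self.tolerance_ppm)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("c_bounds", "h_bounds", "n_bounds", "o_bounds", "rdbe_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def override(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def write_sidecar(output_path: str | Path, config: PipelineConfig,
                  extra: dict | None = None) -> Path:
    """Write ``<output>.meta.json`` echoing the configuration used."""
    sidecar = Path(str(output_path) + ".meta.json")
    payload = {"config": config.to_dict()}
    if extra:
        payload.update(extra)
    sidecar.write_text(json.dumps(payload, indent=1, default=str) + "\n")
    return sidecar
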