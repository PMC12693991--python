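"""YAML/JSON serialisation of build configuration and the magnet catalogue.

Every experiment is fully described by a geometry, a magnet and a sensor
specification; round-tripping them through plain mappings keeps runs
reproducible and lets reports carry their provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

from .kinematics import GeometryConfig
from .magnetostatics import MagnetSpec

__all__ = [
    "geometry_to_dict",
    "geometry_from_dict",
    "magnet_to_dict",
    "magnet_from_dict",
    "load_config",
    "save_config",
    "load_catalogue",
    "reference_magnet",
    "geometry_hash",
]


def geometry_to_dict(geom: GeometryConfig) -> dict:
    return dataclasses.asdict(geom)


def geometry_from_dict(d: dict) -> GeometryConfig:
    return GeometryConfig(**d)


def magnet_to_dict(magnet: MagnetSpec) -> dict:
    return {
        "name": magnet.name,
        "shape": magnet.shape,
        "dimensions": list(magnet.dimensions),
        "br_mT": list(magnet.br_mT),
        "grade": magnet.grade,
    }


def magnet_from_dict(d: dict) -> MagnetSpec:
    return MagnetSpec(
        shape=d["shape"],
        dimensions=tuple(d["dimensions"]),
        br_mT=tuple(d["br_mT"]),
        grade=d.get("grade", ""),
        name=d.get("name", ""),
    )


def save_config(path: str | Path, geom: GeometryConfig,
                magnet: MagnetSpec | None = None, **extra) -> None:
    doc = {"geometry": geometry_to_dict(geom)}
    if magnet is not None:
        doc["magnet"] = magnet_to_dict(magnet)
    doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    out = dict(doc)
    out["geometry"] = geometry_from_dict(doc["geometry"])
    if "magnet" in doc:
        out["magnet"] = magnet_from_dict(doc["magnet"])
    return out


def load_catalogue() -> list[MagnetSpec]:
    """The packaged nine-candidate magnet catalogue."""
    text = resources.files("magthr.data").joinpath("catalogue.yaml").read_text()
    doc = yaml.safe_load(text)
    return [magnet_from_dict(m) for m in doc["magnets"]]


def reference_magnet() -> MagnetSpec:
    """The selected build magnet: the 8 × 2 mm axially magnetised N42 disc."""
    return load_catalogue()[0]


def geometry_hash(geom: GeometryConfig, magnet: MagnetSpec | None = None) -> str:
    """Short stable digest of a configuration, for report provenance."""
    doc = {"geometry": geometry_to_dict(geom)}
    if magnet is not None:
        doc["magnet"] = magnet_to_dict(magnet)
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
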