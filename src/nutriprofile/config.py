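"""Loading of the shipped, versioned rule/point-table configuration.

Every scheme's numeric content (point thresholds, class boundaries, limit
values) lives in YAML files under ``nutriprofile/data`` so the transcription
of each protocol is auditable and swappable; the code implements only the
scoring/thresholding skeletons.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib.resources import files

import yaml

from .errors import ConfigError

_DATA_FILES = {
    "nutriscore": "nutriscore-2017.yaml",
    "ofcom": "ofcom-2005.yaml",
    "fsanz": "fsanz-npsc-2016.yaml",
    "hsr": "hsr-2016.yaml",
    "traffic_light": "traffic-light-2007.yaml",
    "protective_food": "protective-food.yaml",
    "keyhole": "keyhole-2015.yaml",
    "choices": "choices-2015.yaml",
    "finnish_heart": "finnish-heart-2015.yaml",
    "whoe": "whoe-2015.yaml",
    "category_mapping": "category-mapping.yaml",
    "supply_spec": "default-supply-spec.yaml",
}


def data_file_names() -> dict[str, str]:
    return dict(_DATA_FILES)


def read_data_text(name: str) -> str:
    return (files("nutriprofile") / "data" / name).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def load_config(key: str) -> dict:
    """Load one shipped YAML config by model key (cached, read-only)."""
    try:
        fname = _DATA_FILES[key]
    except KeyError as exc:
        raise ConfigError(f"no shipped configuration for {key!r}") from exc
    cfg = yaml.safe_load(read_data_text(fname))
    if not isinstance(cfg, dict):
        raise ConfigError(f"configuration {fname} is not a mapping")
    if key not in ("category_mapping", "supply_spec") and "version" not in cfg:
        raise ConfigError(f"configuration {fname} lacks a version tag")
    return cfg


def config_version(key: str) -> str:
    return str(load_config(key).get("version", "unversioned"))


@dataclass(frozen=True)
class PointTables:
    """Point tables and class boundaries for one score model."""

    model: str
    version: str
    raw: dict

    @property
    def negative(self) -> dict:
        return self.raw["negative"]

    @property
    def positive(self) -> dict:
        return self.raw["positive"]

    def component(self, side: str, name: str) -> dict:
        try:
            return self.raw[side][name]
        except KeyError as exc:
            raise ConfigError(
                f"{self.model} tables lack {side} component {name!r}"
            ) from exc


def _check_tables(cfg: dict, model: str) -> None:
    for side in ("negative", "positive"):
        for name, comp in cfg.get(side, {}).items():
            th = comp.get("thresholds", [])
            pts = comp.get("points", [])
            if len(th) != len(pts):
                raise ConfigError(f"{model}.{name}: thresholds/points length mismatch")
            if any(b <= a for a, b in zip(th, th[1:])):
                raise ConfigError(f"{model}.{name}: thresholds not strictly increasing")
            if any(b < a for a, b in zip(pts, pts[1:])):
                raise ConfigError(f"{model}.{name}: points not non-decreasing")
            if comp.get("comparator") not in ("gt", "ge"):
                raise ConfigError(f"{model}.{name}: comparator must be gt|ge")


@lru_cache(maxsize=None)
def load_point_tables(model: str) -> PointTables:
    if model not in ("nutriscore", "ofcom", "fsanz", "hsr"):
        raise ConfigError(f"{model!r} is not a point-scoring model")
    cfg = load_config(model)
    _check_tables(cfg, model)
    return PointTables(model=model, version=str(cfg["version"]), raw=cfg)
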