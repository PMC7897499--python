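"""Run configuration: defaults, YAML overrides, reproducibility metadata.

A run configuration merges built-in defaults with an optional YAML file.
Recognised top-level keys map onto the parameter dataclasses:

``orf_search``        -> :class:`arrestscan.orfs.OrfSearchParams`
``topology``          -> :class:`arrestscan.screen.TopologyParams`
``align``             -> :class:`arrestscan.conservation.AlignParams`
``screen``            -> remaining :class:`arrestscan.screen.ScreenConfig` fields
``target_keywords``   -> class -> keyword list overriding the default map
``panel``             -> :class:`arrestscan.synthetic.PanelConfig`
``toeprint``          -> :class:`arrestscan.arrest.ToeprintParams`

Every CLI output directory receives a ``run_config.json`` capturing the
merged configuration, package version and seed, so results are
reproducible from the directory alone.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone

import yaml

from . import __version__
from .arrest import ToeprintParams
from .conservation import AlignParams
from .orfs import OrfSearchParams
from .screen import ScreenConfig, TopologyParams
from .synthetic import PanelConfig

__all__ = ["RunConfig", "load_config"]

_SCREEN_SCALARS = (
    "min_exposed_aa",
    "exposure_comparator",
    "group_within_target_class",
    "report_min_len_aa",
    "report_max_len_aa",
    "report_window_nt",
)


def _build(cls, data: dict | None):
    data = dict(data or {})
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for k, v in list(data.items()):
        if isinstance(v, list):
            data[k] = tuple(v)
    return cls(**data)


@dataclasses.dataclass
class RunConfig:
    screen: ScreenConfig
    panel: PanelConfig
    toeprint: ToeprintParams
    seed: int = 0

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            return obj

        return {
            "version": __version__,
            "seed": self.seed,
            "screen": clean(self.screen),
            "panel": clean(self.panel),
            "toeprint": clean(self.toeprint),
        }

    def write(self, path) -> None:
        payload = self.to_dict()
        payload["timestamp"] = datetime.now(timezone.utc).isoformat()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def load_config(path=None, seed: int = 0) -> RunConfig:
    """Build a :class:`RunConfig` from defaults plus an optional YAML file."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")

    screen_kwargs: dict = {}
    screen_kwargs["orf_search"] = _build(OrfSearchParams, raw.get("orf_search"))
    screen_kwargs["topology"] = _build(TopologyParams, raw.get("topology"))
    screen_kwargs["align"] = _build(AlignParams, raw.get("align"))
    extra = dict(raw.get("screen") or {})
    unknown = set(extra) - set(_SCREEN_SCALARS)
    if unknown:
        raise ValueError(f"unknown screen keys: {sorted(unknown)}")
    screen_kwargs.update(extra)
    if "target_keywords" in raw:
        screen_kwargs["target_keywords"] = {
            cls: frozenset(str(k).lower() for k in kws)
            for cls, kws in raw["target_keywords"].items()
        }
    screen = ScreenConfig(**screen_kwargs)
    panel = _build(PanelConfig, raw.get("panel"))
    if "seed" not in (raw.get("panel") or {}):
        panel.seed = seed
    toeprint = _build(ToeprintParams, raw.get("toeprint"))
    return RunConfig(screen=screen, panel=panel, toeprint=toeprint, seed=seed)
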