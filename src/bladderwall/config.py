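"""Pipeline configuration: one flat namespace of dotted keys.

Every tunable of every stage lives under a namespace prefix (``ls.*``
level set, ``outer.*`` search band, ``glcm.*`` / ``polar.*`` features,
``gwo.*`` optimizer, ``cv.*`` evaluation protocol, ``phantom.*`` cohort
generation), plus a global ``seed`` and ``out_dir``.  Unknown keys are
rejected before any computation; a config round-trips through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

__all__ = ["DEFAULTS", "PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "run",
    # preprocessing
    "smooth.radius": 1,
    "contrast.window": 9,
    # level set (both phases share the numerics; balloon/iters differ)
    "ls.dt": 0.5,
    "ls.sigma": 1.0,
    "ls.edge_scale": 8.0,
    "ls.alpha": 3.0,
    "ls.beta": 0.3,
    "ls.inner_balloon": -0.7,
    "ls.outer_balloon": -0.7,
    "ls.inner_max_iters": 1200,
    "ls.outer_max_iters": 600,
    "ls.stop_tol": 0.0001,
    "ls.reinit_every": 20,
    # outer search band
    "outer.max_thickness_mm": 10.0,
    "outer.min_separation_px": 1,
    # seed disk
    "seed_disk.radius_px": 5.0,
    # features
    "glcm.levels": 32,
    "polar.n_theta": 360,
    # selection
    "select.method": "sffs",
    "select.floating": True,
    "select.max_size": 40,
    # GWO
    "gwo.pack_size": 10,
    "gwo.iterations": 30,
    "gwo.log10C_bounds": [-2.0, 2.0],
    "gwo.log10gamma_bounds": [-4.0, 1.0],
    # evaluation protocol
    "cv.folds": 5,
    "cv.test_frac": 0.2,
    # phantom cohort
    "phantom.n_per_class": 10,
    "phantom.image_size": 128,
    "phantom.pixel_spacing": 1.0,
    "phantom.inner_radius": 22.0,
    "phantom.noise_sigma": 8.0,
    "phantom.class0.thickness_mean": 4.0,
    "phantom.class0.thickness_sd": 0.3,
    "phantom.class0.irregularity": 0.0,
    "phantom.class0.n_diverticula": 0,
    "phantom.class1.thickness_mean": 7.0,
    "phantom.class1.thickness_sd": 0.6,
    "phantom.class1.irregularity": 1.5,
    "phantom.class1.n_diverticula": 2,
}


class PipelineConfig:
    """Validated dotted-key configuration with defaults."""

    def __init__(self, overrides: dict[str, Any] | None = None):
        values = dict(DEFAULTS)
        for key, val in (overrides or {}).items():
            if key not in DEFAULTS:
                raise ConfigError(f"unknown config key: {key!r}")
            values[key] = _coerce(key, val)
        self._values = values

    def __getitem__(self, key: str) -> Any:
        if key not in self._values:
            raise ConfigError(f"unknown config key: {key!r}")
        return self._values[key]

    def as_dict(self) -> dict[str, Any]:
        return dict(self._values)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._values, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(json.loads(Path(path).read_text()))

    @classmethod
    def from_overrides(cls, pairs: list[str]) -> "PipelineConfig":
        """Build from ``key=value`` strings (CLI ``--set``)."""
        overrides: dict[str, Any] = {}
        for pair in pairs:
            if "=" not in pair:
                raise ConfigError(f"override must be key=value, got {pair!r}")
            key, raw = pair.split("=", 1)
            overrides[key.strip()] = _parse_literal(raw.strip())
        return cls(overrides)


def _parse_literal(raw: str) -> Any:
    try:
        return json.loads(raw)
    except json.JSONDecodeError:
        return raw


def _coerce(key: str, val: Any) -> Any:
    ref = DEFAULTS[key]
    if isinstance(ref, bool):
        if isinstance(val, bool):
            return val
        raise ConfigError(f"{key} expects a boolean, got {val!r}")
    if isinstance(ref, int) and not isinstance(ref, bool):
        if isinstance(val, (int, float)) and float(val) == int(val):
            return int(val)
        raise ConfigError(f"{key} expects an integer, got {val!r}")
    if isinstance(ref, float):
        if isinstance(val, (int, float)):
            return float(val)
        raise ConfigError(f"{key} expects a number, got {val!r}")
    if isinstance(ref, list):
        if isinstance(val, (list, tuple)) and len(val) == len(ref):
            return [float(v) for v in val]
        raise ConfigError(f"{key} expects a {len(ref)}-element list, got {val!r}")
    return val
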