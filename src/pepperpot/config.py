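"""Structured run configuration: geometry, media, whole-wing and fit settings.

One YAML file drives a pipeline run; section/key names follow the model
symbols (snake_case, lengths in nm), and the complex chitin index is given
as a ``[real, imag]`` pair.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import OpticalMedia, ScaleGeometry
from .wholewing import (
    DEFAULT_FLOOR,
    DEFAULT_HIGH_WINDOW,
    DEFAULT_LOW_WINDOW,
    DEFAULT_SIGMA_NM,
    BackgroundLine,
)

__all__ = ["RunConfig", "load_config", "dorsal_config", "ventral_config"]


@dataclass(frozen=True)
class FitSettings:
    x_fit: float = 0.5
    c_bounds: tuple[float, float] = (0.0, 1.0)
    s_bounds: tuple[float, float] = (0.0, 0.05)
    s_grid_points: int = 26
    window: tuple[float, float] = (200.0, 800.0)
    peak_window: tuple[float, float] = (400.0, 700.0)


@dataclass(frozen=True)
class WholeWingSettings:
    background: BackgroundLine = BackgroundLine(0.10, 5e-5)
    sigma_nm: float = DEFAULT_SIGMA_NM
    low_window: tuple[float, float] = DEFAULT_LOW_WINDOW
    high_window: tuple[float, float] = DEFAULT_HIGH_WINDOW
    floor: float = DEFAULT_FLOOR


@dataclass(frozen=True)
class RunConfig:
    geometry: ScaleGeometry
    media: OpticalMedia = field(default_factory=OpticalMedia)
    wholewing: WholeWingSettings = field(default_factory=WholeWingSettings)
    fit: FitSettings = field(default_factory=FitSettings)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        payload = json.dumps(_to_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _to_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, complex):
        return [obj.real, obj.imag]
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _geometry_from_dict(d: dict) -> ScaleGeometry:
    return ScaleGeometry.from_primary(
        p_xy=float(d["p_xy"]),
        d_a=float(d["d_a"]),
        d_b=float(d["d_b"]),
        w_a=float(d["w_a"]),
        w_b=float(d["w_b"]),
        c=float(d["c"]),
        n_stories=int(d.get("n_stories", 4)),
    )


def _media_from_dict(d: dict) -> OpticalMedia:
    chitin = d.get("n_chitin", [1.56, 0.033])
    return OpticalMedia(
        n_chitin=complex(float(chitin[0]), float(chitin[1])),
        n_ethanol=float(d.get("n_ethanol", 1.36)),
        n_air=float(d.get("n_air", 1.0)),
    )


def from_dict(data: dict) -> RunConfig:
    try:
        geometry = _geometry_from_dict(data["geometry"])
    except KeyError as e:
        raise ValueError(f"config geometry section missing key {e}") from None
    media = _media_from_dict(data.get("media", {}))
    ww = data.get("wholewing", {})
    bg = ww.get("background", {})
    wholewing = WholeWingSettings(
        background=BackgroundLine(float(bg.get("intercept", 0.10)),
                                  float(bg.get("slope", 5e-5))),
        sigma_nm=float(ww.get("sigma_nm", DEFAULT_SIGMA_NM)),
        low_window=tuple(ww.get("low_window", DEFAULT_LOW_WINDOW)),
        high_window=tuple(ww.get("high_window", DEFAULT_HIGH_WINDOW)),
        floor=float(ww.get("floor", DEFAULT_FLOOR)),
    )
    ft = data.get("fit", {})
    fit = FitSettings(
        x_fit=float(ft.get("x_fit", 0.5)),
        c_bounds=tuple(ft.get("c_bounds", (0.0, 1.0))),
        s_bounds=tuple(ft.get("s_bounds", (0.0, 0.05))),
        s_grid_points=int(ft.get("s_grid_points", 26)),
        window=tuple(ft.get("window", (200.0, 800.0))),
        peak_window=tuple(ft.get("peak_window", (400.0, 700.0))),
    )
    return RunConfig(geometry=geometry, media=media, wholewing=wholewing, fit=fit)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    return from_dict(data)


def dorsal_config() -> RunConfig:
    """Dorsal (blue) wing side with default media and settings."""
    from .geometry import dorsal_geometry

    return RunConfig(geometry=dorsal_geometry())


def ventral_config() -> RunConfig:
    """Ventral (gold-green) wing side with default media and settings."""
    from .geometry import ventral_geometry

    return RunConfig(geometry=ventral_geometry())
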