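"""TIFF and table I/O plus the flat run configuration.

Every study constant (40 nm pixel pitch, QC ratio 2.25, alpha 0.05, ...)
appears exactly once, as a :class:`RunConfig` default.  Configs serialize to
a flat ``key = value`` text file and round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import SHGMImage


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults."""

    pixel_nm: float = 40.0
    qc_max_ratio: float = 2.25
    orientation_scale_nm: float = 400.0
    trace_min_coherence: float = 0.2
    trace_min_length_um: float = 8.5
    transverse_half_width_px: float = 3.0
    acf_max_lag_um: float = 6.0
    fit_sl_min_um: float = 1.0
    fit_sl_max_um: float = 2.5
    fit_abl_min_um: float = 0.4
    fit_abl_max_um: float = 1.2
    fit_ttil_min_um: float = 0.04
    fit_ttil_max_um: float = 0.2
    alpha: float = 0.05
    aggregate: str = "fiber"
    seed: int = 0
    out_dir: str = "results"

    def fit_bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "sl_um": (self.fit_sl_min_um, self.fit_sl_max_um),
            "abl_um": (self.fit_abl_min_um, self.fit_abl_max_um),
            "ttil_um": (self.fit_ttil_min_um, self.fit_ttil_max_um),
        }

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            t = types[key]
            kwargs[key] = int(val) if t == "int" else float(val) if t == "float" else val
        return cls(**kwargs)


def write_image(path: str | Path, image: SHGMImage) -> None:
    """Write a single-channel 16-bit TIFF with the pixel pitch in its description."""
    data = np.clip(np.round(image.intensity), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        str(path), data, description=json.dumps({"pixel_nm": image.pixel_nm, "id": image.id})
    )


def read_image(path: str | Path, pixel_nm: float | None = None) -> SHGMImage:
    """Read a single-channel TIFF into an :class:`SHGMImage`.

    The pixel pitch is taken from ``pixel_nm`` if given, otherwise from the
    JSON image description written by :func:`write_image`; multi-channel data
    or a missing pitch raise explicit errors.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    if arr.ndim != 2:
        raise ValueError(f"expected single-channel 2-D TIFF, got shape {arr.shape}")
    image_id = Path(str(path)).stem
    if pixel_nm is None:
        try:
            meta = json.loads(desc)
            pixel_nm = float(meta["pixel_nm"])
            image_id = meta.get("id", image_id)
        except (json.JSONDecodeError, KeyError, TypeError):
            raise ValueError(
                f"{path}: no pixel pitch in TIFF description; pass pixel_nm explicitly"
            )
    return SHGMImage(intensity=arr.astype(float), pixel_nm=pixel_nm, id=image_id)


def write_truth(path: str | Path, truth) -> None:
    truth.to_frame().to_csv(path, index=False)


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
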