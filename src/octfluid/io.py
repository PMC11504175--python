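"""Image, mask, manifest and configuration I/O.

Images are PNG or TIFF, 8- or 16-bit grayscale, normalized to [0, 1] on
read by bit depth.  Label masks are single-channel 8-bit PNGs with literal
class values 0-3 (0 background, 1 IRF, 2 SRF, 3 PED).  Manifests are
tab-separated text, one record per image/mask pair.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .errors import ConfigError, OctFluidError, ShapeError

logger = logging.getLogger("octfluid")

VALID_LABELS = frozenset({0, 1, 2, 3})

# display convention: red = IRF (1), green = SRF (2), blue = PED (3)
CLASS_COLOURS = {1: (255, 0, 0), 2: (0, 255, 0), 3: (0, 0, 255)}

_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF into a float array in [0, 1].

    RGB inputs are converted by luminance with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise OctFluidError(f"image not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise OctFluidError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        logger.warning("RGB image %s converted to grayscale by luminance", path)
        arr = arr[..., :3] @ _LUMA
        scale = 255.0 if arr.max() <= 255 else 65535.0
        return np.clip(arr / scale, 0.0, 1.0)
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(float), 0.0, 1.0)
    raise OctFluidError(f"unsupported image dtype {arr.dtype} in {path}")


def write_image(path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float grid as 8-bit PNG or 16-bit TIFF by extension."""
    path = Path(path)
    pixels = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), np.round(pixels * 65535).astype(np.uint16))
    else:
        Image.fromarray(np.round(pixels * 255).astype(np.uint8), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    """Read a label mask PNG; values outside {0..3} raise a validation error."""
    path = Path(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise OctFluidError(f"mask {path} is not single-channel")
    bad = sorted(set(np.unique(arr).tolist()) - VALID_LABELS)
    if bad:
        raise OctFluidError(f"mask {path} contains invalid labels {bad}")
    return arr.astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    bad = sorted(set(np.unique(mask).tolist()) - VALID_LABELS)
    if bad:
        raise OctFluidError(f"mask contains invalid labels {bad}")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(Path(path))


def render_overlay(image: np.ndarray, mask: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend class colours onto the grayscale image (uint8 HxWx3)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ShapeError(f"image {image.shape} and mask {mask.shape} differ")
    base = np.repeat(np.round(np.clip(image, 0, 1) * 255)[..., None], 3, axis=2)
    out = base.astype(float)
    for cls, colour in CLASS_COLOURS.items():
        sel = mask == cls
        out[sel] = (1 - alpha) * out[sel] + alpha * np.array(colour, dtype=float)
    return np.round(out).astype(np.uint8)


# --------------------------------------------------------------- manifests

def write_manifest(path, records: list[dict]) -> None:
    """TSV manifest: image path, mask path, seed (one record per pair)."""
    lines = ["image\tmask\tseed"]
    for r in records:
        lines.append(f"{r['image']}\t{r['mask']}\t{r['seed']}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> list[dict]:
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    header = lines[0].split("\t")
    if header != ["image", "mask", "seed"]:
        raise OctFluidError(f"malformed manifest header in {path}: {header}")
    out = []
    for line in lines[1:]:
        img, msk, seed = line.split("\t")
        out.append({"image": img, "mask": msk, "seed": int(seed)})
    return out


# ----------------------------------------------------------- configuration

def dataclass_from_mapping(cls, mapping: dict, where: str):
    """Build a dataclass from a dict, rejecting unknown keys by name."""
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - field_names)
    if unknown:
        raise ConfigError(f"unknown key(s) {unknown} in {where}")
    kwargs = dict(mapping)
    for f in dataclasses.fields(cls):
        # YAML has no tuples; restore them for tuple-typed fields
        if f.name in kwargs and isinstance(kwargs[f.name], list) \
                and "tuple" in str(f.type):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_run_config(path):
    """Load a YAML run configuration into a RunConfig."""
    from .model import RunConfig  # local import to avoid a cycle

    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_mapping(raw)


def save_run_config(path, config) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_mapping(), sort_keys=False))
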