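"""TIFF and sidecar I/O for images, probability maps, and label maps.

Conventions: multichannel images are written as multi-page TIFF, one page
per channel per z-slice (channel-major), with a JSON sidecar
(``<name>.json``) recording the channel order, shape, and pixel size.
Instance label maps are 16-bit unsigned TIFF; probability maps are float32
TIFF with the three class pages (background, nuclei, cytoskeleton) per
z-slice.  Every pipeline command also writes a run manifest documenting
config, seed, package version, and input checksums, so any artifact is
reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

import lfseg
from lfseg.types import MultichannelImage


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_multichannel(path: str | Path, image: MultichannelImage) -> None:
    """Write channels as a channel-major multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    order = list(image.channels)
    shape = image.shape
    pages = []
    for name in order:
        channel = np.asarray(image.channels[name], dtype=np.float32)
        if channel.ndim == 3:
            pages.extend(channel)
        else:
            pages.append(channel)
    tifffile.imwrite(path, np.stack(pages))
    meta = {
        "kind": "multichannel",
        "channel_order": order,
        "shape": list(shape),
        "pixel_size_um": image.pixel_size,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_multichannel(path: str | Path) -> MultichannelImage:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    pages = tifffile.imread(path)
    shape = tuple(meta["shape"])
    order = meta["channel_order"]
    per_channel = len(pages) // len(order) if len(shape) == 3 else 1
    channels = {}
    for i, name in enumerate(order):
        if len(shape) == 3:
            channels[name] = np.asarray(pages[i * per_channel : (i + 1) * per_channel])
        else:
            channels[name] = np.asarray(pages[i]) if pages.ndim == 3 else np.asarray(pages)
    return MultichannelImage(channels=channels, pixel_size=meta.get("pixel_size_um"))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write an instance or class label map as 16-bit unsigned TIFF."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))).astype(np.int32)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a single-channel image (e.g. reflectance) as float32 TIFF."""
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))).astype(np.float64)


def write_probability_map(path: str | Path, probs: np.ndarray) -> None:
    """Write a (3, *spatial) class probability map as float32 TIFF."""
    probs = np.asarray(probs, dtype=np.float32)
    if probs.ndim not in (3, 4) or probs.shape[0] != 3:
        raise ValueError(f"expected (3, y, x) or (3, z, y, x), got {probs.shape}")
    tifffile.imwrite(Path(path), probs)
    meta = {
        "kind": "probability_map",
        "classes": ["background", "nuclei", "cytoskeleton"],
        "shape": list(probs.shape[1:]),
    }
    _sidecar_path(Path(path)).write_text(json.dumps(meta, indent=2))


def read_probability_map(path: str | Path) -> np.ndarray:
    probs = np.asarray(tifffile.imread(Path(path))).astype(np.float64)
    if probs.shape[0] != 3:
        raise ValueError(f"not a class probability map: shape {probs.shape}")
    return probs


# -- run manifests ---------------------------------------------------------


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: list[str | Path] = (),
    extra: dict | None = None,
) -> Path:
    """Write ``<artifact>.manifest.json`` beside a pipeline output."""
    out_path = Path(out_path)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "lfseg_version": lfseg.__version__,
        "numpy_version": np.__version__,
        "input_checksums": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
    }
    if extra:
        manifest.update(extra)
    path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(artifact_path: str | Path) -> dict | None:
    path = Path(str(artifact_path) + ".manifest.json")
    if not path.exists():
        return None
    return json.loads(path.read_text())


# -- synthetic scene persistence ------------------------------------------


def save_scene(out_dir: str | Path, scene) -> None:
    """Write a synthetic scene: channels, truth maps, positives, manifest."""
    from dataclasses import asdict

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_multichannel(out_dir / "channels.tif", scene.channels)
    write_labels(out_dir / "truth.tif", scene.truth)
    write_labels(out_dir / "nuclei_truth.tif", scene.nuclei_truth)
    meta = {
        "params": asdict(scene.params),
        "positives": sorted(scene.positives),
    }
    (out_dir / "scene.json").write_text(json.dumps(meta, indent=2))


def load_scene(scene_dir: str | Path):
    """Rebuild a :class:`~lfseg.synthetic.SyntheticScene` from disk."""
    from lfseg.synthetic import SceneParams, SyntheticScene

    scene_dir = Path(scene_dir)
    meta = json.loads((scene_dir / "scene.json").read_text())
    params_d = dict(meta["params"])
    params_d["shape"] = tuple(params_d["shape"])
    return SyntheticScene(
        params=SceneParams(**params_d),
        truth=read_labels(scene_dir / "truth.tif"),
        nuclei_truth=read_labels(scene_dir / "nuclei_truth.tif"),
        channels=read_multichannel(scene_dir / "channels.tif"),
        positives=frozenset(meta["positives"]),
    )
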