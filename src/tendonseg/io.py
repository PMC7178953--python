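"""Image/mask file I/O and run manifests.

Images and masks are 8-bit single-channel PNG (TIFF accepted for images);
masks use 0 = background, 255 = foreground and are binarized at 128 on
read.  Every pipeline command writes a RunManifest JSON capturing the
command, configuration snapshot, seed, and paths, from which the run can be
reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "RunManifest"]


def _load_gray(path) -> np.ndarray:
    path = Path(path)
    try:
        im = Image.open(path)
    except Exception as exc:
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    if im.mode == "I;16" or im.mode.startswith("I"):
        raise ValueError(
            f"{path}: 16-bit input not supported; convert to 8-bit grayscale first")
    if im.mode not in ("L", "1"):
        raise ValueError(
            f"{path}: expected 8-bit single-channel input, got mode '{im.mode}'; "
            "convert to grayscale ('L') first")
    return np.asarray(im.convert("L"), dtype=np.uint8)


def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF as a (H, W) uint8 array."""
    return _load_gray(path)


def write_image(path, img) -> None:
    """Write a (H, W) uint8 array as 8-bit grayscale PNG/TIFF (lossless)."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if img.max() <= 1.0:
            img = (img * 255).round().astype(np.uint8)
        else:
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(Path(path))


def read_mask(path) -> np.ndarray:
    """Read a mask PNG; pixels >= 128 become foreground (bool array)."""
    return _load_gray(path) >= 128


def write_mask(path, mask) -> None:
    """Write a binary mask as 0/255 grayscale PNG."""
    mask = np.asarray(mask).astype(bool)
    write_image(path, mask.astype(np.uint8) * 255)


def _package_version() -> str:
    try:
        return version("tendonseg")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunManifest:
    """One JSON record per pipeline run; round-trips losslessly."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    package_version: str = field(default_factory=_package_version)

    def start(self):
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def finish(self):
        self.finished = datetime.now(timezone.utc).isoformat()
        return self

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
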