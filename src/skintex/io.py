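"""Image and mask I/O plus run manifests.

All in-memory images use float arrays in [0, 1], row-major ``(row, col)``
indexing; binary masks are boolean arrays. Files are exchanged as 8-bit
PNG/JPEG/TIFF (16-bit inputs are accepted and scaled by 65535).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "RunManifest",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file and scale intensities to [0, 1].

    Returns a float64 array of shape (H, W) for single-channel files or
    (H, W, 3) for color files (an alpha channel, if present, is dropped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    # float input assumed already in [0, 1]
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a [0, 1] float image as 8-bit PNG (or other format by suffix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.round(data * 255.0).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 mask PNG as a boolean array."""
    return read_image(path) > 0.5


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as a single-channel 0/255 8-bit PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.where(mask.astype(bool), 255, 0).astype(np.uint8))
    return path


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one pipeline run: configs, seeds and produced artifacts."""

    config_hashes: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    file_index: list[dict] = field(default_factory=list)
    version: str = "0.1.0"

    def add_config(self, stage: str, config) -> None:
        self.config_hashes[stage] = _digest(config)

    def add_file(self, path: str | Path, role: str) -> None:
        path = Path(path)
        self.file_index.append(
            {
                "path": str(path),
                "role": role,
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path

    def validate(self) -> None:
        """Check every indexed artifact exists and hashes identically."""
        for entry in self.file_index:
            p = Path(entry["path"])
            if not p.exists():
                raise FileNotFoundError(f"manifest artifact missing: {p}")
            if hashlib.sha256(p.read_bytes()).hexdigest() != entry["sha256"]:
                raise ValueError(f"manifest artifact hash mismatch: {p}")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
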