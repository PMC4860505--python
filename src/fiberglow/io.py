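"""File I/O contracts: multi-page TIFF image sets, annotated CSV tables and
run manifests.

All tabular outputs are comma-separated UTF-8 with ``.`` decimals. Each CSV
begins with ``#``-prefixed comment lines recording the units and the
calibration constants (kb/um, um/px) the numbers depend on; kb values are
written to three decimals. Image sets are 16-bit multi-page TIFFs with the
channel names and pixel scale in the image description, and round-trip
losslessly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .render import ImageSet

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed image or table files."""


def write_imageset(image_set: ImageSet, path) -> None:
    """Write an image set as a multi-page 16-bit TIFF with JSON metadata."""
    path = Path(path)
    names = list(image_set.channels)
    stack = np.stack([image_set.channels[ch] for ch in names]).astype(np.uint16)
    desc = json.dumps(
        {"channels": names, "pixel_um": image_set.pixel_um, "meta": image_set.meta}, default=float
    )
    tifffile.imwrite(path, stack, description=desc, metadata=None, photometric="minisblack")


def read_imageset(path, required_channels=("cldU", "idU", "qdot")) -> ImageSet:
    """Read an image set written by :func:`write_imageset`.

    8-bit pages are accepted and up-converted to 16-bit (x257) with a
    warning; a missing required channel raises :class:`FormatError` naming
    the channel.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description or ""
    try:
        info = json.loads(desc)
        names = info["channels"]
        pixel_um = float(info["pixel_um"])
        meta = dict(info.get("meta", {}))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"{path}: missing or malformed image metadata: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(names):
        raise FormatError(f"{path}: {stack.shape[0]} pages but {len(names)} channel names {names}")
    if stack.dtype == np.uint8:
        log.warning("%s: 8-bit input up-converted to 16-bit", path)
        stack = stack.astype(np.uint16) * 257
    elif stack.dtype != np.uint16:
        raise FormatError(f"{path}: unsupported dtype {stack.dtype}; expected uint8 or uint16")
    channels = {ch: stack[i] for i, ch in enumerate(names)}
    for ch in required_channels:
        if ch not in channels:
            raise FormatError(f"{path}: required channel {ch!r} missing (found {names})")
    return ImageSet(channels=channels, pixel_um=pixel_um, meta=meta)


def write_table(df: pd.DataFrame, path, units: dict[str, str] | None = None, calibration: dict | None = None) -> None:
    """Write a CSV with comment lines naming units and calibration constants."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].round(3)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if units:
            fh.write("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()) + "\n")
        if calibration:
            fh.write("# calibration: " + ", ".join(f"{k}={v}" for k, v in calibration.items()) + "\n")
        df.to_csv(fh, index=False, float_format="%.3f")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record sufficient to re-run a deterministic stage chain."""

    config_hash: str
    seed: int
    version: str
    created_utc: str = ""
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # relative path -> sha256

    def __post_init__(self) -> None:
        if not self.created_utc:
            self.created_utc = datetime.now(timezone.utc).isoformat()

    def add_output(self, root: Path, path: Path) -> None:
        self.outputs[str(path.relative_to(root))] = sha256_file(path)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def validate(self, root) -> list[str]:
        """Return the relative paths whose checksum no longer matches."""
        root = Path(root)
        return [rel for rel, digest in self.outputs.items() if sha256_file(root / rel) != digest]
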