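"""Readers, writers, run configuration and manifests.

Images travel as single-channel 8/16-bit TIFF (multi-page for
time-lapse stacks) with the intensity-scaling convention recorded in
the image description tag.  ROIs use a documented JSON polygon schema
(canonical) plus a reader for the de-facto binary ``.roi`` / roi-zip
dialect of the common image-analysis tool.  Tables are CSV.  Every CLI
run writes a manifest recording the effective config hash, software
version, input checksums and output files, so identical inputs
reproduce identical outputs for deterministic stages.

ROI JSON schema (version 1)::

    {
      "schema": "virtustain-roi-1",
      "rois": [
        {
          "cell_id": "cell_0001",
          "phenotype": "SS" | "RS" | "FC" | null,
          "cell_polygon": [[x, y], ...],       # pixel coordinates
          "nucleus_polygon": [[x, y], ...] | null
        }, ...
      ]
    }
"""

from __future__ import annotations

import hashlib
import json
import struct
import zipfile
from dataclasses import dataclass, field as _field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from virtustain.cellprofile import CellROI
from virtustain.errors import FormatError, ValidationError

__all__ = [
    "read_image",
    "write_image",
    "to_float",
    "from_float",
    "read_rois_json",
    "write_rois_json",
    "read_roi_imagej",
    "read_rois_zip",
    "RunConfig",
    "Manifest",
]

ROI_SCHEMA = "virtustain-roi-1"

#: intensity convention: float images in [0, 1] scale linearly to the
#: full range of the stored integer dtype
FLOAT_SCALE = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}


def to_float(img: np.ndarray) -> np.ndarray:
    """Stored integer image -> float in [0, 1]."""
    img = np.asarray(img)
    if img.dtype in FLOAT_SCALE:
        return img.astype(np.float64) / FLOAT_SCALE[img.dtype]
    return img.astype(np.float64)


def from_float(img: np.ndarray, dtype="uint16") -> np.ndarray:
    """Float [0, 1] image -> integer image of the given dtype (clipped)."""
    dtype = np.dtype(dtype)
    if dtype not in FLOAT_SCALE:
        raise FormatError(f"unsupported target dtype {dtype}")
    scale = FLOAT_SCALE[dtype]
    return (np.clip(np.asarray(img, dtype=np.float64), 0, 1) * scale + 0.5).astype(
        dtype
    )


def write_image(path, image: np.ndarray) -> None:
    """Write a single- or multi-page grayscale TIFF.

    Accepts uint8/uint16 arrays (stored losslessly) or float arrays in
    [0, 1] (stored as uint16).  2-D arrays become one page; 3-D arrays
    (frames, H, W) one page per frame.
    """
    img = np.asarray(image)
    if img.ndim not in (2, 3):
        raise FormatError(f"expected 2-D image or 3-D stack, got ndim={img.ndim}")
    if np.issubdtype(img.dtype, np.floating):
        img = from_float(img)
    if img.dtype not in FLOAT_SCALE:
        raise FormatError(f"unsupported bit depth: {img.dtype}")
    desc = json.dumps(
        {"scaling": "linear [0,1] x full dtype range", "dtype": str(img.dtype)}
    )
    tifffile.imwrite(path, img, description=desc, photometric="minisblack")


def read_image(path) -> np.ndarray:
    """Read a grayscale 8/16-bit TIFF; multi-page files return a stack
    of frames in page order.  RGB or other bit depths are rejected."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < arr.shape[0]:
        raise FormatError("RGB TIFF not supported; images must be single-channel")
    if arr.dtype not in FLOAT_SCALE:
        raise FormatError(f"unsupported bit depth: {arr.dtype}")
    return arr


# ---------------------------------------------------------------------------
# ROI files

def _roi_to_dict(roi: CellROI) -> dict:
    return {
        "cell_id": roi.cell_id,
        "phenotype": roi.phenotype_label,
        "cell_polygon": np.asarray(roi.cell_polygon, dtype=float).tolist(),
        "nucleus_polygon": (
            np.asarray(roi.nucleus_polygon, dtype=float).tolist()
            if roi.nucleus_polygon is not None
            else None
        ),
    }


def write_rois_json(rois: list[CellROI], path) -> None:
    doc = {"schema": ROI_SCHEMA, "rois": [_roi_to_dict(r) for r in rois]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_rois_json(path) -> list[CellROI]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != ROI_SCHEMA:
        raise FormatError(
            f"unknown ROI schema {doc.get('schema')!r}; expected {ROI_SCHEMA!r}"
        )
    rois = []
    for d in doc["rois"]:
        rois.append(
            CellROI(
                cell_id=d["cell_id"],
                cell_polygon=np.asarray(d["cell_polygon"], dtype=float),
                nucleus_polygon=(
                    np.asarray(d["nucleus_polygon"], dtype=float)
                    if d.get("nucleus_polygon")
                    else None
                ),
                phenotype_label=d.get("phenotype"),
            )
        )
    return rois


_IJ_POLYGON_TYPES = {0, 3, 7}  # polygon, freehand line(excluded below), freehand


def read_roi_imagej(data: bytes, cell_id: str = "roi") -> CellROI:
    """Parse one binary ``.roi`` record (polygon/freehand outlines).

    Minimal reader for the common image-analysis tool's format: magic
    "Iout", ROI type at offset 6, bounds at 8..16, vertex count at 16,
    and int16 coordinates relative to (left, top) starting at 64.
    """
    if len(data) < 64 or data[:4] != b"Iout":
        raise FormatError("not an ImageJ .roi record (missing 'Iout' magic)")
    roi_type = data[6]
    if roi_type not in (0, 7):  # 0=polygon, 7=freehand
        raise FormatError(f"unsupported ROI type {roi_type}; need a polygon outline")
    top, left, _bottom, _right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">h", data[16:18])[0]
    if n < 3:
        raise FormatError("ROI has fewer than 3 vertices")
    end = 64 + 4 * n
    if len(data) < end:
        raise FormatError("truncated .roi record")
    xs = np.frombuffer(data[64 : 64 + 2 * n], dtype=">i2").astype(float) + left
    ys = np.frombuffer(data[64 + 2 * n : end], dtype=">i2").astype(float) + top
    return CellROI(cell_id=cell_id, cell_polygon=np.column_stack([xs, ys]))


def read_rois_zip(path) -> list[CellROI]:
    """Read every polygon ROI from a roi-zip archive."""
    rois = []
    with zipfile.ZipFile(path) as zf:
        for name in sorted(zf.namelist()):
            if name.endswith(".roi"):
                rois.append(
                    read_roi_imagej(zf.read(name), cell_id=Path(name).stem)
                )
    return rois


# ---------------------------------------------------------------------------
# configuration and manifests

@dataclass
class RunConfig:
    """Merged run configuration (YAML file, overridden by CLI flags)."""

    seed: int = 0
    paths: dict = _field(default_factory=dict)
    translator: dict = _field(default_factory=dict)
    metrics: dict = _field(default_factory=lambda: {
        "kernel_size": 31, "confidence_level": 0.60,
    })
    temporal: dict = _field(default_factory=lambda: {
        "detrend": True, "max_head_fraction": 0.25, "profile_length": 100,
    })
    schema_version: int = 1

    @classmethod
    def load(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if doc.get("schema_version", 1) != 1:
            raise FormatError(
                f"unsupported config schema_version {doc.get('schema_version')}"
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate_paths(self) -> None:
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise ValidationError(f"configured path {key}={p!r} does not exist")

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "paths": dict(self.paths),
            "translator": dict(self.translator),
            "metrics": dict(self.metrics),
            "temporal": dict(self.temporal),
        }

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Per-run provenance record."""

    stage: str
    config: dict
    software_version: str
    inputs: dict = _field(default_factory=dict)  # path -> sha256
    outputs: list = _field(default_factory=list)

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def write(self, path) -> None:
        doc = {
            "stage": self.stage,
            "software_version": self.software_version,
            "config": self.config,
            "config_hash": self.config_hash,
            "inputs": self.inputs,
            "outputs": sorted(self.outputs),
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
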