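"""TIFF + JSON-sidecar I/O for frames, phase maps, phantoms and labels.

Dialect: 32-bit float little-endian TIFF; raw frame sets are 4-page files
in fixed arm order (+x, -x, +y, -y); phase maps are single-page; label
masks are uint8.  Every write produces a ``<name>.json`` sidecar with
provenance; reads tolerate a missing sidecar with a warning.  Write->read
round trips are bit-exact.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .forward import RawFrameSet
from .reconstruct import PhaseImage

__all__ = [
    "ARM_ORDER",
    "write_frames",
    "read_frames",
    "write_phase",
    "read_phase",
    "write_labels",
    "read_labels",
    "write_phantom_maps",
    "write_transfer_functions",
]

ARM_ORDER = ("+x", "-x", "+y", "-y")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    _sidecar(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar(path)
    if not sc.exists():
        warnings.warn(f"missing sidecar {sc.name}; provenance unavailable", stacklevel=3)
        return {}
    return json.loads(sc.read_text())


def write_frames(path, frames: RawFrameSet) -> None:
    """Write a 4-page float32 TIFF (+x, -x, +y, -y) with a JSON sidecar."""
    path = Path(path)
    missing = [a for a in ARM_ORDER if a not in frames.frames]
    if missing:
        raise ValueError(f"frame set is missing arms {missing}")
    stack = np.stack([frames.frames[a].astype(np.float32) for a in ARM_ORDER])
    tifffile.imwrite(path, stack, byteorder="<", photometric="minisblack")
    _write_sidecar(
        path,
        {
            "kind": "raw_frames",
            "arm_order": list(ARM_ORDER),
            "exposure_meta": frames.exposure_meta,
            "sys_ref": frames.sys_ref,
        },
    )


def read_frames(path) -> RawFrameSet:
    """Read a 4-page frame TIFF written by :func:`write_frames`."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 4:
        n = 1 if stack.ndim == 2 else stack.shape[0]
        raise ValueError(f"expected 4 pages in {path.name}, got {n}")
    if stack.dtype != np.float32:
        raise ValueError(f"expected float32 frames in {path.name}, got {stack.dtype}")
    meta = _read_sidecar(path)
    return RawFrameSet(
        frames={a: stack[i] for i, a in enumerate(ARM_ORDER)},
        exposure_meta=meta.get("exposure_meta", {}),
        sys_ref=meta.get("sys_ref", {}),
    )


def write_phase(path, img: PhaseImage) -> None:
    """Write a reconstructed phase map as single-page float32 TIFF (radians)."""
    path = Path(path)
    tifffile.imwrite(path, img.phase.astype(np.float32), byteorder="<")
    _write_sidecar(
        path,
        {
            "kind": "phase",
            "units": "radians",
            "alpha": img.alpha,
            "provenance": img.provenance,
        },
    )


def read_phase(path) -> PhaseImage:
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"expected single-page phase TIFF in {path.name}")
    if arr.dtype != np.float32:
        raise ValueError(f"expected float32 phase in {path.name}, got {arr.dtype}")
    meta = _read_sidecar(path)
    return PhaseImage(
        phase=arr.astype(float),
        alpha=float(meta.get("alpha", np.nan)),
        provenance=meta.get("provenance", {}),
    )


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.uint8), byteorder="<")


def read_labels(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.dtype != np.uint8:
        raise ValueError(f"expected uint8 label mask, got {arr.dtype}")
    return arr


def write_phantom_maps(path, phantom) -> None:
    """Write phantom phase + absorption as a 2-page float32 TIFF + sidecar."""
    path = Path(path)
    stack = np.stack(
        [phantom.phase.astype(np.float32), phantom.absorption.astype(np.float32)]
    )
    tifffile.imwrite(path, stack, byteorder="<", photometric="minisblack")
    _write_sidecar(path, {"kind": "phantom", "pages": ["phase", "absorption"],
                          "meta": phantom.meta})


def write_transfer_functions(path, tf) -> None:
    """Export one arm's WOTFs for inspection: 4 float32 pages
    (Re/Im H_abs, Re/Im H_ph)."""
    path = Path(path)
    stack = np.stack(
        [
            tf.h_abs.real.astype(np.float32),
            tf.h_abs.imag.astype(np.float32),
            tf.h_ph.real.astype(np.float32),
            tf.h_ph.imag.astype(np.float32),
        ]
    )
    tifffile.imwrite(path, stack, byteorder="<", photometric="minisblack")
    _write_sidecar(
        path,
        {
            "kind": "transfer_functions",
            "pages": ["h_abs_re", "h_abs_im", "h_ph_re", "h_ph_im"],
            "background": tf.background,
            "source_label": tf.source_label,
        },
    )
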