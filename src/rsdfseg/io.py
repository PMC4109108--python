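"""Image/mask I/O and run artefact writers.

Images are ingested as single-channel float fields on [0, 255]: integer
inputs are scaled by their dtype range (so 16-bit data maps linearly onto
[0, 255]), float inputs are min-max rescaled, and RGB(A) inputs are reduced
to luminance.  Masks round-trip as 8-bit PNGs with inside = 255.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict
from typing import Optional

import imageio.v3 as iio
import numpy as np

from .engine import SegmentationResult
from .errors import ImageIOError

__all__ = [
    "load_image",
    "save_mask",
    "load_mask",
    "save_phantom",
    "write_trace_csv",
    "write_result_json",
]

MIN_IMAGE_SIDE = 16


def load_image(path: str) -> np.ndarray:
    """Read a PNG/TIFF/NumPy ``.npy`` image as a [0, 255] float field."""
    if not os.path.exists(path):
        raise ImageIOError(f"input image not found: {path}")
    try:
        if path.endswith(".npy"):
            arr = np.load(path)
        else:
            arr = iio.imread(path)
    except ImageIOError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap every reader failure
        raise ImageIOError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        if np.issubdtype(arr.dtype, np.integer):
            rgb /= np.iinfo(arr.dtype).max
        # ITU-R 709 luminance
        arr = rgb @ np.array([0.2126, 0.7152, 0.0722])
        arr = arr * 255.0
    elif arr.ndim == 2:
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float64) * (255.0 / np.iinfo(arr.dtype).max)
        else:
            arr = arr.astype(np.float64)
            lo, hi = float(arr.min()), float(arr.max())
            if hi > lo:
                arr = (arr - lo) * (255.0 / (hi - lo))
            else:
                arr = np.clip(arr, 0.0, 255.0)
    else:
        raise ImageIOError(
            f"{path}: expected a single-channel or RGB(A) 2-D image, got shape {arr.shape}"
        )

    if not np.all(np.isfinite(arr)):
        raise ImageIOError(f"{path}: image contains non-finite values")
    if min(arr.shape) < MIN_IMAGE_SIDE:
        raise ImageIOError(
            f"{path}: image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}, "
            f"got {arr.shape}"
        )
    return arr


def save_mask(path: str, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (inside = 255, outside = 0)."""
    m = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    try:
        iio.imwrite(path, m)
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"could not write mask {path}: {exc}") from exc


def load_mask(path: str) -> np.ndarray:
    """Read a mask PNG back to a boolean field (threshold at half range)."""
    if not os.path.exists(path):
        raise ImageIOError(f"mask not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"could not read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (np.iinfo(arr.dtype).max // 2 if np.issubdtype(arr.dtype, np.integer)
                  else 0.5)


def save_phantom(out_dir: str, stem: str, image: np.ndarray,
                 truth: np.ndarray, spec_json: str) -> dict:
    """Write a phantom as 16-bit image PNG + truth PNG + JSON sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    img_path = os.path.join(out_dir, f"{stem}.png")
    truth_path = os.path.join(out_dir, f"{stem}_truth.png")
    json_path = os.path.join(out_dir, f"{stem}.json")
    img16 = np.round(np.clip(image, 0, 255) / 255.0 * 65535.0).astype(np.uint16)
    try:
        iio.imwrite(img_path, img16)
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"could not write phantom image {img_path}: {exc}") from exc
    save_mask(truth_path, truth)
    with open(json_path, "w") as fh:
        fh.write(spec_json + "\n")
    return {"image": img_path, "truth": truth_path, "spec": json_path}


def write_trace_csv(path: str, result: SegmentationResult) -> None:
    """Per-iteration evolution log: sign-change count and energy breakdown."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iter", "delta_pixels", "E_G", "E_L", "J_G", "J_L",
                         "L", "R", "F"])
        for i, (d, e) in enumerate(zip(result.zero_crossing_deltas,
                                       result.energy_trace), start=1):
            writer.writerow([i, d, e.E_G, e.E_L, e.J_G, e.J_L,
                             e.L_len, e.R_reg, e.F_total])


def write_result_json(path: str, result: SegmentationResult, params,
                      init_desc: str, jaccard_score: Optional[float] = None,
                      extra: Optional[dict] = None) -> None:
    """Run summary with a full parameter echo sufficient to re-run."""
    payload = {
        "params": asdict(params),
        "init": init_desc,
        "n_iter": result.n_iter,
        "converged": result.converged,
        "diagnostic": result.diagnostic,
        "mask_pixels": int(result.mask.sum()),
    }
    if jaccard_score is not None:
        payload["jaccard"] = jaccard_score
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
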