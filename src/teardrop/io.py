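"""Image and array export helpers for displays and activity maps."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .stimuli import VisualDisplay


def to_uint8(arr: np.ndarray, vmax: float | None = None) -> np.ndarray:
    """Scale a nonnegative array to uint8 grey levels (0..255)."""
    arr = np.asarray(arr, float)
    hi = float(vmax) if vmax else max(float(arr.max()), 1e-12)
    return np.clip(255.0 * arr / hi, 0, 255).astype(np.uint8)


def save_png(path: str | Path, arr: np.ndarray, vmax: float | None = None) -> None:
    iio.imwrite(Path(path), to_uint8(arr, vmax))


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as floats in [0, 1] (natural-scene demos)."""
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img.astype(float) / max(float(img.max()), 1e-12)


def save_pgm(path: str | Path, arr: np.ndarray, vmax: float | None = None) -> None:
    """Plain-text (P2) PGM writer, handy for diff-able activity dumps."""
    a = to_uint8(arr, vmax)
    lines = [f"P2\n{a.shape[1]} {a.shape[0]}\n255\n"]
    lines += [" ".join(str(v) for v in row) + "\n" for row in a]
    Path(path).write_text("".join(lines))


def mask_to_rle(mask: np.ndarray) -> dict:
    """Row-major run-length encoding of a boolean mask (JSON-friendly)."""
    flat = np.asarray(mask, bool).ravel()
    runs = []
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    prev = 0
    for c in changes.tolist() + [flat.size - 1]:
        runs.append(int(c + 1 - prev))
        prev = c + 1
    return {"shape": list(mask.shape), "first": bool(flat[0]), "runs": runs}


def rle_to_mask(rle: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(rle["shape"])), bool)
    val = rle["first"]
    pos = 0
    for r in rle["runs"]:
        flat[pos:pos + r] = val
        pos += r
        val = not val
    return flat.reshape(rle["shape"])


def export_display(display: VisualDisplay, out_dir: str | Path) -> Path:
    """Write a display's image (PNG) and masks (RLE JSON) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_png(out / f"{display.name}.png", display.image, vmax=1.0)
    meta = {
        "name": display.name,
        "params": display.params,
        "seed": display.seed,
        "figure_mask": mask_to_rle(display.figure_mask),
        "boundary_mask": mask_to_rle(display.boundary_mask),
        "medial_mask": mask_to_rle(display.medial_mask),
    }
    path = out / f"{display.name}.json"
    path.write_text(json.dumps(meta))
    return path


def export_activity_stack(activity: np.ndarray, out_dir: str | Path,
                          prefix: str) -> list[Path]:
    """Write one PNG per channel of an (H, W, C) activity array."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vmax = max(float(activity.max()), 1e-12)
    paths = []
    for c in range(activity.shape[2]):
        p = out / f"{prefix}_{c + 1}.png"
        save_png(p, activity[:, :, c], vmax=vmax)
        paths.append(p)
    return paths
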