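"""File I/O: HDF5 hypercube container, TIFF export, two-column spectra.

The container layout is a single HDF5 file with datasets ``cube``
(m x n x s), ``axis`` (s) and file attributes for metadata (exposure_ms,
seed, config hash, ...).  Reference and retrieved spectra round-trip
through plain two-column text (wavenumber, intensity).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .axes import WavenumberAxis
from .containers import Hypercube, ReferenceSet


def save_hypercube(path, cube: Hypercube) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data, compression="gzip")
        f.create_dataset("axis", data=cube.axis.values)
        for key, val in cube.meta.items():
            try:
                f.attrs[key] = val
            except TypeError:
                f.attrs[key] = json.dumps(val)


def load_hypercube(path) -> Hypercube:
    with h5py.File(path, "r") as f:
        data = f["cube"][...]
        axis = WavenumberAxis(f["axis"][...])
        meta = {k: f.attrs[k] for k in f.attrs}
    return Hypercube(data=data, axis=axis, meta=meta)


def export_tiff(path, cube_or_images: np.ndarray) -> None:
    """Export a cube or an image stack as a multi-page float32 TIFF.

    An (m, n, c) array is written as c pages of (m, n) so channel images
    open as a stack in standard viewers.
    """
    arr = np.asarray(cube_or_images, dtype=np.float32)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    tifffile.imwrite(path, arr, photometric="minisblack")


def export_rgb_png(path, abundance_stack: np.ndarray,
                   percentile: float = 99.0) -> None:
    """False-color composite: up to 3 abundance images -> R, G, B channels.

    Each channel is independently scaled to its `percentile` value.
    """
    from PIL import Image

    ab = np.asarray(abundance_stack, dtype=float)
    if ab.ndim != 3 or ab.shape[-1] > 3:
        raise ValueError("expected (m, n, k<=3) abundance stack")
    m, n, k = ab.shape
    rgb = np.zeros((m, n, 3))
    for c in range(k):
        top = np.percentile(ab[..., c], percentile)
        if top > 0:
            rgb[..., c] = np.clip(ab[..., c] / top, 0, 1)
    Image.fromarray((rgb * 255).astype(np.uint8)).save(path)


def save_spectrum(path, axis: WavenumberAxis, intensity: np.ndarray,
                  header: str = "wavenumber_cm-1 intensity") -> None:
    np.savetxt(path, np.column_stack([axis.values, intensity]), header=header)


def load_spectrum(path):
    arr = np.loadtxt(path)
    return WavenumberAxis(arr[:, 0]), arr[:, 1]


def save_reference_set(directory, ref: ReferenceSet) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in ("analyte_mean", "nrb_mean", "dark_mean"):
        save_spectrum(d / f"{name}.txt", ref.axis, getattr(ref, name))
    (d / "meta.json").write_text(json.dumps({"n_averaged": ref.n_averaged}))


def load_reference_set(directory) -> ReferenceSet:
    d = Path(directory)
    spectra = {}
    axis = None
    for name in ("analyte_mean", "nrb_mean", "dark_mean"):
        axis, spectra[name] = load_spectrum(d / f"{name}.txt")
    meta = json.loads((d / "meta.json").read_text())
    return ReferenceSet(axis=axis, n_averaged=meta["n_averaged"], **spectra)
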