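"""In-memory containers for hypercubes and reference spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import WavenumberAxis


@dataclass
class Hypercube:
    """An m x n x s intensity cube with a calibrated wavenumber axis.

    `data[i, j, :]` is the spectrum of spatial pixel (i, j) on `axis`.
    `meta` carries acquisition/provenance keys (exposure_ms, seed, ...).
    """

    data: np.ndarray
    axis: WavenumberAxis
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("cube data must be m x n x s")
        if d.shape[2] != self.axis.channel_count:
            raise ValueError(
                f"cube has {d.shape[2]} channels but axis has "
                f"{self.axis.channel_count}"
            )
        self.data = d

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def pixels(self) -> np.ndarray:
        """View of the cube as (pixels, channels), row-major over (m, n)."""
        m, n, s = self.data.shape
        return self.data.reshape(m * n, s)

    def with_data(self, data: np.ndarray) -> "Hypercube":
        return Hypercube(data=data, axis=self.axis, meta=dict(self.meta))


@dataclass
class ReferenceSet:
    """Averaged analyte, NRB and dark reference spectra on a shared axis.

    Mirrors the instrument protocol of recording ~100 spectra each of a
    known analyte (toluene), of a bare quartz coverslip (taken as the pure
    nonresonant background) and of the closed shutter (dark), then
    averaging each set.
    """

    axis: WavenumberAxis
    analyte_mean: np.ndarray
    nrb_mean: np.ndarray
    dark_mean: np.ndarray
    n_averaged: int = 1

    def __post_init__(self):
        s = self.axis.channel_count
        for name in ("analyte_mean", "nrb_mean", "dark_mean"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (s,):
                raise ValueError(f"{name} must have {s} channels")
            setattr(self, name, v)
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")
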