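"""Spectral unmixing: N-FINDR endmember extraction + NNLS abundances.

N-FINDR assumes the linear mixing model with pure pixels: the spectra of
a k-species image live inside the simplex whose vertices are the pure
spectra.  After projecting the pixels to (k-1) principal-component
dimensions, the algorithm seeks the k pixels spanning the
maximum-volume simplex,

    V(E) = |det E| / (k-1)!,   E = [[1 ... 1], [e_1 ... e_k]]

by iterated single-pixel replacement: every pixel is tried in every
endmember slot, a replacement is kept when it strictly increases the
volume, and the sweep repeats until no replacement survives.  The
selected pixels' original spectra are the endmembers; per-pixel
abundances follow from nonnegatively constrained least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .containers import Hypercube

logger = logging.getLogger(__name__)


def simplex_volume(points: np.ndarray) -> float:
    """Volume of the simplex spanned by k points in (k-1) dimensions.

    `points` is (k, k-1).  Volume = |det of the augmented matrix with a top
    row of ones and the points as columns| / (k-1)!.
    """
    pts = np.asarray(points, dtype=float)
    k = pts.shape[0]
    if pts.ndim != 2 or pts.shape[1] != k - 1:
        raise ValueError(f"expected {k} points in {k - 1} dimensions")
    aug = np.vstack([np.ones(k), pts.T])  # (k, k)
    return abs(np.linalg.det(aug)) / factorial(k - 1)


def _as_pixel_matrix(cube_or_matrix):
    if isinstance(cube_or_matrix, Hypercube):
        return cube_or_matrix.pixels(), cube_or_matrix.shape[:2]
    arr = np.asarray(cube_or_matrix, dtype=float)
    if arr.ndim == 3:
        m, n, s = arr.shape
        return arr.reshape(m * n, s), (m, n)
    if arr.ndim != 2:
        raise ValueError("expected a Hypercube, an (m,n,s) cube or a (p,s) matrix")
    return arr, None


@dataclass
class EndmemberSet:
    """k endmember spectra and the pixel indices they came from."""

    spectra: np.ndarray  # (k, s)
    pixel_indices: np.ndarray  # (k,) flat indices into the pixel matrix
    volume: float

    @property
    def k(self) -> int:
        return self.spectra.shape[0]

    def __post_init__(self):
        sv = np.linalg.svd(self.spectra, compute_uv=False)
        if sv[-1] <= 1e-8 * sv[0]:
            raise ValueError("endmember spectra are linearly dependent")


@dataclass
class AbundanceMap:
    """Nonnegative per-pixel abundances and reconstruction residuals."""

    values: np.ndarray  # (m, n, k) or (p, k)
    residual: np.ndarray  # (m, n) or (p,)


class NFINDR(BaseEstimator, TransformerMixin):
    """Simplex-volume endmember extraction with NNLS abundance transform.

    Parameters
    ----------
    n_endmembers : int
        Number of endmembers k (chosen by the analyst; there is no
        automatic selection).
    max_sweeps : int
        Cap on full replacement sweeps per restart.
    n_restarts : int
        Random initializations; the highest-volume run wins, mitigating
        the sensitivity to the random start.
    random_state : int
        Seed for the initial endmember draws.

    Attributes
    ----------
    endmembers_ : EndmemberSet with the original (unreduced) spectra.
    components_ : (k, s) endmember spectra (sklearn naming).
    volume_ : simplex volume attained in reduced space.
    n_sweeps_ : sweeps used by the winning restart.
    """

    def __init__(self, n_endmembers: int = 3, max_sweeps: int = 20,
                 n_restarts: int = 5, random_state: int = 0):
        self.n_endmembers = n_endmembers
        self.max_sweeps = max_sweeps
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- core algorithm ----------------------------------------------------

    @staticmethod
    def _sweep(reduced_aug: np.ndarray, idx: np.ndarray, max_sweeps: int):
        """Endmember-major, pixel-minor replacement until a sweep is quiet.

        `reduced_aug` is (p, k): each pixel as a column vector [1, x]^T of
        the augmented determinant.  Uses Cramer's rule to evaluate all
        candidate determinants for one slot in a single matrix product.
        """
        k = idx.size
        sweeps = 0
        E = reduced_aug[idx].T.copy()  # (k, k) columns = endmembers
        best = abs(np.linalg.det(E))
        while sweeps < max_sweeps:
            sweeps += 1
            changed = False
            for slot in range(k):
                det_E = np.linalg.det(E)
                if abs(det_E) > 1e-300:
                    # det with column `slot` replaced by x = det(E) * (E^-1 x)[slot]
                    row = np.linalg.inv(E)[slot]
                    cand = np.abs(det_E * (reduced_aug @ row))
                else:  # degenerate start: brute-force the column replacement
                    cand = np.empty(reduced_aug.shape[0])
                    Etmp = E.copy()
                    for p in range(reduced_aug.shape[0]):
                        Etmp[:, slot] = reduced_aug[p]
                        cand[p] = abs(np.linalg.det(Etmp))
                cand[idx] = -np.inf  # a pixel may occupy only one slot
                p_best = int(np.argmax(cand))
                if cand[p_best] > best * (1 + 1e-12) and cand[p_best] > best:
                    idx[slot] = p_best
                    E[:, slot] = reduced_aug[p_best]
                    best = cand[p_best]
                    changed = True
            if not changed:
                break
        return idx, best, sweeps

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, y=None):
        pixels, spatial = _as_pixel_matrix(X)
        self._spatial_shape = spatial
        k = int(self.n_endmembers)
        if k < 2:
            raise ValueError("need at least 2 endmembers")
        p = pixels.shape[0]
        if p < k:
            raise ValueError("fewer pixels than endmembers")
        if np.allclose(pixels.std(axis=0), 0):
            raise ValueError("zero-variance data: nothing to unmix")

        pca = PCA(n_components=k - 1, random_state=0)
        reduced = pca.fit_transform(pixels)  # (p, k-1)
        aug = np.hstack([np.ones((p, 1)), reduced])  # (p, k)

        rng = np.random.default_rng(self.random_state)
        best_idx, best_vol, best_sweeps = None, -np.inf, 0
        for _ in range(max(1, int(self.n_restarts))):
            idx = rng.choice(p, size=k, replace=False)
            idx, vol, sweeps = self._sweep(aug, idx.copy(), self.max_sweeps)
            if sweeps >= self.max_sweeps:
                logger.info("N-FINDR restart hit the sweep cap (%d)", sweeps)
            if vol > best_vol:
                best_idx, best_vol, best_sweeps = np.sort(idx), vol, sweeps

        self.pca_ = pca
        self.volume_ = best_vol / factorial(k - 1)
        self.n_sweeps_ = best_sweeps
        self.endmembers_ = EndmemberSet(
            spectra=pixels[best_idx].copy(),
            pixel_indices=best_idx,
            volume=self.volume_,
        )
        self.components_ = self.endmembers_.spectra
        return self

    def transform(self, X) -> np.ndarray:
        """NNLS abundances of `X` in the fitted endmember basis, (p, k) or
        (m, n, k)."""
        check_is_fitted(self, "endmembers_")
        amap = nnls_abundances(X, self.endmembers_)
        return amap.values

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)


def nfindr(cube_or_matrix, k: int, seed: int = 0, max_sweeps: int = 20,
           n_restarts: int = 5) -> EndmemberSet:
    """Functional wrapper: extract `k` endmembers from a cube or matrix."""
    est = NFINDR(n_endmembers=k, max_sweeps=max_sweeps, n_restarts=n_restarts,
                 random_state=seed)
    return est.fit(cube_or_matrix).endmembers_


def volume_scree(cube_or_matrix, k_values=(2, 3, 4, 5, 6), seed: int = 0) -> dict:
    """Attained simplex volume per candidate endmember count.

    A diagnostic for choosing k by eye (the choice itself stays with the
    analyst): volumes typically rise steeply while genuine spectral
    components remain and flatten once additional endmembers only chase
    intensity or noise.
    """
    out = {}
    for k in k_values:
        try:
            out[int(k)] = nfindr(cube_or_matrix, int(k), seed=seed).volume
        except ValueError:
            # more endmembers than independent components: degenerate simplex
            out[int(k)] = 0.0
    return out


def nnls_abundances(cube_or_matrix, endmembers: EndmemberSet) -> AbundanceMap:
    """Per-pixel nonnegative least-squares abundances.

    Solves min ||E a - spectrum||^2, a >= 0 for every pixel and records the
    residual norm.
    """
    pixels, spatial = _as_pixel_matrix(cube_or_matrix)
    E = endmembers.spectra.T  # (s, k)
    if E.shape[0] < E.shape[1]:
        raise ValueError("more endmembers than spectral channels")
    sv = np.linalg.svd(E, compute_uv=False)
    if sv[-1] <= 1e-10 * sv[0]:
        raise ValueError("endmember matrix is rank deficient")
    p, k = pixels.shape[0], E.shape[1]
    values = np.empty((p, k))
    resid = np.empty(p)
    for i in range(p):
        values[i], resid[i] = nnls(E, pixels[i])
    if spatial is not None:
        m, n = spatial
        return AbundanceMap(values=values.reshape(m, n, k),
                            residual=resid.reshape(m, n))
    return AbundanceMap(values=values, residual=resid)
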