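"""Two-stage dimension reduction (2SDR) denoising of particle stacks.

Stage 1 keeps each image as a matrix and projects it onto shared
orthonormal row/column bases obtained from the stack's mode-wise scatter
matrices (a HOSVD-style multilinear reduction): image X_i becomes the
p0 x q0 core U^T X_i V.  Stage 2 vectorizes the cores and fits an ordinary
PCA with r components, cleaning a second layer of noise.  Reconstruction
U (mean + components^T c_i) V^T yields the denoised image.

The appeal over plain PCA on vectorized images is cost: the stage-1
eigenproblems are H x H and W x W regardless of n, and the stage-2 PCA
sees only p0*q0-dimensional vectors.  Ranks are fixed (no adaptive
selection); the defaults (25, 25, 50) are the settings used throughout
for cryo-EM particle denoising.  The HOSVD stage is not centered — the
mean is modeled entirely by the PCA stage, which makes the full-rank
configuration an exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .stack_io import ParticleStack

__all__ = ["TwoSDRConfig", "TwoSDRModel", "fit_hosvd", "project_cores", "fit_pca", "denoise"]

DEFAULT_P0 = 25
DEFAULT_Q0 = 25
DEFAULT_R = 50


@dataclass(frozen=True)
class TwoSDRConfig:
    """Ranks of the two stages: (p0, q0) row/column ranks, r PCA components."""

    p0: int = DEFAULT_P0
    q0: int = DEFAULT_Q0
    r: int = DEFAULT_R

    def validate(self, n: int, h: int, w: int) -> None:
        if not (1 <= self.p0 <= h):
            raise ValueError(f"p0 must be in [1, {h}], got {self.p0}")
        if not (1 <= self.q0 <= w):
            raise ValueError(f"q0 must be in [1, {w}], got {self.q0}")
        if not (1 <= self.r <= min(n, self.p0 * self.q0)):
            raise ValueError(
                f"r must be in [1, min(n={n}, p0*q0={self.p0 * self.q0})], got {self.r}"
            )

    def clipped(self, n: int, h: int, w: int) -> "TwoSDRConfig":
        """Shrink ranks to what the stack supports (used by the CLI)."""
        p0 = min(self.p0, h)
        q0 = min(self.q0, w)
        return TwoSDRConfig(p0, q0, min(self.r, n, p0 * q0))


@dataclass
class TwoSDRModel:
    """Fitted bases and scores; reconstructable to a denoised stack."""

    U: np.ndarray              # H x p0, orthonormal columns
    V: np.ndarray              # W x q0, orthonormal columns
    pca_mean: np.ndarray       # p0*q0
    pca_components: np.ndarray  # r x p0*q0, orthonormal rows
    coefficients: np.ndarray   # n x r

    def reconstruct(self) -> np.ndarray:
        """Denoised images, shape (n, H, W)."""
        p0 = self.U.shape[1]
        q0 = self.V.shape[1]
        vecs = self.pca_mean[None, :] + self.coefficients @ self.pca_components
        cores = vecs.reshape(-1, p0, q0)
        return np.einsum("hp,npq,wq->nhw", self.U, cores, self.V, optimize=True)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (deterministic)."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def _top_eigvecs(scatter: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of a symmetric PSD matrix, eigenvalues descending."""
    d = scatter.shape[0]
    vals, vecs = scipy.linalg.eigh(scatter, subset_by_index=[d - k, d - 1])
    return _fix_signs(vecs[:, ::-1])


def fit_hosvd(stack: ParticleStack | np.ndarray, p0: int, q0: int):
    """Shared row/column bases from the stack's mode-wise scatter matrices.

    U holds the top-p0 eigenvectors of sum_i X_i X_i^T and V the top-q0
    eigenvectors of sum_i X_i^T X_i, each with the largest-magnitude entry
    of every column made positive so repeated fits are bit-identical.
    """
    images = stack.images if isinstance(stack, ParticleStack) else np.asarray(stack)
    if images.ndim != 3 or images.shape[0] < 1:
        raise ValueError("need a non-empty (n, H, W) stack")
    n, h, w = images.shape
    if not (1 <= p0 <= h and 1 <= q0 <= w):
        raise ValueError(f"ranks ({p0}, {q0}) exceed image shape ({h}, {w})")
    x = images.astype(np.float64)
    row_scatter = np.einsum("nhw,ngw->hg", x, x, optimize=True)
    col_scatter = np.einsum("nhw,nhv->wv", x, x, optimize=True)
    return _top_eigvecs(row_scatter, p0), _top_eigvecs(col_scatter, q0)


def project_cores(stack: ParticleStack | np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Per-image cores U^T X_i V, shape (n, p0, q0)."""
    images = stack.images if isinstance(stack, ParticleStack) else np.asarray(stack)
    if images.shape[1] != U.shape[0] or images.shape[2] != V.shape[0]:
        raise ValueError("basis shapes do not match image shape")
    return np.einsum("hp,nhw,wq->npq", U, images.astype(np.float64), V, optimize=True)


def fit_pca(cores: np.ndarray, r: int):
    """PCA on vectorized cores: (mean, components, coefficients).

    Components are the top-r eigenvectors of the sample covariance of the
    centered vectorized cores (descending eigenvalue, deterministic signs);
    coefficients are the centered cores projected on them.
    """
    n = cores.shape[0]
    vecs = cores.reshape(n, -1).astype(np.float64)
    d = vecs.shape[1]
    if not (1 <= r <= min(n, d)):
        raise ValueError(f"r must be in [1, min({n}, {d})], got {r}")
    if n == 1:
        raise ValueError("PCA needs at least two images (no variance with n = 1)")
    mean = vecs.mean(axis=0)
    centered = vecs - mean
    # Right singular vectors of the centered matrix == covariance eigenvectors.
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    components = _fix_signs(vt[:r].T).T
    coefficients = centered @ components.T
    return mean, components, coefficients


def denoise(stack: ParticleStack, config: TwoSDRConfig | None = None):
    """Run both stages and reconstruct the denoised stack.

    Returns ``(denoised, model)``; the input stack is left untouched and
    the output keeps its shape, pixel size and particle order.
    """
    if config is None:
        config = TwoSDRConfig()
    n, h, w = stack.images.shape
    config.validate(n, h, w)
    U, V = fit_hosvd(stack, config.p0, config.q0)
    cores = project_cores(stack, U, V)
    mean, components, coefficients = fit_pca(cores, config.r)
    model = TwoSDRModel(U, V, mean, components, coefficients)
    denoised = ParticleStack(
        model.reconstruct().astype(np.float32),
        stack.pixel_size,
        None if stack.meta is None else stack.meta.copy(),
    )
    return denoised, model
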