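"""Perceptual distribution distances over image feature sets.

FID (Fréchet inception distance) fits a Gaussian to each feature set and
reports

    ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2})

KID (kernel inception distance) is the unbiased squared MMD under the
degree-3 polynomial kernel k(x, y) = (x·y/d + 1)^3, averaged over random
subsets.  Both are agnostic to the feature extractor: the canonical choice
is an Inception-v3 pool3 embedding (2048-d), but any extractor producing an
n×d matrix works, and a deterministic random-projection extractor is
provided so the estimators run without pretrained weights.

Also here: the patchwise InfoNCE loss used by contrastive unpaired style
transfer.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "FeatureSet",
    "fid",
    "kid",
    "patch_nce_loss",
    "RandomProjectionExtractor",
    "save_features",
    "load_features",
]


@dataclasses.dataclass
class FeatureSet:
    """n×d matrix of image embeddings plus the id of the extractor that made it."""

    matrix: np.ndarray
    extractor_id: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix must be finite")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


def _check_pair(a: FeatureSet, b: FeatureSet) -> None:
    if a.d != b.d:
        raise ValueError(f"feature dimensionality mismatch: {a.d} vs {b.d}")


def _sqrt_psd(mat: np.ndarray, clamp: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() < -1e-4 * max(vals.max(), 1.0):
        raise np.linalg.LinAlgError(
            f"matrix strongly non-PSD (min eigenvalue {vals.min():.3g}); "
            "covariance estimate is ill-conditioned")
    vals = np.clip(vals, -clamp, None)
    vals = np.maximum(vals, 0.0)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(a: FeatureSet, b: FeatureSet) -> float:
    """Fréchet distance between Gaussian fits of two feature sets.

    Covariances use 1/(n-1) normalization; the cross term
    Tr((S_a S_b)^{1/2}) is evaluated as Tr((A S_b A)^{1/2}) with
    A = S_a^{1/2}, which is symmetric, via eigen-decomposition with small
    negative eigenvalues clamped.
    """
    _check_pair(a, b)
    if a.n < 2 or b.n < 2:
        raise ValueError("FID requires at least 2 samples per set")
    mu_a, mu_b = a.matrix.mean(axis=0), b.matrix.mean(axis=0)
    cov_a = np.cov(a.matrix, rowvar=False, ddof=1)
    cov_b = np.cov(b.matrix, rowvar=False, ddof=1)
    cov_a, cov_b = np.atleast_2d(cov_a), np.atleast_2d(cov_b)
    root_a = _sqrt_psd(cov_a)
    cross = _sqrt_psd(root_a @ cov_b @ root_a)
    val = float(np.sum((mu_a - mu_b) ** 2)
                + np.trace(cov_a) + np.trace(cov_b) - 2.0 * np.trace(cross))
    return max(val, 0.0)


def _poly_kernel(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    return (x @ y.T / d + 1.0) ** 3


def kid(a: FeatureSet, b: FeatureSet, subset_size: int = 100,
        n_subsets: int = 10, rng_seed: int = 0) -> float:
    """Unbiased KID: subset-averaged squared MMD with a cubic polynomial kernel.

    For each subset the unbiased estimator is the mean off-diagonal kernel
    within each set minus twice the mean cross kernel.  Subsets are drawn
    without replacement; deterministic under ``rng_seed``.
    """
    _check_pair(a, b)
    if subset_size < 2:
        raise ValueError("subset_size must be >= 2")
    m = min(a.n, b.n)
    if subset_size > m:
        raise ValueError(f"subset_size {subset_size} exceeds smaller set size {m}")
    rng = np.random.default_rng(rng_seed)
    vals = []
    for _ in range(n_subsets):
        xa = a.matrix[rng.choice(a.n, subset_size, replace=False)]
        xb = b.matrix[rng.choice(b.n, subset_size, replace=False)]
        kaa = _poly_kernel(xa, xa)
        kbb = _poly_kernel(xb, xb)
        kab = _poly_kernel(xa, xb)
        s = subset_size
        term_a = (kaa.sum() - np.trace(kaa)) / (s * (s - 1))
        term_b = (kbb.sum() - np.trace(kbb)) / (s * (s - 1))
        vals.append(term_a + term_b - 2.0 * kab.mean())
    return float(np.mean(vals))


def patch_nce_loss(query: np.ndarray, positive: np.ndarray,
                   negatives: np.ndarray, temperature: float = 0.07) -> float:
    """InfoNCE over one query patch feature vs one positive and N negatives.

    -log[ exp(q·p/τ) / (exp(q·p/τ) + Σ_n exp(q·neg_n/τ)) ], computed with
    log-sum-exp stabilization.
    """
    q = np.asarray(query, dtype=np.float64)
    p = np.asarray(positive, dtype=np.float64)
    neg = np.atleast_2d(np.asarray(negatives, dtype=np.float64))
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if not (np.isfinite(q).all() and np.isfinite(p).all() and np.isfinite(neg).all()):
        raise ValueError("non-finite inputs to patch_nce_loss")
    logits = np.concatenate([[q @ p], neg @ q]) / temperature
    return float(logsumexp(logits) - logits[0])


class RandomProjectionExtractor:
    """Deterministic feature extractor: fixed Gaussian projection + ReLU.

    Images (H, W, 3) in [0, 1] are resized by block averaging to a
    ``patch_hw`` grid, flattened, passed through a fixed random linear map,
    rectified, and projected again.  No pretrained weights involved; the
    two-layer nonlinearity is enough for FID/KID to discriminate lighting
    and palette statistics.
    """

    def __init__(self, out_dim: int = 192, patch_hw: int = 16, seed: int = 0):
        self.out_dim = out_dim
        self.patch_hw = patch_hw
        rng = np.random.default_rng(seed)
        in_dim = patch_hw * patch_hw * 3
        hidden = 2 * out_dim
        self.w1 = rng.normal(0, 1.0 / np.sqrt(in_dim), size=(in_dim, hidden))
        self.w2 = rng.normal(0, 1.0 / np.sqrt(hidden), size=(hidden, out_dim))
        self.extractor_id = f"random-projection-{out_dim}d-seed{seed}"

    def _resize(self, img: np.ndarray) -> np.ndarray:
        h, w = img.shape[:2]
        th = self.patch_hw
        ys = (np.arange(th + 1) * h / th).astype(int)
        xs = (np.arange(th + 1) * w / th).astype(int)
        out = np.empty((th, th, 3))
        for i in range(th):
            for j in range(th):
                out[i, j] = img[ys[i]:max(ys[i + 1], ys[i] + 1),
                                xs[j]:max(xs[j + 1], xs[j] + 1)].mean(axis=(0, 1))
        return out

    def __call__(self, images) -> FeatureSet:
        feats = []
        for img in images:
            x = self._resize(np.asarray(img, dtype=np.float64)).ravel()
            h = np.maximum(x @ self.w1, 0.0)
            feats.append(h @ self.w2)
        return FeatureSet(np.asarray(feats), self.extractor_id)


def save_features(fs: FeatureSet, path: str | Path) -> None:
    """Write features as flat little-endian float32 with a JSON sidecar."""
    path = Path(path)
    fs.matrix.astype("<f4").tofile(path)
    sidecar = {"n": fs.n, "d": fs.d, "extractor_id": fs.extractor_id}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_features(path: str | Path) -> FeatureSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    mat = np.fromfile(path, dtype="<f4").reshape(meta["n"], meta["d"])
    return FeatureSet(mat.astype(np.float64), meta["extractor_id"])
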