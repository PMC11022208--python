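"""Desk-scale contrastive unpaired style-transfer smoke harness.

Full contrastive unpaired translation (CUT-style) training pairs a GAN
objective with a patchwise InfoNCE loss that ties each output patch to the
input patch at the same location.  Training the full model takes tens of
GPU-hours, so this module provides a miniature, dependency-free realization
of the same *contract*: a per-pixel color-transform generator, a logistic
discriminator on image color statistics, and a frozen random-projection
patch encoder feeding :func:`uroscope.metrics.patch_nce_loss`.  It exists
to exercise the loss plumbing end-to-end — the combined objective must
decrease over a few hundred steps on small synthetic image pairs — not to
produce publication-quality style transfer.

The generator has 12 parameters (3x3 channel mix + bias) and is optimized
by central finite differences; the discriminator uses analytic logistic
gradients.  Everything is deterministic under ``rng_seed``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .metrics import patch_nce_loss

__all__ = ["ColorGenerator", "PatchEncoder", "style_smoke_train", "mean_patch_nce"]


@dataclasses.dataclass
class ColorGenerator:
    """Per-pixel affine color transform: out = img @ W.T + b."""

    weight: np.ndarray  # (3, 3)
    bias: np.ndarray    # (3,)

    @classmethod
    def identity(cls) -> "ColorGenerator":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator, scale: float = 0.5) -> "ColorGenerator":
        return cls(np.eye(3) + rng.normal(0, scale, (3, 3)), rng.normal(0, scale, 3))

    def __call__(self, img: np.ndarray) -> np.ndarray:
        return img @ self.weight.T + self.bias

    def params(self) -> np.ndarray:
        return np.concatenate([self.weight.ravel(), self.bias])

    @classmethod
    def from_params(cls, p: np.ndarray) -> "ColorGenerator":
        return cls(p[:9].reshape(3, 3), p[9:12])


class PatchEncoder:
    """Frozen random projection of k×k×3 patches to unit-norm feature vectors."""

    def __init__(self, patch: int = 5, dim: int = 24, seed: int = 0):
        self.patch = patch
        rng = np.random.default_rng(seed)
        self.proj = rng.normal(0, 1.0 / np.sqrt(patch * patch * 3),
                               size=(patch * patch * 3, dim))

    def encode_at(self, img: np.ndarray, centers: np.ndarray) -> np.ndarray:
        half = self.patch // 2
        feats = []
        for cy, cx in centers:
            p = img[cy - half:cy - half + self.patch, cx - half:cx - half + self.patch]
            f = p.ravel() @ self.proj
            feats.append(f / max(np.linalg.norm(f), 1e-12))
        return np.asarray(feats)

    def sample_centers(self, shape, n: int, rng: np.random.Generator) -> np.ndarray:
        half = self.patch // 2
        ys = rng.integers(half, shape[0] - half, size=n)
        xs = rng.integers(half, shape[1] - half, size=n)
        return np.stack([ys, xs], axis=1)


def mean_patch_nce(gen: ColorGenerator, images, encoder: PatchEncoder,
                   n_locations: int = 8, temperature: float = 0.07,
                   rng_seed: int = 0) -> float:
    """Mean patchwise InfoNCE between inputs and their generated outputs.

    For each image, ``n_locations`` patch centres are drawn; the query is
    the output-patch feature, the positive is the input-patch feature at
    the same location, and the other locations' input patches serve as
    negatives.
    """
    rng = np.random.default_rng(rng_seed)
    losses = []
    for img in images:
        out = gen(np.asarray(img, dtype=np.float64))
        centers = encoder.sample_centers(img.shape, n_locations, rng)
        f_in = encoder.encode_at(np.asarray(img, dtype=np.float64), centers)
        f_out = encoder.encode_at(out, centers)
        for i in range(n_locations):
            negs = np.delete(f_in, i, axis=0)
            losses.append(patch_nce_loss(f_out[i], f_in[i], negs, temperature))
    return float(np.mean(losses))


def _disc_features(img: np.ndarray) -> np.ndarray:
    return np.concatenate([img.mean(axis=(0, 1)), img.std(axis=(0, 1))])


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def style_smoke_train(rendered, styled, steps: int = 200, rng_seed: int = 0,
                      lr_gen: float = 0.08, lr_disc: float = 0.03,
                      lambda_nce: float = 1.0, temperature: float = 0.07,
                      batch: int = 4) -> dict:
    """Train the miniature generator against a style domain; return loss traces.

    Returns a dict of per-step arrays ``total``/``nce``/``adv``/``disc`` and
    the trained generator.  ``steps=0`` returns empty traces and leaves
    nothing mutated.  Image sets must be non-empty, small (≤ 64×64) and
    steps ≤ 500 (this is a smoke harness, not a trainer).

    The default learning rates keep the generator ahead of the
    discriminator; a fast discriminator inflates the adversarial term
    faster than the generator can reduce it and the combined loss drifts
    upward even while translation quality improves.
    """
    rendered = [np.asarray(im, dtype=np.float64) for im in rendered]
    styled = [np.asarray(im, dtype=np.float64) for im in styled]
    if not rendered or not styled:
        raise ValueError("rendered and styled image sets must be non-empty")
    if any(max(im.shape[:2]) > 64 for im in rendered + styled):
        raise ValueError("smoke harness accepts images up to 64x64 only")
    if steps > 500:
        raise ValueError("smoke harness caps steps at 500")
    trace = {k: [] for k in ("total", "nce", "adv", "disc")}
    rng = np.random.default_rng(rng_seed)
    gen = ColorGenerator.random(rng, scale=0.35)
    encoder = PatchEncoder(seed=rng_seed)
    dw = np.zeros(6)
    db = 0.0

    def gen_loss(params: np.ndarray, imgs, seed: int) -> tuple[float, float, float]:
        g = ColorGenerator.from_params(params)
        nce = mean_patch_nce(g, imgs, encoder, temperature=temperature, rng_seed=seed)
        adv = 0.0
        for im in imgs:
            d = _sigmoid(_disc_features(g(im)) @ dw + db)
            adv += -np.log(max(d, 1e-12))
        adv /= len(imgs)
        return lambda_nce * nce + adv, nce, adv

    for step in range(int(steps)):
        idx = rng.choice(len(rendered), size=min(batch, len(rendered)), replace=False)
        imgs = [rendered[i] for i in idx]
        sty = [styled[i] for i in rng.choice(len(styled), size=min(batch, len(styled)),
                                             replace=False)]
        # --- discriminator: analytic logistic-regression step
        gd_w = np.zeros(6)
        gd_b = 0.0
        dloss = 0.0
        for im in sty:
            f = _disc_features(im)
            p = _sigmoid(f @ dw + db)
            dloss += -np.log(max(p, 1e-12))
            gd_w += (p - 1.0) * f
            gd_b += (p - 1.0)
        for im in imgs:
            f = _disc_features(gen(im))
            p = _sigmoid(f @ dw + db)
            dloss += -np.log(max(1.0 - p, 1e-12))
            gd_w += p * f
            gd_b += p
        m = len(sty) + len(imgs)
        dw -= lr_disc * gd_w / m
        db -= lr_disc * gd_b / m
        # --- generator: central finite differences on 12 parameters
        seed = int(rng.integers(2**31))
        p0 = gen.params()
        loss0, nce0, adv0 = gen_loss(p0, imgs, seed)
        grad = np.zeros_like(p0)
        eps = 1e-4
        for k in range(len(p0)):
            pp, pm = p0.copy(), p0.copy()
            pp[k] += eps
            pm[k] -= eps
            grad[k] = (gen_loss(pp, imgs, seed)[0] - gen_loss(pm, imgs, seed)[0]) / (2 * eps)
        gen = ColorGenerator.from_params(p0 - lr_gen * grad)
        trace["total"].append(loss0)
        trace["nce"].append(nce0)
        trace["adv"].append(adv0)
        trace["disc"].append(dloss / m)
    return {k: np.asarray(v) for k, v in trace.items()} | {"generator": gen,
                                                           "encoder": encoder}
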