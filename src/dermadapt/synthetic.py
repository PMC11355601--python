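"""Synthetic two-domain, two-class lesion-image corpora.

The generator renders ellipse-like "lesions" on a skin-toned background.
Class 0 is a diffuse ellipse with a smooth border; class 1 is an irregular,
multi-lobed shape with a sharper border — i.e. the discriminative signal is
*shape* (asymmetry / border irregularity, echoing the clinical ABCD
intuition), never colour.  The target domain applies a controllable
covariate shift (brightness, hue rotation, blur, noise) on top of the same
class-conditional geometry, so colour and intensity are genuine nuisance
variables: a shift can hide the classes from a source-trained model but
cannot change them.

Everything is reproducible bit-for-bit from (n, image_size, seed, shift).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .nn.layers import seed_rng

__all__ = ["ShiftSpec", "SHIFT_PRESETS", "SyntheticCorpus", "make_corpus",
           "write_corpus"]


@dataclass(frozen=True)
class ShiftSpec:
    """Parameters of the source→target covariate shift.

    brightness_delta : additive intensity offset in [-0.5, 0.5]
    hue_rotation     : rotation of RGB values around the grey axis, degrees
    blur_sigma       : Gaussian blur radius in pixels, >= 0
    noise_sd         : additive Gaussian pixel noise std, >= 0

    The all-zero spec leaves the target distribution identical to the source.
    """

    brightness_delta: float = 0.0
    hue_rotation: float = 0.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if not -0.5 <= self.brightness_delta <= 0.5:
            raise ValueError("brightness_delta must lie in [-0.5, 0.5]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def is_null(self) -> bool:
        return (self.brightness_delta == 0 and self.hue_rotation == 0
                and self.blur_sigma == 0 and self.noise_sd == 0)


SHIFT_PRESETS = {
    "none": ShiftSpec(),
    "mild": ShiftSpec(brightness_delta=0.15, blur_sigma=0.75),
    "strong": ShiftSpec(brightness_delta=0.3, blur_sigma=1.5),
}


@dataclass
class SyntheticCorpus:
    """Images (n, 3, s, s) in [0, 1] with class and domain labels."""

    images: np.ndarray
    class_labels: np.ndarray
    domain_labels: np.ndarray
    seed: int
    shift: ShiftSpec

    def domain(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        """(images, class_labels) of one domain (0 = source, 1 = target)."""
        mask = self.domain_labels == d
        return self.images[mask], self.class_labels[mask]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_lesion(size: int, cls: int, rng: np.random.Generator) -> np.ndarray:
    """One RGB image; geometry differs by class, colours are shared.

    The palette is deliberately dark (max ~0.65) so that the strongest
    brightness shift (+0.3) stays in gamut, and the class signal lives in
    *low-frequency* border geometry (lobedness/asymmetry) so it survives the
    strongest blur — the shift transforms are nuisance covariates by
    construction, they cannot create or destroy the label structure.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32) / size - 0.5

    # muted skin-toned background with low-frequency mottling
    base = np.array([0.60, 0.46, 0.40], np.float32)
    tex = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), size / 12.0)
    tex = (tex / (np.abs(tex).max() + 1e-6) * 0.03).astype(np.float32)
    img = base[:, None, None] + tex[None] * np.array([1.0, 0.9, 0.8],
                                                     np.float32)[:, None, None]

    # lesion placement: both classes draw from the same scale/offset/colour
    # distributions, so only the border geometry separates them
    cx, cy = rng.uniform(-0.06, 0.06, 2)
    r0 = rng.uniform(0.22, 0.30)
    shade = rng.uniform(0.4, 0.75)
    colour = np.array([0.30, 0.20, 0.16], np.float32) * shade

    dx, dy = xx - cx, yy - cy
    theta = np.arctan2(dy, dx)
    rr = np.sqrt(dx * dx + dy * dy)
    edge = r0 * 0.15  # same border softness for both classes

    if cls == 0:
        # smooth ellipse with mild eccentricity
        ecc = rng.uniform(0.8, 1.0)
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        rx, ry = dx * ca + dy * sa, -dx * sa + dy * ca
        dist = np.sqrt(rx ** 2 + (ry / ecc) ** 2)
        alpha = 1.0 / (1.0 + np.exp((dist - r0) / edge * 6.0))
    else:
        # irregular multi-lobed boundary: low-frequency radius modulation
        radius = np.full_like(theta, r0)
        for k in range(2, 6):
            amp = rng.uniform(0.25, 0.45)
            phase = rng.uniform(0, 2 * np.pi)
            radius = radius * (1.0 + amp * np.sin(k * theta + phase) / 2)
        alpha = 1.0 / (1.0 + np.exp((rr - radius) / edge * 6.0))

    # pigment speckle inside the lesion
    speck = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), 1.0)
    speck = (speck * 0.05).astype(np.float32)
    lesion = colour[:, None, None] * (1.0 + speck[None])

    alpha = alpha.astype(np.float32)[None]
    out = img * (1.0 - alpha) + lesion * alpha
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _hue_rotation_matrix(degrees: float) -> np.ndarray:
    """Linear RGB rotation about the grey axis (1,1,1)/sqrt(3)."""
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    one3 = 1.0 / 3.0
    sq3 = np.sqrt(1.0 / 3.0)
    m = np.full((3, 3), one3 * (1.0 - c)) + np.eye(3) * c
    off = np.array([[0, -1, 1], [1, 0, -1], [-1, 1, 0]], np.float64) * sq3 * s
    return (m + off).astype(np.float32)


def apply_shift(images: np.ndarray, shift: ShiftSpec,
                rng: np.random.Generator) -> np.ndarray:
    """Apply the covariate shift to a (n, 3, s, s) stack."""
    out = images.astype(np.float32).copy()
    if shift.hue_rotation:
        m = _hue_rotation_matrix(shift.hue_rotation)
        out = np.einsum("ij,njhw->nihw", m, out)
    if shift.brightness_delta:
        out = out + np.float32(shift.brightness_delta)
    if shift.blur_sigma > 0:
        out = ndimage.gaussian_filter(
            out, sigma=(0, 0, shift.blur_sigma, shift.blur_sigma))
    if shift.noise_sd > 0:
        out = out + rng.normal(0, shift.noise_sd, out.shape).astype(np.float32)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def make_corpus(n_per_class_per_domain: int, image_size: int = 64,
                shift: ShiftSpec = SHIFT_PRESETS["strong"],
                seed: int = 0) -> SyntheticCorpus:
    """Balanced two-domain, two-class corpus with the given shift.

    Both domains draw their lesions from the same class-conditional geometry
    distributions (independent streams); the shift transforms are then
    applied to the target domain only.
    """
    if n_per_class_per_domain < 1:
        raise ValueError("n_per_class_per_domain must be >= 1")
    if image_size < 32:
        raise ValueError("image_size must be >= 32")

    n = n_per_class_per_domain
    images, classes, domains = [], [], []
    for d in (0, 1):
        for cls in (0, 1):
            for i in range(n):
                rng = seed_rng(seed, 7000 + d, cls, i)
                images.append(_render_lesion(image_size, cls, rng))
                classes.append(cls)
                domains.append(d)
    images = np.stack(images)
    classes = np.asarray(classes, dtype=np.int64)
    domains = np.asarray(domains, dtype=np.int64)

    tgt = domains == 1
    images[tgt] = apply_shift(images[tgt], shift, seed_rng(seed, 7100))
    return SyntheticCorpus(images=images, class_labels=classes,
                           domain_labels=domains, seed=seed, shift=shift)


# ---------------------------------------------------------------------------
# on-disk form: 8-bit PNG + labels CSV + JSON manifest
# ---------------------------------------------------------------------------

def write_corpus(corpus: SyntheticCorpus, directory) -> Path:
    """Write PNGs, ``labels.csv`` (path,class,domain) and ``manifest.json``.

    Returns the manifest path.  Round-trips through the dataset reader to
    within 8-bit quantisation (1/255 per channel).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = ["path,class,domain"]
    for i in range(corpus.images.shape[0]):
        d, c = int(corpus.domain_labels[i]), int(corpus.class_labels[i])
        name = f"d{d}_c{c}_{i:05d}.png"
        arr = np.round(corpus.images[i].transpose(1, 2, 0) * 255.0)
        Image.fromarray(arr.astype(np.uint8), mode="RGB").save(directory / name)
        rows.append(f"{name},{c},{d}")
    (directory / "labels.csv").write_text("\n".join(rows) + "\n")
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({
        "seed": corpus.seed,
        "shift": asdict(corpus.shift),
        "n_images": int(corpus.images.shape[0]),
        "image_size": int(corpus.images.shape[-1]),
        "labels_csv": "labels.csv",
    }, indent=2))
    return manifest
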