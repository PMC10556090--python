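"""Image-noise survival simulation: translating a C-index into missing information.

The simulation treats a 28x28 grey-scale digit image as one "patient" whose
full information content is known.  The image stack is reduced to its first
two principal components, a true survival time is assigned by the
deterministic map ``T(x) = MST * exp(S * (PC1 + PC2))``, and information is
then progressively destroyed by replacing a fraction ``p`` of the pixels
with uniform noise.  Refitting the PCA and a two-covariate Cox model on the
noised images and scoring Harrell's C against the true times yields a curve
from C = 1 (no noise) down to C = 0.5 (pure noise), so the noise fraction is
directly interpretable as the fraction of missing information: an observed
C-index can be mapped to how much of the initial information
(``100% - noise%``) a prognostic model is working with.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import cox_newton
from .concordance import concordance

__all__ = [
    "ImageSample",
    "SimulationConfig",
    "NoiseCurve",
    "IdxFormatError",
    "read_idx_images",
    "write_idx_images",
    "generate_synthetic_digits",
    "add_noise",
    "reduce_pca2",
    "simulate_survival",
    "normalized_entropy",
    "cindex_vs_noise",
    "cindex_vs_entropy",
]

IDX_MAGIC = 0x00000803
IMG_SIDE = 28
N_PIXELS = IMG_SIDE * IMG_SIDE
N_LEVELS = 256


class IdxFormatError(ValueError):
    """Malformed IDX image file."""


@dataclass
class ImageSample:
    """A stack of 28x28 integer-intensity images."""

    images: np.ndarray  # (n, 28, 28) uint8
    source: str = "synthetic"  # idx_file | synthetic

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3 or self.images.shape[1:] != (IMG_SIDE, IMG_SIDE):
            raise ValueError(f"images must be (n, {IMG_SIDE}, {IMG_SIDE})")
        if self.images.shape[0] < 2:
            raise ValueError("need at least 2 images")
        if self.images.min() < 0 or self.images.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.images = self.images.astype(np.uint8)

    @property
    def n(self) -> int:
        return self.images.shape[0]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the noise-vs-concordance simulation.

    ``mst`` is the median survival time in years at PC1 + PC2 = 0 and
    ``skew`` the coefficient controlling how right-skewed the simulated
    survival distribution is; the defaults (10 years, 0.6) emulate typical
    breast-cancer survival distributions.
    """

    n_images: int = 2000
    mst: float = 10.0
    skew: float = 0.6
    noise_levels: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    reps: int = 100
    seed: int = 0
    ridge: float = 1e-3
    entropy_subsample: int = 256

    def __post_init__(self) -> None:
        levels = tuple(float(p) for p in self.noise_levels)
        if any(not 0.0 <= p <= 1.0 for p in levels):
            raise ValueError("noise levels must lie in [0, 1]")
        if list(levels) != sorted(levels):
            raise ValueError("noise levels must be sorted ascending")
        object.__setattr__(self, "noise_levels", levels)


@dataclass
class NoiseCurve:
    """Per-noise-level aggregates of the simulated concordance."""

    noise_levels: np.ndarray
    median_c: np.ndarray
    se_median: np.ndarray
    mean_entropy: np.ndarray
    rep_c: np.ndarray = field(repr=False, default=None)  # (reps, levels)

    @property
    def missing_information(self) -> np.ndarray:
        """Missing information in percent: noise * 100."""
        return self.noise_levels * 100.0

    @property
    def initial_information(self) -> np.ndarray:
        """Initial information in percent: 100 - noise%."""
        return 100.0 - self.missing_information

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "noise": self.noise_levels,
                "missing_information_pct": self.missing_information,
                "median_c": self.median_c,
                "se_median": self.se_median,
                "mean_entropy": self.mean_entropy,
            }
        )


# ---------------------------------------------------------------------------
# IDX container (the standard layout of the classic digit-image corpora)
# ---------------------------------------------------------------------------


def read_idx_images(path) -> ImageSample:
    """Read a stack of 28x28 images from an IDX file (big-endian header)."""
    data = open(path, "rb").read()
    if len(data) < 16:
        raise IdxFormatError("file too short for an IDX image header")
    magic, n, rows, cols = struct.unpack(">IIII", data[:16])
    if magic != IDX_MAGIC:
        raise IdxFormatError(f"bad magic number 0x{magic:08x}, expected 0x{IDX_MAGIC:08x}")
    if (rows, cols) != (IMG_SIDE, IMG_SIDE):
        raise IdxFormatError(f"expected {IMG_SIDE}x{IMG_SIDE} images, got {rows}x{cols}")
    expected = 16 + n * rows * cols
    if len(data) < expected:
        raise IdxFormatError(f"truncated file: {len(data)} bytes, expected {expected}")
    images = np.frombuffer(data[16:expected], dtype=np.uint8).reshape(n, rows, cols)
    return ImageSample(images=images, source="idx_file")


def write_idx_images(sample: ImageSample, path) -> None:
    """Write a stack back to the IDX layout (round-trip counterpart)."""
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", IDX_MAGIC, sample.n, IMG_SIDE, IMG_SIDE))
        fh.write(sample.images.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# synthetic digits (download-free image source with digit-like structure)
# ---------------------------------------------------------------------------

# Stroke skeletons on a unit square (x right, y down); polylines and ellipse
# arcs (cx, cy, rx, ry, a0, a1 in turns).  Deliberately crude: what matters is
# MNIST-like ink statistics (dark background, bright strokes) and a
# low-dimensional latent parameterization.
_ARCS = "arc"
_DIGIT_STROKES = {
    0: [("arc", 0.5, 0.5, 0.30, 0.42, 0.0, 1.0)],
    1: [("line", (0.35, 0.25), (0.55, 0.10), (0.55, 0.90))],
    2: [("arc", 0.5, 0.30, 0.28, 0.22, 0.5, 1.25),
        ("line", (0.72, 0.40), (0.25, 0.90), (0.78, 0.90))],
    3: [("arc", 0.45, 0.30, 0.25, 0.20, 0.55, 1.30),
        ("arc", 0.45, 0.70, 0.28, 0.22, 0.70, 1.45)],
    4: [("line", (0.65, 0.90), (0.65, 0.10), (0.25, 0.65), (0.80, 0.65))],
    5: [("line", (0.75, 0.12), (0.30, 0.12), (0.28, 0.48)),
        ("arc", 0.48, 0.68, 0.26, 0.24, 0.65, 1.40)],
    6: [("line", (0.62, 0.10), (0.35, 0.45)),
        ("arc", 0.50, 0.68, 0.24, 0.23, 0.0, 1.0)],
    7: [("line", (0.25, 0.12), (0.75, 0.12), (0.42, 0.90))],
    8: [("arc", 0.5, 0.30, 0.22, 0.19, 0.0, 1.0),
        ("arc", 0.5, 0.71, 0.26, 0.22, 0.0, 1.0)],
    9: [("arc", 0.52, 0.32, 0.23, 0.21, 0.0, 1.0),
        ("line", (0.74, 0.35), (0.62, 0.90))],
}

_YY, _XX = np.mgrid[0:IMG_SIDE, 0:IMG_SIDE]


def _stroke_points(stroke, rng, jitter: float):
    if stroke[0] == "arc":
        _, cx, cy, rx, ry, a0, a1 = stroke
        t = np.linspace(a0, a1, 40) * 2 * np.pi
        pts = np.stack([cx + rx * np.cos(t), cy + ry * np.sin(t)], axis=1)
    else:
        ctrl = np.asarray(stroke[1:], dtype=float)
        ctrl = ctrl + rng.normal(0, jitter, ctrl.shape)
        segs = []
        for a, b in zip(ctrl[:-1], ctrl[1:]):
            segs.append(np.linspace(a, b, 20))
        pts = np.concatenate(segs)
    return pts


def generate_synthetic_digits(n: int, seed: int = 0) -> ImageSample:
    """Render ``n`` digit-like 28x28 images from a small stroke family.

    Each image draws a digit class 0-9, applies a random rotation, scale,
    shift, pen width and ink intensity, and rasterizes the strokes with a
    Gaussian pen on a dark background.  The low-dimensional latent
    parameterization (class + affine pose) guarantees non-degenerate leading
    principal components.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    images = np.zeros((n, IMG_SIDE, IMG_SIDE), dtype=np.uint8)
    for i in range(n):
        digit = int(rng.integers(10))
        angle = rng.normal(0.0, 0.15)  # radians
        scale = rng.uniform(0.75, 1.05)
        shift = rng.normal(0.0, 1.3, size=2)
        sigma = rng.uniform(0.7, 1.15)  # pen width in pixels
        ink = rng.uniform(180, 255)
        ca, sa = np.cos(angle), np.sin(angle)
        canvas = np.zeros((IMG_SIDE, IMG_SIDE))
        for stroke in _DIGIT_STROKES[digit]:
            pts = _stroke_points(stroke, rng, jitter=0.02)
            # unit square -> pixel coordinates with pose
            xy = (pts - 0.5) * scale
            xr = xy[:, 0] * ca - xy[:, 1] * sa
            yr = xy[:, 0] * sa + xy[:, 1] * ca
            px = (xr + 0.5) * (IMG_SIDE - 1) + shift[0]
            py = (yr + 0.5) * (IMG_SIDE - 1) + shift[1]
            d2 = (_XX[None] - px[:, None, None]) ** 2 + (_YY[None] - py[:, None, None]) ** 2
            canvas = np.maximum(canvas, np.exp(-d2 / (2 * sigma**2)).max(axis=0))
        images[i] = np.clip(canvas * ink, 0, 255).astype(np.uint8)
    return ImageSample(images=images, source="synthetic")


# ---------------------------------------------------------------------------
# noise, reduction, survival, entropy
# ---------------------------------------------------------------------------


def add_noise(sample: ImageSample, noise_fraction: float, seed: int = 0) -> ImageSample:
    """Replace each pixel independently with uniform noise with probability p.

    ``p = 0`` is the identity; ``p = 1`` replaces every pixel, making the
    output independent of the input (hence exactly information-free).
    """
    p = float(noise_fraction)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"noise fraction must lie in [0, 1], got {p}")
    if p == 0.0:
        return ImageSample(images=sample.images.copy(), source=sample.source)
    rng = np.random.default_rng(seed)
    mask = rng.random(sample.images.shape) < p
    noise = rng.integers(0, N_LEVELS, size=sample.images.shape, dtype=np.int64)
    out = np.where(mask, noise, sample.images.astype(np.int64))
    return ImageSample(images=out.astype(np.uint8), source=sample.source)


def reduce_pca2(sample: ImageSample) -> np.ndarray:
    """First two principal-component scores of the flattened images.

    The stack is mean-centered, the components come from the pixel
    covariance, and the returned scores are standardized to unit variance
    (so the survival skew coefficient acts on a fixed scale).  Refit on every
    (noised) stack it is given.
    """
    X = sample.images.reshape(sample.n, N_PIXELS).astype(float)
    X = X - X.mean(axis=0)
    cov = (X.T @ X) / max(sample.n - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    comps = vecs[:, ::-1][:, :2]  # leading two eigenvectors
    scores = X @ comps
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    return scores / sd


def simulate_survival(pcs: np.ndarray, mst: float = 10.0, skew: float = 0.6) -> np.ndarray:
    """Deterministic survival times ``T = MST * exp(S * (PC1 + PC2))``.

    No censoring; all times are positive by construction.
    """
    pcs = np.asarray(pcs, dtype=float)
    return mst * np.exp(skew * (pcs[:, 0] + pcs[:, 1]))


def normalized_entropy(image: np.ndarray) -> float:
    """Shannon entropy of the 256-level intensity histogram, scaled to [0, 1].

    ``p_k`` is the fraction of the 784 pixels at intensity ``k``; zero-count
    levels contribute nothing; the normalizer is ``ln(256)``.
    """
    img = np.asarray(image)
    counts = np.bincount(img.ravel().astype(np.int64), minlength=N_LEVELS)
    p = counts / counts.sum()
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return float(h / np.log(N_LEVELS))


def _stack_entropy(images: np.ndarray) -> float:
    """Mean per-image normalized entropy of a stack (vectorized)."""
    n = images.shape[0]
    flat = images.reshape(n, -1).astype(np.int64)
    offsets = np.arange(n)[:, None] * N_LEVELS
    counts = np.bincount((flat + offsets).ravel(), minlength=n * N_LEVELS)
    p = counts.reshape(n, N_LEVELS) / flat.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float((-terms.sum(axis=1) / np.log(N_LEVELS)).mean())


def cindex_vs_noise(sample: ImageSample, cfg: SimulationConfig) -> NoiseCurve:
    """The median-concordance-versus-noise curve of the image simulation.

    Per repetition: draw ``cfg.n_images`` images from the supplied pool,
    define the true times from the noise-free principal components, then for
    each noise level replace pixels, refit the PCA, fit a ridge-stabilized
    two-covariate Cox model against the true times (all uncensored) and score
    Harrell's C in-sample.  Aggregates the median and the standard error of
    the median over repetitions, plus the mean normalized entropy of the
    noised images (on a fixed-size subsample, averaged over repetitions).
    """
    levels = np.asarray(cfg.noise_levels)
    rep_c = np.full((cfg.reps, len(levels)), np.nan)
    rep_h = np.full((cfg.reps, len(levels)), np.nan)
    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = ss.generate_state(2 * cfg.reps * max(len(levels), 1) + cfg.reps) % (2**31)
    pool = sample.images
    k = 0
    for r in range(cfg.reps):
        rng = np.random.default_rng(rep_seeds[k]); k += 1
        idx = rng.choice(pool.shape[0], size=cfg.n_images, replace=pool.shape[0] < cfg.n_images)
        base = ImageSample(images=pool[idx], source=sample.source)
        clean_pcs = reduce_pca2(base)
        time = simulate_survival(clean_pcs, cfg.mst, cfg.skew)
        event = np.ones(cfg.n_images, dtype=int)
        for li, p in enumerate(levels):
            noised = add_noise(base, p, seed=int(rep_seeds[k])); k += 1
            pcs = reduce_pca2(noised)
            fit = cox_newton(pcs, time, event, ridge=cfg.ridge)
            score = pcs @ fit.beta
            if np.ptp(score) == 0:  # fully penalized / degenerate fit
                rep_c[r, li] = 0.5
            else:
                rep_c[r, li] = concordance(score, time, event)
            m = min(cfg.entropy_subsample, cfg.n_images)
            rep_h[r, li] = _stack_entropy(noised.images[:m])
    median_c = np.median(rep_c, axis=0)
    # SE of the median via the normal approximation 1.2533 * sd / sqrt(reps)
    se = 1.2533 * rep_c.std(axis=0, ddof=1) / np.sqrt(cfg.reps) if cfg.reps > 1 else np.zeros(len(levels))
    return NoiseCurve(
        noise_levels=levels.astype(float),
        median_c=median_c,
        se_median=se,
        mean_entropy=rep_h.mean(axis=0),
        rep_c=rep_c,
    )


def cindex_vs_entropy(curve: NoiseCurve) -> pd.DataFrame:
    """Pair the per-level mean entropy with the per-level median concordance."""
    return pd.DataFrame(
        {
            "noise": curve.noise_levels,
            "mean_entropy": curve.mean_entropy,
            "median_c": curve.median_c,
        }
    )
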