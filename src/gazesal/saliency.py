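"""Graph-based bottom-up visual saliency (GBVS-style).

The model builds, per feature channel and scale, a fully connected Markov
chain over a coarse lattice of image locations and treats equilibrium
distributions as maps:

1. **Activation.** Edge weight between lattice nodes ``(i, j)`` and
   ``(p, q)``: ``|log(M(i,j) / M(p,q))| * exp(-d^2 / (2 sigma^2))`` —
   dissimilarity in feature value times a Gaussian falloff in lattice
   distance.  The chain's stationary distribution concentrates mass on
   nodes that differ from their surround.
2. **Conspicuity normalization.** A second chain with weights
   ``A(p, q) * exp(-d^2 / (2 sigma^2))`` attracts mass toward already
   active nodes, sharpening a few conspicuous peaks and making maps from
   different channels comparable before summation.

Feature channels are the classic early-vision triad — intensity, two color
opponencies (red-green, blue-yellow) and four orientation energies from
quadrature Gabor pairs — each at ``n_scales`` dyadic scales.

Orientation convention: ``orientation_0`` responds to *horizontal*
structure (energy of horizontally oriented edges/gratings), angles grow
counterclockwise, so ``orientation_90`` responds to vertical structure.

Degenerate inputs: a constant feature map has all log-ratio weights zero;
the activation is then defined as the uniform distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel
from skimage.transform import resize

CHANNELS = ("intensity", "color_opponent_rg", "color_opponent_by",
            "orientation_0", "orientation_45", "orientation_90", "orientation_135")


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested tolerance."""


@dataclass
class SaliencyMap:
    """Nonnegative 2-D saliency map; ``unit_sum`` maps sum to one."""

    values: np.ndarray
    normalization: str = "unit_sum"

    def z_scored(self) -> np.ndarray:
        v = self.values
        sd = v.std()
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    def resampled(self, shape: tuple[int, int]) -> "SaliencyMap":
        v = resize(self.values, shape, order=1, anti_aliasing=False)
        v = np.clip(v, 0.0, None)
        s = v.sum()
        return SaliencyMap(v / s if s > 0 else v, self.normalization)


@dataclass
class FeatureMap:
    channel: str
    scale: int
    values: np.ndarray


@dataclass
class GBVSConfig:
    """Free parameters of the graph-based saliency model.

    The lattice preserves the 16:9 aspect of the presentation screen by
    default.  ``sigma_dist_frac`` scales the Gaussian distance falloff as a
    fraction of the lattice diagonal.  All channels are weighted equally by
    default; exact numerical parity with any particular reference
    implementation is not a goal — the construction is.
    """

    lattice_w: int = 32
    lattice_h: int = 18
    sigma_dist_frac: float = 0.15
    channel_weights: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CHANNELS})
    n_scales: int = 2
    epsilon_floor: float = 1e-6
    power_iter_tol: float = 1e-9
    power_iter_max: int = 10_000
    final_blur_frac: float = 0.02  # sigma as a fraction of image width
    gabor_frequency: float = 0.2  # cycles/pixel at working resolution

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.channel_weights.values()):
            raise ValueError("channel weights must be nonnegative")
        if self.power_iter_tol <= 0:
            raise ValueError("power_iter_tol must be positive")

    @property
    def sigma_dist(self) -> float:
        return self.sigma_dist_frac * math.hypot(self.lattice_w, self.lattice_h)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def _as_float_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected a 3-channel color image (H, W, 3)")
    img = img.astype(float)
    if img.max() > 1.5:  # 8-bit input
        img = img / 255.0
    return img


_GABOR_CACHE: dict[tuple, list[np.ndarray]] = {}


def _gabor_bank(frequency: float) -> list[np.ndarray]:
    """Quadrature Gabor kernels for the four orientation channels.

    ``skimage.filters.gabor_kernel(theta=t)`` varies along the direction
    rotated by ``t`` from the x-axis: ``theta = pi/2`` responds to
    *horizontal* structure (variation along y).  The bank is ordered to
    match :data:`CHANNELS`: orientation_0 = horizontal structure.
    """
    key = (round(frequency, 6),)
    if key not in _GABOR_CACHE:
        thetas = [math.pi / 2, 3 * math.pi / 4, 0.0, math.pi / 4]  # 0,45,90,135 deg
        _GABOR_CACHE[key] = [gabor_kernel(frequency, theta=t) for t in thetas]
    return _GABOR_CACHE[key]


def extract_feature_maps(image: np.ndarray, config: GBVSConfig) -> list[FeatureMap]:
    """Intensity, color-opponency and orientation-energy maps at each scale,
    downsampled to the lattice and epsilon-floored."""
    img = _as_float_image(image)
    h, w = img.shape[:2]
    if h < config.lattice_h or w < config.lattice_w:
        raise ValueError(
            f"image {w}x{h} smaller than the {config.lattice_w}x{config.lattice_h} lattice")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    intensity = img.mean(axis=2)
    rg = np.abs(r - g)
    by = np.abs(b - (r + g) / 2.0)
    lat = (config.lattice_h, config.lattice_w)
    out: list[FeatureMap] = []
    for scale in range(config.n_scales):
        # working resolution: dyadic multiples of the lattice, finest first
        factor = 2 ** (config.n_scales - scale + 1)
        work = (min(h, config.lattice_h * factor), min(w, config.lattice_w * factor))
        ints = resize(intensity, work, order=1, anti_aliasing=True)
        for channel, values in (("intensity", ints),
                                ("color_opponent_rg", resize(rg, work, order=1, anti_aliasing=True)),
                                ("color_opponent_by", resize(by, work, order=1, anti_aliasing=True))):
            m = resize(values, lat, order=1, anti_aliasing=False)
            out.append(FeatureMap(channel, scale, np.maximum(m, config.epsilon_floor)))
        for name, kernel in zip(CHANNELS[3:], _gabor_bank(config.gabor_frequency)):
            k_re = np.real(kernel)
            k_re = k_re - k_re.mean()  # zero DC: flat patches give no energy
            re = ndimage.convolve(ints, k_re, mode="nearest")
            im = ndimage.convolve(ints, np.imag(kernel), mode="nearest")
            energy = np.hypot(re, im)
            m = resize(energy, lat, order=1, anti_aliasing=False)
            out.append(FeatureMap(name, scale, np.maximum(m, config.epsilon_floor)))
    return out


# ---------------------------------------------------------------------------
# Markov machinery
# ---------------------------------------------------------------------------


def markov_equilibrium(weight_matrix: np.ndarray, tol: float = 1e-9,
                       max_iter: int = 10_000) -> np.ndarray:
    """Stationary distribution of the row-normalized chain, by power iteration.

    Iterates the lazy chain ``(P + I) / 2``, which shares P's stationary
    distribution but is aperiodic — dissimilarity-weighted chains over
    two-level images are near-bipartite and make plain power iteration
    oscillate.  Raises on zero rows (no outgoing mass) and on
    non-convergence (L1 change between sweeps still above ``tol`` after
    ``max_iter``).
    """
    W = np.asarray(weight_matrix, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(W < 0):
        raise ValueError("weight matrix must be nonnegative")
    rows = W.sum(axis=1)
    if np.any(rows <= 0):
        raise ValueError(f"{int((rows <= 0).sum())} zero row(s) in weight matrix")
    P = W / rows[:, None]
    n = P.shape[0]
    v = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = 0.5 * (v + v @ P)
        nxt /= nxt.sum()
        delta = np.abs(nxt - v).sum()
        v = nxt
        if delta < tol:
            return v
    raise ConvergenceError(
        f"power iteration did not converge: residual {delta:.3e} > tol {tol:.3e}")


def _lattice_distance_kernel(h: int, w: int, sigma: float) -> np.ndarray:
    """Pairwise ``exp(-d^2 / (2 sigma^2))`` over all lattice cell pairs."""
    yy, xx = np.mgrid[0:h, 0:w]
    ys, xs = yy.ravel(), xx.ravel()
    d2 = (ys[:, None] - ys[None, :]) ** 2 + (xs[:, None] - xs[None, :]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


_BALANCED_CACHE: dict[tuple, np.ndarray] = {}


def _balanced_distance_kernel(h: int, w: int, sigma: float) -> np.ndarray:
    """Doubly-stochastic (Sinkhorn-balanced) version of the distance kernel.

    On a bounded lattice the raw Gaussian kernel gives border nodes a lower
    degree, which would bias the conspicuity chain toward the lattice
    center.  Balancing makes the kernel's own chain mass-preserving, so
    uniform activation is an exact fixed point of the conspicuity step.
    """
    key = (h, w, round(sigma, 9))
    if key not in _BALANCED_CACHE:
        K = _lattice_distance_kernel(h, w, sigma)
        for _ in range(200):
            K = K / K.sum(axis=1, keepdims=True)
            K = K / K.sum(axis=0, keepdims=True)
            if np.abs(K.sum(axis=1) - 1.0).max() < 1e-12:
                break
        K = 0.5 * (K + K.T)  # symmetric by construction; remove roundoff drift
        _BALANCED_CACHE[key] = K
    return _BALANCED_CACHE[key]


def graph_activation(feature: FeatureMap | np.ndarray, config: GBVSConfig) -> np.ndarray:
    """Markovian activation of one feature map (unit-sum, lattice shape).

    A constant map (all dissimilarities zero) yields the uniform
    distribution by definition.  A small uniform floor on the weights
    guarantees ergodicity when isolated cells match their surround exactly.
    """
    M = np.asarray(getattr(feature, "values", feature), dtype=float)
    h, w = M.shape
    logM = np.log(np.maximum(M, config.epsilon_floor)).ravel()
    D = np.abs(logM[:, None] - logM[None, :])
    if D.max() == 0.0:
        return np.full((h, w), 1.0 / (h * w))
    G = _lattice_distance_kernel(h, w, config.sigma_dist)
    W = (D + config.epsilon_floor) * G
    v = markov_equilibrium(W, tol=config.power_iter_tol, max_iter=config.power_iter_max)
    return v.reshape(h, w)


def conspicuity_normalize(activation: np.ndarray, config: GBVSConfig) -> np.ndarray:
    """Second Markovian step: mass flows toward already active locations,
    concentrating the map (entropy non-increasing on typical inputs).

    Uses the border-corrected (doubly-stochastic) distance kernel so that
    uniform activation is a fixed point rather than acquiring a spurious
    center bias from lattice borders.
    """
    A = np.asarray(activation, dtype=float)
    h, w = A.shape
    G = _balanced_distance_kernel(h, w, config.sigma_dist)
    W = G * np.maximum(A.ravel(), config.epsilon_floor)[None, :]
    v = markov_equilibrium(W, tol=config.power_iter_tol, max_iter=config.power_iter_max)
    return v.reshape(h, w)


def gbvs_saliency(image: np.ndarray, config: GBVSConfig | None = None) -> SaliencyMap:
    """Full bottom-up pipeline: features -> activation -> conspicuity ->
    weighted channel sum -> upsample to image resolution -> blur -> unit sum."""
    config = config or GBVSConfig()
    if all(wt == 0 for wt in config.channel_weights.values()):
        raise ValueError("all channel weights are zero")
    img = _as_float_image(image)
    h, w = img.shape[:2]
    acc = np.zeros((config.lattice_h, config.lattice_w))
    for fm in extract_feature_maps(img, config):
        wt = config.channel_weights.get(fm.channel, 0.0)
        if wt == 0:
            continue
        acc += wt * conspicuity_normalize(graph_activation(fm, config), config)
    acc /= acc.sum()
    full = resize(acc, (h, w), order=1, anti_aliasing=False)
    if config.final_blur_frac > 0:
        full = ndimage.gaussian_filter(full, sigma=config.final_blur_frac * w)
    full = np.clip(full, 0.0, None)
    return SaliencyMap(full / full.sum())


# ---------------------------------------------------------------------------
# External maps and I/O
# ---------------------------------------------------------------------------


def load_external_saliency(path, target_resolution: tuple[int, int] | None = None
                           ) -> SaliencyMap:
    """Load a saliency map exported by any model (16-bit PNG or ``.npy``),
    resample to ``target_resolution`` (h, w), floor at 0, unit-sum."""
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path).astype(float)
    else:
        import imageio.v3 as iio

        values = iio.imread(path).astype(float)
        if values.ndim == 3:
            values = values.mean(axis=2)
    values = np.clip(values, 0.0, None)
    if values.sum() == 0:
        raise ValueError(f"all-zero saliency map: {path}")
    m = SaliencyMap(values / values.sum())
    if target_resolution is not None and tuple(values.shape) != tuple(target_resolution):
        m = m.resampled(tuple(target_resolution))
    return m


def save_saliency_map(smap: SaliencyMap | np.ndarray, path) -> None:
    """Write a map as 16-bit grayscale PNG or raw ``.npy`` float, by suffix."""
    values = np.asarray(getattr(smap, "values", smap), dtype=float)
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, values)
        return
    import imageio.v3 as iio

    peak = values.max()
    scaled = np.zeros_like(values) if peak == 0 else values / peak
    iio.imwrite(path, (scaled * 65535).round().astype(np.uint16))
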