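"""Frozen feature cores and image preprocessing.

A *core* is a fixed (never trained alongside the readout) function mapping a
batch of grayscale images to a stack of feature maps, shape
``(batch, channels, height, width)``.  Two desk-scale cores are provided:

- :class:`GaborBankCore` — a bank of zero-mean Gabor filters over a grid of
  orientations, spatial frequencies and phases.  Analytically tractable: the
  response of each channel to a matched full-field grating can be predicted,
  which makes the core useful as an oracle in tests.
- :class:`RandomConvNetCore` — a small, seeded, untrained convolutional
  network (conv + rectify stages), the analogue of an untrained-baseline
  network with random weights.

Arbitrary external feature extractors (e.g. wrappers around pretrained
networks) can be plugged in through :class:`ExternalCore`, which only needs a
callable and a declared channel count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessSpec:
    """Central crop in degrees of visual angle followed by resampling.

    Parameters
    ----------
    crop_degrees
        Visual-angle extent (one side of the square crop) to keep.
    source_resolution
        Resolution of the input image in pixels per degree.
    target_resolution
        Resolution the cropped patch is resampled to, in pixels per degree.
        Treated as a model hyperparameter: it decouples a core layer's
        receptive-field size in pixels from its nonlinear complexity.
    interpolation
        Resampling order name: "bicubic" (default), "bilinear" or "nearest".
    """

    crop_degrees: float
    source_resolution: float
    target_resolution: float
    interpolation: str = "bicubic"

    _ORDERS = {"nearest": 0, "bilinear": 1, "bicubic": 3}

    @property
    def crop_pixels(self) -> int:
        return int(round(self.crop_degrees * self.source_resolution))

    @property
    def target_pixels(self) -> int:
        n = int(round(self.crop_degrees * self.target_resolution))
        if n < 1:
            raise ValueError("target size must be at least 1 pixel")
        return n

    @property
    def order(self) -> int:
        try:
            return self._ORDERS[self.interpolation]
        except KeyError:
            raise ValueError(f"unknown interpolation {self.interpolation!r}") from None


def preprocess_image(image: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Crop the central ``crop_degrees`` and resample to the target resolution.

    Anti-aliasing is applied automatically when downsampling.  Returns a float
    array; intensities are not rescaled.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single 2D grayscale image")
    n = spec.crop_pixels
    h, w = image.shape
    if n > h or n > w:
        raise ValueError(
            f"crop of {n}px does not fit inside a {h}x{w} image"
        )
    top = (h - n) // 2
    left = (w - n) // 2
    crop = image[top:top + n, left:left + n].astype(float)
    m = spec.target_pixels
    if m == n:
        return crop
    anti_alias = m < n
    return resize(crop, (m, m), order=spec.order, anti_aliasing=anti_alias,
                  mode="reflect", preserve_range=True)


def preprocess_batch(images: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    return np.stack([preprocess_image(im, spec) for im in np.asarray(images)])


# ---------------------------------------------------------------------------
# Cores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreSpec:
    """Identifies a frozen core and the layer read from it."""

    core_id: str
    layer_id: str = "default"
    channels: int = 0
    trained: bool = False


class Core:
    """Base class: a frozen image -> feature-map function.

    Subclasses implement :meth:`features`, must be deterministic, and must not
    mutate any state when called.  Input images are expected on the 8-bit
    intensity scale [0, 255]; cores internally map them to [-0.5, 0.5].
    """

    core_id: str = "core"
    layer_id: str = "default"
    channels: int
    trained: bool = False

    def spec(self) -> CoreSpec:
        return CoreSpec(self.core_id, self.layer_id, self.channels, self.trained)

    def features(self, images: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, images: np.ndarray) -> np.ndarray:
        return self.features(images)

    @staticmethod
    def _as_batch(images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            images = images[None]
        if images.ndim != 3:
            raise ValueError("expected images of shape (batch, H, W) or (H, W)")
        return images / 255.0 - 0.5


def gabor_kernel(size: int, frequency: float, orientation: float,
                 phase: float, sigma: float) -> np.ndarray:
    """A zero-mean Gabor patch; frequency in cycles per pixel."""
    half = size // 2
    yy, xx = np.mgrid[-half:size - half, -half:size - half].astype(float)
    rot = xx * np.cos(orientation) + yy * np.sin(orientation)
    envelope = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    carrier = np.cos(2.0 * np.pi * frequency * rot + phase)
    k = envelope * carrier
    k -= k.mean()  # exactly zero response to constant images
    norm = np.linalg.norm(k)
    return k / norm if norm > 0 else k


class GaborBankCore(Core):
    """Bank of zero-mean Gabor filters, one output channel per filter.

    Channels are ordered orientation-major:
    ``channel = (i_orientation * n_freq + i_freq) * n_phase + i_phase``.
    Convolution uses 'same' boundary handling; the output grid is subsampled
    with the given stride, so output side length is ``ceil(side / stride)``.
    """

    core_id = "gabor_bank"

    def __init__(self, n_orientations: int = 4, frequencies: Sequence[float] = (0.1, 0.2),
                 phases: Sequence[float] = (0.0, np.pi / 2), kernel_size: int = 15,
                 sigma: float | None = None, stride: int = 4):
        self.n_orientations = int(n_orientations)
        self.frequencies = tuple(float(f) for f in frequencies)
        self.phases = tuple(float(p) for p in phases)
        self.kernel_size = int(kernel_size)
        self.sigma = float(sigma) if sigma is not None else kernel_size / 5.0
        self.stride = int(stride)
        self.orientations = tuple(
            np.pi * i / self.n_orientations for i in range(self.n_orientations)
        )
        self.init_kwargs = dict(
            n_orientations=self.n_orientations, frequencies=list(self.frequencies),
            phases=list(self.phases), kernel_size=self.kernel_size,
            sigma=self.sigma, stride=self.stride,
        )
        kernels = [
            gabor_kernel(self.kernel_size, f, theta, p, self.sigma)
            for theta in self.orientations
            for f in self.frequencies
            for p in self.phases
        ]
        self._kernels = np.stack(kernels)  # (C, k, k), frozen
        self.channels = len(kernels)
        self.layer_id = "gabor"

    def channel_index(self, i_orientation: int, i_freq: int, i_phase: int) -> int:
        return (i_orientation * len(self.frequencies) + i_freq) * len(self.phases) + i_phase

    def features(self, images: np.ndarray) -> np.ndarray:
        x = self._as_batch(images)
        s = self.stride
        h, w = x.shape[1:]
        k = self.kernel_size
        fh, fw = h + k - 1, w + k - 1          # linear-convolution FFT size
        fk = np.fft.rfft2(self._kernels, s=(fh, fw))     # (C, fh, fw//2+1)
        lo = k // 2
        chunks = []
        for start in range(0, x.shape[0], 64):  # bound FFT workspace memory
            xb = x[start:start + 64]
            fx = np.fft.rfft2(xb, s=(fh, fw))
            full = np.fft.irfft2(fx[:, None] * fk[None], s=(fh, fw))
            same = full[:, :, lo:lo + h, lo:lo + w]      # centered 'same' crop
            chunks.append(np.ascontiguousarray(same[:, :, ::s, ::s]))
        return np.concatenate(chunks) if len(chunks) > 1 else chunks[0]


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Strided 2D convolution (cross-correlation) with zero 'same' padding.

    x: (B, Cin, H, W); w: (Cout, Cin, k, k) -> (B, Cout, ceil(H/s), ceil(W/s)).
    """
    b, cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (B, Cin, Ho, Wo, k, k)
    return np.einsum("bihwyx,oiyx->bohw", windows, w, optimize=True)


class RandomConvNetCore(Core):
    """Small untrained convnet: seeded He-initialized conv + ReLU stages.

    Serves as the random-weights baseline with an architecture matched in
    spirit (conv stages, growing channels, spatial downsampling) to trained
    cores.  Fully deterministic given the seed.
    """

    core_id = "random_convnet"

    def __init__(self, seed: int = 0, stage_channels: Sequence[int] = (8, 16, 32),
                 kernel_size: int = 5, strides: Sequence[int] | None = None):
        rng = np.random.default_rng(seed)
        self.seed = int(seed)
        strides = tuple(strides) if strides is not None else (2,) * len(stage_channels)
        if len(strides) != len(stage_channels):
            raise ValueError("strides and stage_channels must have equal length")
        self.strides = strides
        weights = []
        cin = 1
        for cout in stage_channels:
            scale = np.sqrt(2.0 / (cin * kernel_size ** 2))
            weights.append(rng.normal(0.0, scale, size=(cout, cin, kernel_size, kernel_size)))
            cin = cout
        self._weights = weights  # frozen
        self.channels = stage_channels[-1]
        self.layer_id = f"stage{len(stage_channels)}"
        self.init_kwargs = dict(seed=self.seed, stage_channels=list(stage_channels),
                                kernel_size=kernel_size, strides=list(strides))

    def features(self, images: np.ndarray) -> np.ndarray:
        x = self._as_batch(images)[:, None, :, :]
        chunks = []
        for start in range(0, x.shape[0], 256):
            xb = x[start:start + 256]
            for w, s in zip(self._weights, self.strides):
                xb = np.maximum(_conv2d(xb, w, s), 0.0)
            chunks.append(xb)
        return np.concatenate(chunks) if len(chunks) > 1 else chunks[0]


class ExternalCore(Core):
    """Adapter wrapping any callable image-batch -> feature-map function.

    The callable must return ``(batch, channels, h, w)`` arrays and be
    deterministic; this class only supplies the :class:`Core` interface
    (declared channel count, spec metadata).  Pretrained weights are never
    bundled with this package.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], channels: int,
                 core_id: str = "external", layer_id: str = "default",
                 trained: bool = True):
        self._fn = fn
        self.channels = int(channels)
        self.core_id = core_id
        self.layer_id = layer_id
        self.trained = trained

    def features(self, images: np.ndarray) -> np.ndarray:
        out = np.asarray(self._fn(np.asarray(images)))
        if out.ndim != 4 or out.shape[1] != self.channels:
            raise ValueError(
                f"external core returned shape {out.shape}, expected "
                f"(batch, {self.channels}, h, w)"
            )
        return out


class ConcatCore(Core):
    """Channel-concatenation of member cores (equal spatial dims required).

    Used mainly as a *generating* core for ground-truth neurons whose tuning
    mixes two feature families — the synthetic analogue of a neuron whose
    nonlinearities are only partly captured by any single feature space.
    """

    core_id = "concat"

    def __init__(self, cores: Sequence[Core]):
        self.members = list(cores)
        self.channels = sum(c.channels for c in self.members)
        self.layer_id = "+".join(c.layer_id for c in self.members)

    def features(self, images: np.ndarray) -> np.ndarray:
        feats = [c.features(images) for c in self.members]
        shapes = {f.shape[2:] for f in feats}
        if len(shapes) != 1:
            raise ValueError(f"member cores disagree on spatial dims: {shapes}")
        return np.concatenate(feats, axis=1)


_CORE_FACTORIES = {
    "gabor_bank": GaborBankCore,
    "random_convnet": RandomConvNetCore,
}


def make_core(core_id: str, **kwargs) -> Core:
    """Instantiate a registered core by id (configuration entry point)."""
    try:
        factory = _CORE_FACTORIES[core_id]
    except KeyError:
        raise ValueError(
            f"unknown core id {core_id!r}; known: {sorted(_CORE_FACTORIES)}"
        ) from None
    return factory(**kwargs)
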