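"""Synthetic stimuli, ground-truth neurons and multi-session datasets.

Every downstream stage of the pipeline (feature head, point readout, Poisson
training, reliability and performance estimators) is validated by parameter
recovery on data generated here, where the true readout positions, weights
and signal/noise split are known.

The generator emulates the statistical structure the analysis assumes:

* grayscale 8-bit images with broadband spatial content — 1/f-filtered
  Gaussian noise mixed with randomly oriented Gabor patches, affinely mapped
  to [0, 255] and quantized;
* per-session unique single-trial train/validation images, plus one test set
  (default 75 images) shared by all sessions and repeated (default 45 times,
  the midpoint of the study's 40-50 repeats);
* per-neuron spike counts drawn independently Poisson(rate), where the rate
  is the same linear-nonlinear point-readout form the model fits:
  gain * (ELU(w . phi(pos) + b) + 1), with phi the core's feature maps after
  a fixed per-channel standardization and rectification.  Ground-truth rates
  are scaled (via ``gain``) so median counts land in the 0-10 per-presentation
  regime typical of cortical windows.

Because generation reuses the package's own interpolation and nonlinearity,
a model fitted with the matched core is correctly specified, and recovery of
(mu_n, w_n) is a sharp test of the whole fitting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .cores import Core, make_core, gabor_kernel
from .readout import ReadoutParams, readout_forward, softplus_inv


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImageSet:
    """Stack of grayscale 8-bit images plus generation metadata."""

    images: np.ndarray        # (n, size, size) uint8
    image_size: int
    resolution: float         # pixels per degree
    seed: int

    def __len__(self) -> int:
        return self.images.shape[0]


def _pink_noise(rng: np.random.Generator, size: int, exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal((size, size))
    fx = np.fft.fftfreq(size)
    fy = np.fft.fftfreq(size)
    f = np.sqrt(fx[None, :] ** 2 + fy[:, None] ** 2)
    f[0, 0] = 1.0  # leave DC untouched
    spectrum = np.fft.fft2(white) / f ** exponent
    out = np.real(np.fft.ifft2(spectrum))
    return (out - out.mean()) / (out.std() + 1e-12)


def generate_images(n: int, size: int = 64, resolution: float = 14.0,
                    seed: int = 0, n_patches: int = 3,
                    patch_amplitude: float = 1.5) -> SyntheticImageSet:
    """Generate broadband synthetic stimuli.

    Each image is 1/f-filtered Gaussian noise plus ``n_patches`` Gabor
    patches at random positions, orientations, frequencies and phases, then
    affinely mapped to [0, 255] and rounded to 8-bit.  Deterministic given
    the seed.
    """
    if n < 1 or size < 16:
        raise ValueError("need n >= 1 and size >= 16")
    rng = np.random.default_rng(seed)
    images = np.empty((n, size, size), dtype=np.uint8)
    for i in range(n):
        canvas = _pink_noise(rng, size)
        for _ in range(n_patches):
            ksize = int(rng.integers(size // 6, size // 2))
            patch = gabor_kernel(
                ksize,
                frequency=float(rng.uniform(0.05, 0.3)),
                orientation=float(rng.uniform(0, np.pi)),
                phase=float(rng.uniform(0, 2 * np.pi)),
                sigma=ksize / 4.0,
            )
            amp = patch_amplitude / (np.abs(patch).max() + 1e-12)
            top = int(rng.integers(0, size - ksize + 1))
            left = int(rng.integers(0, size - ksize + 1))
            canvas[top:top + ksize, left:left + ksize] += amp * patch
        lo, hi = canvas.min(), canvas.max()
        scaled = (canvas - lo) / (hi - lo + 1e-12) * 255.0
        images[i] = np.round(scaled).astype(np.uint8)
    return SyntheticImageSet(images=images, image_size=size,
                             resolution=resolution, seed=seed)


# ---------------------------------------------------------------------------
# Ground-truth neurons
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthNeuron:
    """Generative parameters of one simulated neuron."""

    core_id: str
    layer_id: str
    position: np.ndarray      # (2,) relative coordinates in [-1, 1]
    weights: np.ndarray       # (channels,)
    bias: float
    gain: float               # positive rate scale


@dataclass
class GroundTruthPopulation(Sequence):
    """A set of ground-truth neurons tied to a generating core.

    ``feature_mean`` / ``feature_std`` define the fixed per-channel
    standardization applied to the core's raw maps before rectification —
    the generative mirror of the fitted batch-norm head.  They are frozen at
    first use (or set explicitly via :meth:`standardize_from`) so repeated
    simulations share one feature space.
    """

    core: Core
    neurons: list[GroundTruthNeuron]
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.neurons)

    def __getitem__(self, i):
        return self.neurons[i]

    def standardize_from(self, images: np.ndarray) -> None:
        raw = self.core.features(images)
        self.feature_mean = raw.mean(axis=(0, 2, 3))
        self.feature_std = raw.std(axis=(0, 2, 3)) + 1e-8

    def phi(self, images: np.ndarray) -> np.ndarray:
        """Standardized, rectified feature maps of the generating core."""
        if self.feature_mean is None:
            self.standardize_from(images)
        raw = self.core.features(images)
        xhat = ((raw - self.feature_mean[:, None, None])
                / self.feature_std[:, None, None])
        return np.maximum(xhat, 0.0)

    def rates(self, images: np.ndarray) -> np.ndarray:
        """Noise-free firing rates, shape (n_images, n_neurons).

        Computed with the package's own readout forward (bilinear
        interpolation at the true position, ELU + 1), scaled by each
        neuron's gain — so a fitted model with the matched core is correctly
        specified up to the per-channel affine the head learns.
        """
        phi = self.phi(images)
        params = ReadoutParams(
            mu=np.stack([n.position for n in self.neurons]),
            sigma_raw=np.full(len(self), softplus_inv(1e-3)),
            weights=np.stack([n.weights for n in self.neurons]),
            bias=np.array([n.bias for n in self.neurons]),
        )
        gains = np.array([n.gain for n in self.neurons])
        return readout_forward(phi, params) * gains


def make_population(core: Core | str, n_neurons: int, weight_sparsity: float = 0.3,
                    gain: float = 2.0, seed: int = 0, weight_scale: float = 2.0,
                    bias_std: float = 0.1, position_range: float = 1.0,
                    **core_kwargs) -> GroundTruthPopulation:
    """Draw a random ground-truth population for a generating core.

    Positions are uniform in [-position_range, position_range]^2 (default the
    full map); each weight vector is zero-mean Gaussian with an independent
    Bernoulli(weight_sparsity) nonzero mask, rescaled to ``weight_scale``
    Euclidean norm so signal strength is comparable across neurons.  The
    generated rate is strictly positive for every input (ELU + 1 range times
    a positive gain).
    """
    if not 0 < weight_sparsity <= 1:
        raise ValueError("weight_sparsity must be in (0, 1]")
    if gain <= 0:
        raise ValueError("gain must be positive")
    if isinstance(core, str):
        core = make_core(core, **core_kwargs)
    rng = np.random.default_rng(seed)
    neurons = []
    for _ in range(n_neurons):
        pos = rng.uniform(-position_range, position_range, size=2)
        w = rng.standard_normal(core.channels)
        mask = rng.random(core.channels) < weight_sparsity
        if not mask.any():
            mask[rng.integers(core.channels)] = True
        w = w * mask
        w *= weight_scale / (np.linalg.norm(w) + 1e-12)
        neurons.append(GroundTruthNeuron(
            core_id=core.core_id, layer_id=core.layer_id, position=pos,
            weights=w, bias=float(rng.normal(0.0, bias_std)), gain=float(gain),
        ))
    return GroundTruthPopulation(core=core, neurons=neurons)


def simulate_responses(population: GroundTruthPopulation, images: np.ndarray,
                       repeats: int = 1, seed: int = 0) -> np.ndarray:
    """Poisson spike counts for every image x repeat x neuron.

    Counts are drawn independently Poisson(rate) per repeat; output shape
    (n_images, repeats, n_neurons) — the repeat axis is kept even for
    repeats=1.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    rates = population.rates(images)                    # (n_images, N)
    lam = np.broadcast_to(rates[:, None, :], (rates.shape[0], repeats, rates.shape[1]))
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# Sessions and area datasets
# ---------------------------------------------------------------------------

@dataclass
class SessionData:
    """One recording session: single-trial train/validation, repeated test."""

    session_id: str
    train_images: np.ndarray        # (n_train, size, size)
    train_counts: np.ndarray        # (n_train, n_neurons) single trial
    validation_images: np.ndarray
    validation_counts: np.ndarray
    test_images: np.ndarray         # shared across sessions
    test_counts: np.ndarray         # (n_test, repeats, n_neurons)
    neuron_ids: list
    train_image_ids: np.ndarray = None
    validation_image_ids: np.ndarray = None
    ground_truth: GroundTruthPopulation | None = None

    def __post_init__(self):
        for counts in (self.train_counts, self.validation_counts, self.test_counts):
            if np.any(counts < 0):
                raise ValueError("spike counts must be nonnegative")
        if self.test_counts.shape[1] < 2:
            raise ValueError("test set needs >= 2 repeats per image")
        if (self.train_image_ids is not None
                and self.validation_image_ids is not None
                and np.intersect1d(self.train_image_ids,
                                   self.validation_image_ids).size):
            raise ValueError("train and validation image sets must be disjoint")


def assemble_area_dataset(n_sessions: int, images_per_session: int,
                          neurons_per_session: int, n_test_images: int = 75,
                          test_repeats: int = 45, validation_fraction: float = 0.2,
                          seed: int = 0, core: Core | str = "gabor_bank",
                          image_size: int = 64, resolution: float = 14.0,
                          gain: float = 2.0, weight_sparsity: float = 0.3,
                          weight_scale: float = 2.0, pool_size: int | None = None,
                          **core_kwargs) -> list[SessionData]:
    """Simulate all sessions of one visual 'area'.

    Each session receives its own ground-truth neurons and its own unique
    train/validation images (disjoint across sessions); one shared test set
    of ``n_test_images`` is repeated ``test_repeats`` times in every session.
    The feature standardization behind the ground-truth rates is estimated
    once from the full image pool and shared by all sessions.
    """
    if n_test_images < 2:
        raise ValueError("need at least 2 test images")
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    if isinstance(core, str):
        core = make_core(core, **core_kwargs)
    needed = n_sessions * images_per_session + n_test_images
    if pool_size is None:
        pool_size = needed
    if pool_size < needed:
        raise ValueError(
            f"image pool of {pool_size} cannot supply {needed} distinct images"
        )
    rng = np.random.default_rng(seed)
    pool = generate_images(pool_size, size=image_size, resolution=resolution,
                           seed=int(rng.integers(2 ** 31)))
    order = rng.permutation(pool_size)
    test_ids = order[:n_test_images]
    test_images = pool.images[test_ids]

    # one shared standardization for the whole area
    stats_pop = None
    sessions = []
    cursor = n_test_images
    n_val = int(round(validation_fraction * images_per_session))
    for s in range(n_sessions):
        ids = order[cursor:cursor + images_per_session]
        cursor += images_per_session
        val_ids, train_ids = ids[:n_val], ids[n_val:]
        population = make_population(
            core, neurons_per_session, weight_sparsity=weight_sparsity,
            gain=gain, weight_scale=weight_scale,
            seed=int(rng.integers(2 ** 31)),
        )
        if stats_pop is None:
            population.standardize_from(pool.images)
            stats_pop = population
        else:
            population.feature_mean = stats_pop.feature_mean
            population.feature_std = stats_pop.feature_std
        train_images = pool.images[train_ids]
        val_images = pool.images[val_ids]
        sim_seed = int(rng.integers(2 ** 31))
        train_counts = simulate_responses(population, train_images, 1, sim_seed)[:, 0, :]
        val_counts = simulate_responses(population, val_images, 1, sim_seed + 1)[:, 0, :]
        test_counts = simulate_responses(population, test_images, test_repeats,
                                         sim_seed + 2)
        sessions.append(SessionData(
            session_id=f"session{s:02d}",
            train_images=train_images, train_counts=train_counts,
            validation_images=val_images, validation_counts=val_counts,
            test_images=test_images, test_counts=test_counts,
            neuron_ids=[f"s{s:02d}n{i:03d}" for i in range(neurons_per_session)],
            train_image_ids=train_ids, validation_image_ids=val_ids,
            ground_truth=population,
        ))
    return sessions


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_dataset(sessions: list[SessionData], path, attrs: dict | None = None) -> None:
    """Write an area dataset to HDF5.

    Layout: ``/test/images`` (shared), and per session
    ``/sessions/<id>/{train,validation}/{images,counts}`` plus
    ``/sessions/<id>/test/counts`` stored image x repeat x neuron.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("test/images", data=sessions[0].test_images)
        for sess in sessions:
            g = f.create_group(f"sessions/{sess.session_id}")
            g.create_dataset("train/images", data=sess.train_images)
            g.create_dataset("train/counts", data=sess.train_counts)
            g.create_dataset("validation/images", data=sess.validation_images)
            g.create_dataset("validation/counts", data=sess.validation_counts)
            g.create_dataset("test/counts", data=sess.test_counts)
            g.attrs["neuron_ids"] = [str(n) for n in sess.neuron_ids]
            if sess.train_image_ids is not None:
                g.create_dataset("train/image_ids", data=sess.train_image_ids)
                g.create_dataset("validation/image_ids", data=sess.validation_image_ids)
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def load_dataset(path) -> list[SessionData]:
    sessions = []
    with h5py.File(path, "r") as f:
        test_images = f["test/images"][:]
        for sid in sorted(f["sessions"]):
            g = f[f"sessions/{sid}"]
            sessions.append(SessionData(
                session_id=sid,
                train_images=g["train/images"][:],
                train_counts=g["train/counts"][:],
                validation_images=g["validation/images"][:],
                validation_counts=g["validation/counts"][:],
                test_images=test_images,
                test_counts=g["test/counts"][:],
                neuron_ids=list(g.attrs["neuron_ids"]),
                train_image_ids=(g["train/image_ids"][:]
                                 if "train/image_ids" in g else None),
                validation_image_ids=(g["validation/image_ids"][:]
                                      if "validation/image_ids" in g else None),
            ))
    return sessions
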