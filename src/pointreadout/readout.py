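"""Per-neuron Gaussian point readout.

Each neuron reads the feature tensor at a single continuous spatial location
expressed in relative coordinates: (x, y) in [-1, 1]^2 with (0, 0) at the map
center, x along width and y along height.  During training the location is a
reparameterized draw from an isotropic Gaussian N(mu_n, sigma_n^2 I) — wide
at initialization so gradients reach mu_n from a large neighborhood, shrinking
as sigma_n^2 is learned down.  At evaluation the readout is deterministic and
uses mu_n.  Features at the location are bilinearly interpolated over the
2x2 grid neighborhood, combined linearly with an L1-regularized weight vector
plus bias, and passed through ELU + 1 so predicted rates are strictly
positive.  Parameter count per neuron: c + 4 (c weights, 2D mean, scalar
variance, bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._math import elu_plus_one, softplus, softplus_inv, sigmoid

#: default position-sampling std at initialization: 5% of the map width.
#: Large enough for gradient flow around the (correlation-map initialized)
#: position, small enough to stay within the feature maps' spatial
#: correlation length at desk-scale map sizes.
INIT_POSITION_STD = 0.1


@dataclass
class ReadoutParams:
    """Parameters of N point readouts over a c-channel feature space.

    sigma2 is stored through a softplus reparameterization (``sigma_raw``) so
    that the variance stays positive under unconstrained gradient updates.
    """

    mu: np.ndarray          # (N, 2) relative coordinates
    sigma_raw: np.ndarray   # (N,) softplus^-1 of the isotropic variance
    weights: np.ndarray     # (N, c)
    bias: np.ndarray        # (N,)

    @property
    def n_neurons(self) -> int:
        return self.mu.shape[0]

    @property
    def channels(self) -> int:
        return self.weights.shape[1]

    @property
    def sigma2(self) -> np.ndarray:
        return softplus(self.sigma_raw)

    @classmethod
    def initialize(cls, n_neurons: int, channels: int, rng: np.random.Generator,
                   weight_scale: float = 0.01, position_jitter: float = 0.05,
                   init_std: float = INIT_POSITION_STD) -> "ReadoutParams":
        """Default initialization: positions near the map center with small
        jitter, wide sampling variance, small random weights, zero bias."""
        mu = rng.normal(0.0, position_jitter, size=(n_neurons, 2)).clip(-1, 1)
        sigma_raw = np.full(n_neurons, float(softplus_inv(init_std ** 2)))
        weights = rng.normal(0.0, weight_scale, size=(n_neurons, channels))
        bias = np.zeros(n_neurons)
        return cls(mu=mu, sigma_raw=sigma_raw, weights=weights, bias=bias)

    def copy(self) -> "ReadoutParams":
        return ReadoutParams(self.mu.copy(), self.sigma_raw.copy(),
                             self.weights.copy(), self.bias.copy())


def sample_position(params: ReadoutParams, train: bool,
                    rng: np.random.Generator | None = None):
    """Draw readout locations for one training step, or return the means.

    Train mode returns ``(positions, eps)`` where ``positions`` is the
    reparameterized draw mu + sqrt(sigma2) * eps clamped to [-1, 1]^2 and
    ``eps`` the standard-normal noise (needed for the sigma gradient).  Eval
    mode returns ``(mu, None)`` exactly.
    """
    if not train:
        return params.mu.copy(), None
    if rng is None:
        raise ValueError("train-mode sampling requires an rng")
    eps = rng.standard_normal(params.mu.shape)
    std = np.sqrt(params.sigma2)[:, None]
    raw = params.mu + std * eps
    return np.clip(raw, -1.0, 1.0), eps


def _grid_coords(positions: np.ndarray, h: int, w: int):
    """Map relative [-1, 1] coordinates to fractional pixel indices.

    Returns integer corner indices and fractional parts for bilinear
    interpolation; positions outside [-1, 1] are clamped to the map edge.
    """
    p = np.clip(np.asarray(positions, dtype=float), -1.0, 1.0)
    gx = (p[:, 0] + 1.0) / 2.0 * (w - 1)
    gy = (p[:, 1] + 1.0) / 2.0 * (h - 1)
    ix0 = np.floor(gx).astype(int)
    iy0 = np.floor(gy).astype(int)
    ix0 = np.clip(ix0, 0, max(w - 2, 0))
    iy0 = np.clip(iy0, 0, max(h - 2, 0))
    ix1 = np.minimum(ix0 + 1, w - 1)
    iy1 = np.minimum(iy0 + 1, h - 1)
    fx = gx - ix0
    fy = gy - iy0
    return ix0, ix1, iy0, iy1, fx, fy


def interpolate_features(features: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Bilinearly interpolate feature maps at per-neuron locations.

    Parameters
    ----------
    features
        (batch, channels, h, w) feature tensor.
    positions
        (N, 2) relative coordinates, shared across the batch.

    Returns
    -------
    (batch, N, channels) array of interpolated feature vectors.
    """
    b, c, h, w = features.shape
    ix0, ix1, iy0, iy1, fx, fy = _grid_coords(positions, h, w)
    v00 = features[:, :, iy0, ix0]  # (B, C, N)
    v01 = features[:, :, iy0, ix1]
    v10 = features[:, :, iy1, ix0]
    v11 = features[:, :, iy1, ix1]
    wx1, wy1 = fx, fy
    wx0, wy0 = 1.0 - fx, 1.0 - fy
    out = (v00 * (wy0 * wx0) + v01 * (wy0 * wx1)
           + v10 * (wy1 * wx0) + v11 * (wy1 * wx1))
    return np.transpose(out, (0, 2, 1))


def readout_forward(features: np.ndarray, params: ReadoutParams,
                    positions: np.ndarray | None = None) -> np.ndarray:
    """Predicted firing rate per neuron: ELU(phi(pos) . w + b) + 1.

    ``positions`` defaults to the deterministic evaluation positions mu.
    Output shape (batch, N); strictly positive.
    """
    if positions is None:
        positions = params.mu
    if params.weights.shape[1] != features.shape[1]:
        raise ValueError(
            f"readout expects {params.weights.shape[1]} channels, feature "
            f"tensor has {features.shape[1]}"
        )
    phi = interpolate_features(features, positions)          # (B, N, C)
    z = np.einsum("bnc,nc->bn", phi, params.weights) + params.bias
    return elu_plus_one(z)


def sigma2_grad_factor(params: ReadoutParams) -> np.ndarray:
    """d sqrt(sigma2) / d sigma_raw, used by the training backward pass."""
    sigma2 = params.sigma2
    return 0.5 / np.sqrt(sigma2 + 1e-12) * sigmoid(params.sigma_raw)
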