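"""Shared feature head: per-channel batch normalization followed by rectification.

The head turns a frozen core's raw feature maps into the nonnegative feature
space shared by all neurons:  BN(x) = gamma * (x - mu) / sigma + beta per
channel, then an elementwise max(., 0).  Normalizing each channel to zero
mean / unit variance before rectification makes a single L1 penalty
meaningful across all readout weights; channels with larger raw variance
would otherwise be penalized less.

In train mode the normalization uses the current batch's statistics and
updates exponentially blended running statistics; in eval mode the running
statistics are frozen and the head is a pure deterministic function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FeatureHead:
    """Trainable scale/shift with running normalization statistics.

    Parameters gamma and beta are learned jointly with the readouts; the
    running mean/variance are updated with momentum (default 0.1) during
    train-mode passes only.
    """

    channels: int
    momentum: float = 0.1
    eps: float = 1e-5
    gamma: np.ndarray = None
    beta: np.ndarray = None
    running_mean: np.ndarray = None
    running_var: np.ndarray = None

    def __post_init__(self):
        c = self.channels
        if self.gamma is None:
            self.gamma = np.ones(c)
        if self.beta is None:
            self.beta = np.zeros(c)
        if self.running_mean is None:
            self.running_mean = np.zeros(c)
        if self.running_var is None:
            self.running_var = np.ones(c)

    def forward(self, raw: np.ndarray, train: bool):
        """Normalize, scale/shift and rectify a raw feature batch.

        Parameters
        ----------
        raw
            Array (batch, channels, h, w) from a frozen core.
        train
            If True, use batch statistics and update running statistics.
            If False, use the stored running statistics and mutate nothing.

        Returns
        -------
        phi, cache
            ``phi`` is the rectified output with the same shape as ``raw``;
            ``cache`` holds the normalized pre-scale activations ``xhat`` and
            the pre-rectification values ``y`` needed for the backward pass.
        """
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 4 or raw.shape[1] != self.channels:
            raise ValueError(
                f"expected (batch, {self.channels}, h, w), got {raw.shape}"
            )
        if train:
            mean = raw.mean(axis=(0, 2, 3))
            var = raw.var(axis=(0, 2, 3))
            n = raw.shape[0] * raw.shape[2] * raw.shape[3]
            unbiased = var * n / max(n - 1, 1)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            if np.any(self.running_var <= 0):
                raise RuntimeError("running variance must be positive in eval mode")
            mean = self.running_mean
            var = self.running_var
        xhat = (raw - mean[:, None, None]) / np.sqrt(var + self.eps)[:, None, None]
        y = self.gamma[:, None, None] * xhat + self.beta[:, None, None]
        phi = np.maximum(y, 0.0)
        return phi, {"xhat": xhat, "y": y}

    def copy(self) -> "FeatureHead":
        return FeatureHead(
            channels=self.channels, momentum=self.momentum, eps=self.eps,
            gamma=self.gamma.copy(), beta=self.beta.copy(),
            running_mean=self.running_mean.copy(),
            running_var=self.running_var.copy(),
        )


def feature_head(raw: np.ndarray, params: FeatureHead, train: bool = False) -> np.ndarray:
    """Functional wrapper returning only the rectified feature tensor."""
    phi, _ = params.forward(raw, train=train)
    return phi
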