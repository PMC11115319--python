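"""Encoding model: frozen core(s) -> feature head(s) -> point readouts.

A single :class:`EncodingModel` covers both the single-core case and joint
readouts from two or three cores: member cores all receive the identical
preprocessed input, each core's raw maps pass through its own batch-norm +
rectify head, the resulting feature tensors are concatenated along channels
(block boundaries recorded), and one point readout per neuron acts on the
concatenated space.  A single-core model is exactly the one-block special
case, so any single model is representable inside a pair model by zeroing the
other block's weights.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .cores import Core, make_core
from .features import FeatureHead
from .readout import ReadoutParams, readout_forward, sample_position


class EncodingModel:
    """Jointly trainable feature head(s) + readouts over frozen cores.

    Parameters
    ----------
    cores
        One to three frozen :class:`~pointreadout.cores.Core` instances.  All
        must produce feature maps with identical spatial dimensions for the
        inputs used.
    n_neurons
        Total number of neurons (across all sessions) read out.
    seed
        Seed for readout initialization.
    bn_momentum
        Momentum of the heads' running-statistic updates.
    """

    def __init__(self, cores: Core | list[Core], n_neurons: int, seed: int = 0,
                 bn_momentum: float = 0.1, readout: ReadoutParams | None = None,
                 heads: list[FeatureHead] | None = None):
        if isinstance(cores, Core):
            cores = [cores]
        if not 1 <= len(cores) <= 3:
            raise ValueError("EncodingModel supports 1-3 cores")
        self.cores = list(cores)
        if heads is None:
            heads = [FeatureHead(c.channels, momentum=bn_momentum) for c in cores]
        self.heads = heads
        channels = [c.channels for c in cores]
        bounds = np.cumsum([0] + channels)
        #: per-core channel slices into the concatenated feature space
        self.block_slices = [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
        self.total_channels = int(bounds[-1])
        rng = np.random.default_rng(seed)
        if readout is None:
            readout = ReadoutParams.initialize(n_neurons, self.total_channels, rng)
        if readout.channels != self.total_channels:
            raise ValueError("readout channel count does not match cores")
        self.readout = readout
        self.n_neurons = n_neurons

    # -- feature pipeline ---------------------------------------------------

    def raw_features(self, images: np.ndarray) -> list[np.ndarray]:
        """Frozen-core feature maps, one array per core; spatial dims checked."""
        raws = [core.features(images) for core in self.cores]
        shapes = {r.shape[2:] for r in raws}
        if len(shapes) != 1:
            raise ValueError(f"member cores disagree on spatial dims: {shapes}")
        return raws

    def concat_phi(self, raws: list[np.ndarray], train: bool = False):
        """Apply each head and concatenate channel blocks.

        Returns the concatenated rectified tensor and the per-block caches
        needed for gradient computation.
        """
        phis, caches = [], []
        for raw, head in zip(raws, self.heads):
            phi, cache = head.forward(raw, train=train)
            phis.append(phi)
            caches.append(cache)
        return np.concatenate(phis, axis=1), caches

    def predict(self, images: np.ndarray | None = None,
                raws: list[np.ndarray] | None = None,
                train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Predicted rates, shape (batch, n_neurons).

        Eval mode (default) is deterministic: frozen normalization statistics
        and readout positions at mu.  Train mode uses batch statistics and a
        sampled position per neuron.
        """
        if raws is None:
            if images is None:
                raise ValueError("provide images or precomputed raw features")
            raws = self.raw_features(images)
        phi, _ = self.concat_phi(raws, train=train)
        positions, _ = sample_position(self.readout, train=train, rng=rng)
        return readout_forward(phi, self.readout, positions)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        """Live views of all trainable arrays, keyed by name."""
        params = {}
        for i, head in enumerate(self.heads):
            params[f"gamma_{i}"] = head.gamma
            params[f"beta_{i}"] = head.beta
        params["mu"] = self.readout.mu
        params["sigma_raw"] = self.readout.sigma_raw
        params["weights"] = self.readout.weights
        params["bias"] = self.readout.bias
        return params

    def get_state(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.parameters().items()}
        for i, head in enumerate(self.heads):
            state[f"running_mean_{i}"] = head.running_mean.copy()
            state[f"running_var_{i}"] = head.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, head in enumerate(self.heads):
            head.gamma = state[f"gamma_{i}"].copy()
            head.beta = state[f"beta_{i}"].copy()
            head.running_mean = state[f"running_mean_{i}"].copy()
            head.running_var = state[f"running_var_{i}"].copy()
        self.readout.mu = state["mu"].copy()
        self.readout.sigma_raw = state["sigma_raw"].copy()
        self.readout.weights = state["weights"].copy()
        self.readout.bias = state["bias"].copy()

    def core_fingerprint(self) -> list[bytes]:
        """Hashable snapshot of frozen core parameters (for frozenness checks)."""
        out = []
        for core in self.cores:
            arrs = []
            for attr in ("_kernels", "_weights"):
                val = getattr(core, attr, None)
                if val is None:
                    continue
                arrs.extend(val if isinstance(val, list) else [val])
            out.append(b"".join(np.ascontiguousarray(a).tobytes() for a in arrs))
        return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: EncodingModel, path, history=None) -> None:
    """Persist a model (and optionally its fit history) to HDF5.

    Core weights are not stored — cores are frozen and reconstructable from
    their configuration (toy cores) or supplied at load time (external
    cores).
    """
    with h5py.File(path, "w") as f:
        f.attrs["n_neurons"] = model.n_neurons
        f.attrs["n_cores"] = len(model.cores)
        for i, (core, head) in enumerate(zip(model.cores, model.heads)):
            g = f.create_group(f"cores/{i}")
            g.attrs["core_id"] = core.core_id
            g.attrs["layer_id"] = core.layer_id
            g.attrs["channels"] = core.channels
            kwargs = getattr(core, "init_kwargs", None)
            if kwargs is not None:
                g.attrs["init_kwargs"] = json.dumps(kwargs)
            gh = f.create_group(f"heads/{i}")
            gh.attrs["momentum"] = head.momentum
            gh.attrs["eps"] = head.eps
            for name in ("gamma", "beta", "running_mean", "running_var"):
                gh.create_dataset(name, data=getattr(head, name))
        gr = f.create_group("readout")
        for name in ("mu", "sigma_raw", "weights", "bias"):
            gr.create_dataset(name, data=getattr(model.readout, name))
        if history is not None:
            gh = f.create_group("history")
            for key, val in history.as_dict().items():
                gh.create_dataset(key, data=np.asarray(val))


def load_checkpoint(path, cores: list[Core] | None = None) -> EncodingModel:
    """Rebuild a model from :func:`save_checkpoint` output.

    Toy cores are reconstructed from their stored configuration; external
    cores must be passed in ``cores`` (order must match the checkpoint).
    """
    with h5py.File(path, "r") as f:
        n_cores = int(f.attrs["n_cores"])
        if cores is None:
            cores = []
            for i in range(n_cores):
                g = f[f"cores/{i}"]
                if "init_kwargs" not in g.attrs:
                    raise ValueError(
                        "checkpoint stores no core configuration; pass cores="
                    )
                cores.append(make_core(g.attrs["core_id"],
                                       **json.loads(g.attrs["init_kwargs"])))
        heads = []
        for i in range(n_cores):
            gh = f[f"heads/{i}"]
            heads.append(FeatureHead(
                channels=cores[i].channels,
                momentum=float(gh.attrs["momentum"]), eps=float(gh.attrs["eps"]),
                gamma=gh["gamma"][:], beta=gh["beta"][:],
                running_mean=gh["running_mean"][:], running_var=gh["running_var"][:],
            ))
        gr = f["readout"]
        readout = ReadoutParams(mu=gr["mu"][:], sigma_raw=gr["sigma_raw"][:],
                                weights=gr["weights"][:], bias=gr["bias"][:])
    return EncodingModel(cores, n_neurons=readout.n_neurons,
                         readout=readout, heads=heads)
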