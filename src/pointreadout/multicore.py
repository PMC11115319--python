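"""Joint readouts over concatenated feature spaces of two or three cores.

All member cores see the identical preprocessed input; their rectified,
batch-normalized feature maps are concatenated along channels and a single
point readout per neuron (one position, one weight vector over the
concatenated channels) maps them to rates.  Because zeroing one block's
weights recovers the other block's single-core model exactly, the pair
model's best achievable fit is never worse than either single model — up to
optimization error, which is exactly what the warm-start training strategies
target:

- ``scratch``          — random readout weights on all blocks;
- ``init1_tune2``      — block 1 copied from its fitted single-core model
  (weights, position, bias, head), block 2 zeroed; only block 2's weights
  (plus shared position/bias and block-2 head) are trained;
- ``init2_tune1``      — the mirror image;
- ``init1_tune_all``   — block 1 copied, block 2 zeroed, everything trained;
- ``init2_tune_all``   — the mirror image.

Triplets are warm-started from a fitted pair: two blocks copied, the third
zeroed, all readout weights fine-tuned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cores import Core
from .model import EncodingModel
from .training import TrainSchedule, fit, validation_loss, neuron_slices

STRATEGIES = ("scratch", "init1_tune2", "init2_tune1",
              "init1_tune_all", "init2_tune_all")


@dataclass(frozen=True)
class StrategySpec:
    """Named warm-start strategy plus the L1 grid to validate over."""

    name: str
    l1_grid: tuple = (1.0,)

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}; one of {STRATEGIES}")


def concat_forward(cores: list[Core], heads, images: np.ndarray):
    """Concatenated rectified feature tensor for a batch of images.

    Returns ``(features, block_slices)`` where block boundaries record each
    core's channel range.  Spatial dimensions must agree across members.
    """
    raws = [core.features(images) for core in cores]
    shapes = {r.shape[2:] for r in raws}
    if len(shapes) != 1:
        raise ValueError(f"member cores disagree on spatial dims: {shapes}")
    phis = [head.forward(raw, train=False)[0] for raw, head in zip(raws, heads)]
    channels = np.cumsum([0] + [p.shape[1] for p in phis])
    slices = [slice(int(a), int(b)) for a, b in zip(channels[:-1], channels[1:])]
    return np.concatenate(phis, axis=1), slices


def _zero_masks_like(model: EncodingModel) -> dict[str, np.ndarray]:
    return {k: np.ones_like(v) for k, v in model.parameters().items()}


def init_pair_readout(strategy: StrategySpec | str, singles: list[EncodingModel],
                      seed: int = 0):
    """Build a joint model over the singles' cores under a training strategy.

    ``singles`` are single-core models (fitted, or freshly initialized for
    controls such as pairing with an untrained core); their neuron counts
    must match.  Returns ``(model, masks)`` where ``masks`` flags the
    parameters the strategy trains (1) or freezes (0).
    """
    if isinstance(strategy, str):
        strategy = StrategySpec(strategy)
    if len(singles) != 2:
        raise ValueError("pair initialization needs exactly two single models")
    if any(len(m.cores) != 1 for m in singles):
        raise ValueError("singles must be single-core models")
    n_neurons = singles[0].n_neurons
    if singles[1].n_neurons != n_neurons:
        raise ValueError("singles must cover the same neurons")

    cores = [m.cores[0] for m in singles]
    heads = [m.heads[0].copy() for m in singles]
    model = EncodingModel(cores, n_neurons=n_neurons, seed=seed, heads=heads)
    masks = _zero_masks_like(model)
    if strategy.name == "scratch":
        return model, masks

    init_block = 0 if strategy.name.startswith("init1") else 1
    other_block = 1 - init_block
    src = singles[init_block]
    blk = model.block_slices[init_block]
    ro = model.readout
    ro.weights[:] = 0.0
    ro.weights[:, blk] = src.readout.weights
    ro.mu[:] = src.readout.mu
    ro.sigma_raw[:] = src.readout.sigma_raw
    ro.bias[:] = src.readout.bias

    if strategy.name.endswith("tune_all"):
        return model, masks
    # tune only the other block's readout weights (and its head); the
    # initialized block's weights and head scale/shift stay frozen
    masks["weights"] = np.zeros_like(ro.weights)
    masks["weights"][:, model.block_slices[other_block]] = 1.0
    masks[f"gamma_{init_block}"] = np.zeros_like(model.heads[init_block].gamma)
    masks[f"beta_{init_block}"] = np.zeros_like(model.heads[init_block].beta)
    return model, masks


def init_triplet_readout(pair: EncodingModel, third: EncodingModel, seed: int = 0):
    """Warm-start a triplet from a fitted pair plus a third single model.

    The pair's two blocks are copied (weights, heads, position), the third
    block starts at zero, and all readout weights are fine-tuned.
    """
    if len(pair.cores) != 2 or len(third.cores) != 1:
        raise ValueError("expected a fitted pair model and a single-core model")
    if third.n_neurons != pair.n_neurons:
        raise ValueError("neuron counts must match")
    cores = list(pair.cores) + [third.cores[0]]
    heads = [h.copy() for h in pair.heads] + [third.heads[0].copy()]
    model = EncodingModel(cores, n_neurons=pair.n_neurons, seed=seed, heads=heads)
    ro = model.readout
    ro.weights[:] = 0.0
    c_pair = pair.total_channels
    ro.weights[:, :c_pair] = pair.readout.weights
    ro.mu[:] = pair.readout.mu
    ro.sigma_raw[:] = pair.readout.sigma_raw
    ro.bias[:] = pair.readout.bias
    return model, _zero_masks_like(model)


def fit_multicore(strategy: StrategySpec | str, singles: list[EncodingModel],
                  sessions, schedule: TrainSchedule | None = None, seed: int = 0):
    """Initialize a pair model under a strategy and fit it.

    If the strategy's ``l1_grid`` has several values, each is fitted from the
    same initialization and the model with the best validation loss is kept.
    Returns ``(model, history, best_l1)``.
    """
    if isinstance(strategy, str):
        strategy = StrategySpec(strategy)
    if schedule is None:
        schedule = TrainSchedule()
    best = None
    for l1 in strategy.l1_grid:
        model, masks = init_pair_readout(strategy, singles, seed=seed)
        sched = TrainSchedule(**{**schedule.__dict__, "l1": l1})
        model, history = fit(model, sessions, sched, masks=masks)
        val = validation_loss(model, sessions,
                              [model.raw_features(s.validation_images) for s in sessions],
                              neuron_slices(sessions))
        if best is None or val < best[0]:
            best = (val, model, history, l1)
    _, model, history, l1 = best
    return model, history, l1
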