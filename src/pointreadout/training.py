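"""Fitting the feature head(s) and point readouts by Poisson + L1 regression.

The objective is the summed Poisson deviance term across neurons and batch
elements plus an L1 penalty on the readout weights:

    L = sum_{i,n} ( rhat_n(x_i) - r_n(x_i) * log rhat_n(x_i) )
        + lambda * sum_{n,k} |w_{nk}|

Only the head parameters (gamma, beta) and the per-neuron readout parameters
(mu, sigma^2, w, b) are trainable; the cores are frozen, so backpropagation
never has to traverse a convolution.  All gradients are derived analytically
and computed in NumPy:

* The loss reaches the feature tensor only through the 4 bilinear-interpolation
  corner pixels of each neuron's location, so head gradients are sparse
  gather-reductions.
* Position gradients follow from the closed-form derivative of bilinear
  interpolation with respect to the fractional coordinates; sampled positions
  clamped to the map edge receive zero gradient.
* sigma^2 is trained through its softplus reparameterization via the usual
  reparameterized-sampling trick (position = mu + sqrt(sigma^2) * eps).

Optimization uses Adam with the schedule: initial learning rate 3e-4, decay
by 0.3 whenever validation loss fails to improve for 5 consecutive epochs
(restoring the best weights first), stopping after 4 decay events.  Training
batches cycle through all sessions, accumulating gradients across the cycle
into a single parameter update; an epoch ends when the longest session's
sample pool is exhausted, shorter sessions restarting from their full pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._math import elu_grad, elu_plus_one
from .model import EncodingModel
from .readout import _grid_coords, sigma2_grad_factor

DEFAULT_GUARD = 1e-8  # epsilon inside log() guarding against underflow of ELU+1


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def poisson_loss(rates: np.ndarray, counts: np.ndarray,
                 guard: float = DEFAULT_GUARD) -> float:
    """Summed Poisson term  sum( rhat - r * log(rhat + guard) )."""
    rates = np.asarray(rates, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("predicted rates must be strictly positive")
    return float(np.sum(rates - counts * np.log(rates + guard)))


def objective(rates: np.ndarray, counts: np.ndarray, weights: np.ndarray,
              l1: float, guard: float = DEFAULT_GUARD) -> float:
    """Full training objective: Poisson term plus L1 penalty on the weights."""
    return poisson_loss(rates, counts, guard) + float(l1) * float(np.abs(weights).sum())


# ---------------------------------------------------------------------------
# Analytic gradients for one batch
# ---------------------------------------------------------------------------

def batch_loss_and_grads(model: EncodingModel, raws: list[np.ndarray],
                         counts: np.ndarray, neuron_slice: slice | None = None,
                         train: bool = True,
                         rng: np.random.Generator | None = None,
                         positions: np.ndarray | None = None,
                         guard: float = DEFAULT_GUARD):
    """Poisson loss and analytic gradients for one image batch.

    Parameters
    ----------
    raws
        Precomputed frozen-core feature maps for the batch, one per core.
    counts
        (batch, n_sub) observed spike counts for the neurons in
        ``neuron_slice`` (all neurons if None).
    train
        Train mode: batch normalization statistics, sampled readout
        positions (requires ``rng``), running-statistic updates.  Eval mode:
        frozen statistics, positions at mu — used by the finite-difference
        gradient checks.
    positions
        Override the readout locations (used by tests); disables the
        sigma^2 gradient.

    Returns
    -------
    loss, grads
        ``grads`` maps parameter names (as in ``model.parameters()``) to
        arrays of matching shape; entries outside ``neuron_slice`` are zero.
        The L1 term is *not* included here — it is added once per
        multi-session cycle.
    """
    ro = model.readout
    s = neuron_slice if neuron_slice is not None else slice(0, ro.n_neurons)
    counts = np.asarray(counts, dtype=float)

    phi, caches = model.concat_phi(raws, train=train)
    B, C, H, W = phi.shape

    mu = ro.mu[s]
    w = ro.weights[s]
    b = ro.bias[s]
    n_sub = mu.shape[0]
    if counts.shape != (B, n_sub):
        raise ValueError(f"counts shape {counts.shape} != {(B, n_sub)}")

    eps_noise = None
    if positions is not None:
        raw_pos = np.asarray(positions, dtype=float)
        if raw_pos.ndim == 2:
            raw_pos = np.broadcast_to(raw_pos, (B, n_sub, 2))
    elif train:
        if rng is None:
            raise ValueError("train mode requires an rng for position sampling")
        # one independent draw per neuron AND batch element: averaging B
        # reparameterized samples per step keeps the position gradient usable
        eps_noise = rng.standard_normal((B, n_sub, 2))
        std = np.sqrt(np.asarray(ro.sigma2)[s])[None, :, None]
        raw_pos = mu[None] + std * eps_noise
    else:
        raw_pos = np.broadcast_to(mu, (B, n_sub, 2))
    # gradient does not flow through the clamp: clamped coordinates get zero
    inside = (raw_pos > -1.0) & (raw_pos < 1.0)
    pos = np.clip(raw_pos, -1.0, 1.0)

    flat = pos.reshape(-1, 2)
    ix0, ix1, iy0, iy1, fx, fy = _grid_coords(flat, H, W)
    ix0, ix1, iy0, iy1, fx, fy = (a.reshape(B, n_sub)
                                  for a in (ix0, ix1, iy0, iy1, fx, fy))
    iy = np.stack([iy0, iy0, iy1, iy1])          # (4, B, n)
    ix = np.stack([ix0, ix1, ix0, ix1])
    wx0, wx1 = 1.0 - fx, fx                      # (B, n)
    wy0, wy1 = 1.0 - fy, fy
    alpha = np.stack([wy0 * wx0, wy0 * wx1, wy1 * wx0, wy1 * wx1])  # (4, B, n)

    # gather pre-rectification values at the interpolation corners per block;
    # corner indices vary per batch element, so gather through flat HW indices
    idx_flat = (iy * W + ix).transpose(1, 0, 2).reshape(B, 4 * n_sub)
    y_corners, xhat_corners = [], []
    for blk, cache in zip(model.block_slices, caches):
        ci = cache["y"].shape[1]
        yb = np.take_along_axis(cache["y"].reshape(B, ci, H * W),
                                idx_flat[:, None, :], axis=2)
        xb = np.take_along_axis(cache["xhat"].reshape(B, ci, H * W),
                                idx_flat[:, None, :], axis=2)
        y_corners.append(yb.reshape(B, ci, 4, n_sub))
        xhat_corners.append(xb.reshape(B, ci, 4, n_sub))
    Y = np.concatenate(y_corners, axis=1)                # (B, C, 4, n)
    V = np.maximum(Y, 0.0)

    phi_at = np.einsum("bckn,kbn->bnc", V, alpha, optimize=True)
    z = np.einsum("bnc,nc->bn", phi_at, w, optimize=True) + b
    rhat = elu_plus_one(z)
    loss = float(np.sum(rhat - counts * np.log(rhat + guard)))

    # ---- backward ----
    g_rhat = 1.0 - counts / (rhat + guard)
    g_z = g_rhat * elu_grad(z)                           # (B, n)
    g_bias = g_z.sum(axis=0)
    g_weights = np.einsum("bn,bnc->nc", g_z, phi_at, optimize=True)
    g_phi_at = np.einsum("bn,nc->bnc", g_z, w, optimize=True)

    Vt = np.transpose(V, (0, 3, 1, 2))                   # (B, n, C, 4)
    dphi_dfx = (wy0[:, :, None] * (Vt[..., 1] - Vt[..., 0])
                + wy1[:, :, None] * (Vt[..., 3] - Vt[..., 2]))
    dphi_dfy = (wx0[:, :, None] * (Vt[..., 2] - Vt[..., 0])
                + wx1[:, :, None] * (Vt[..., 3] - Vt[..., 1]))
    g_x = np.einsum("bnc,bnc->bn", g_phi_at, dphi_dfx, optimize=True) * (W - 1) / 2.0
    g_y = np.einsum("bnc,bnc->bn", g_phi_at, dphi_dfy, optimize=True) * (H - 1) / 2.0
    g_pos = np.stack([g_x, g_y], axis=2) * inside        # (B, n, 2)

    grads = {}
    g_mu_full = np.zeros_like(ro.mu)
    g_sig_full = np.zeros_like(ro.sigma_raw)
    g_w_full = np.zeros_like(ro.weights)
    g_b_full = np.zeros_like(ro.bias)
    g_mu_full[s] = g_pos.sum(axis=0)
    if eps_noise is not None:
        g_sig_full[s] = np.sum(g_pos * eps_noise, axis=(0, 2)) * sigma2_grad_factor(ro)[s]
    g_w_full[s] = g_weights
    g_b_full[s] = g_bias
    grads.update(mu=g_mu_full, sigma_raw=g_sig_full,
                 weights=g_w_full, bias=g_b_full)

    # head gradients: sparse reduction over the corner pixels only
    g_corner = g_phi_at[:, :, :, None] * alpha.transpose(1, 2, 0)[:, :, None, :]
    for i, blk in enumerate(model.block_slices):
        Yb = np.transpose(y_corners[i], (0, 3, 1, 2))    # (B, n, Ci, 4)
        Xb = np.transpose(xhat_corners[i], (0, 3, 1, 2))
        gy = g_corner[:, :, blk, :] * (Yb > 0)
        grads[f"gamma_{i}"] = np.einsum("bnck,bnck->c", gy, Xb, optimize=True)
        grads[f"beta_{i}"] = np.einsum("bnck->c", gy, optimize=True)
    return loss, grads


def correlation_position_init(model: EncodingModel, sessions,
                              raws_per_session=None, slices=None) -> np.ndarray:
    """Initialize readout positions from a correlation receptive-field map.

    For every neuron, correlates its single-trial train counts with each
    feature channel at each grid location (eval-mode features) and places
    mu_n at the location maximizing the sum of squared correlations across
    channels.  This lands each position inside the attraction basin of the
    gradient-based refinement, which matters at desk scale where training
    runs are far shorter than in large-data regimes.  Mutates ``model`` and
    returns the (n_neurons, 2) initial positions.
    """
    if slices is None:
        slices = neuron_slices(sessions)
    mu = model.readout.mu
    for i, (sess, s) in enumerate(zip(sessions, slices)):
        raws = (raws_per_session[i] if raws_per_session is not None
                else model.raw_features(sess.train_images))
        phi, _ = model.concat_phi(raws, train=False)
        n_img, c, h, w = phi.shape
        x = phi.reshape(n_img, -1)
        x = x - x.mean(axis=0)
        xs = x / (np.linalg.norm(x, axis=0) + 1e-12)
        r = sess.train_counts - sess.train_counts.mean(axis=0)
        rs = r / (np.linalg.norm(r, axis=0) + 1e-12)
        corr = xs.T @ rs                                  # (c*h*w, n_sub)
        score = (corr.reshape(c, h * w, -1) ** 2).sum(axis=0)  # (h*w, n_sub)
        best = np.argmax(score, axis=0)
        by, bx = np.divmod(best, w)
        mu[s, 0] = 2.0 * bx / max(w - 1, 1) - 1.0
        mu[s, 1] = 2.0 * by / max(h - 1, 1) - 1.0
    return mu.copy()


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Plain Adam with per-parameter masks for frozen entries.

    beta1 defaults to 0.1 (the training schedule's momentum setting);
    configurable.
    """

    def __init__(self, lr: float = 3e-4, beta1: float = 0.1,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             masks: dict[str, np.ndarray] | None = None) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in params.items():
            g = grads.get(key)
            if g is None:
                continue
            if key not in self._m:
                self._m[key] = np.zeros_like(p)
                self._v[key] = np.zeros_like(p)
            m = self._m[key]
            v = self._v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if masks is not None and key in masks:
                update = update * masks[key]
            p -= update


# ---------------------------------------------------------------------------
# Schedule, history, early stopping
# ---------------------------------------------------------------------------

@dataclass
class TrainSchedule:
    """Optimization hyperparameters.

    Defaults follow the study schedule: Adam at 3e-4, decay factor 0.3,
    plateau patience 5 epochs, 4 early-stopping (decay) events.  Batch size
    is per session and per cycle.
    """

    learning_rate: float = 3e-4
    decay_factor: float = 0.3
    patience: int = 5
    max_decay_events: int = 4
    batch_size: int = 64
    l1: float = 1.0
    beta1: float = 0.1
    beta2: float = 0.999
    seed: int = 0
    max_epochs: int = 500
    guard: float = DEFAULT_GUARD
    #: "correlation" places initial readout positions at the peak of each
    #: neuron's correlation receptive-field map; "none" keeps the model's
    #: current positions (used by warm-started joint readouts)
    position_init: str = "correlation"


@dataclass
class FitHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    decay_epochs: list = field(default_factory=list)
    best_epoch: int = -1

    def as_dict(self) -> dict:
        return {
            "train_loss": self.train_loss, "val_loss": self.val_loss,
            "learning_rate": self.learning_rate, "decay_epochs": self.decay_epochs,
            "best_epoch": [self.best_epoch],
        }


class EarlyStopping:
    """Plateau detector driving weight restoration and learning-rate decay.

    ``update`` returns one of:

    - ``"improved"`` — new best validation loss; caller should snapshot weights.
    - ``"wait"`` — no improvement, patience not yet exhausted.
    - ``"decay"`` — patience exhausted: caller restores the best weights and
      multiplies the learning rate by the decay factor.
    - ``"stop"`` — the configured number of decay events is complete: caller
      restores the best weights and stops.
    """

    def __init__(self, patience: int = 5, max_events: int = 4):
        self.patience = patience
        self.max_events = max_events
        self.best = math.inf
        self.since_improvement = 0
        self.events = 0

    def update(self, val_loss: float) -> str:
        if val_loss < self.best:
            self.best = val_loss
            self.since_improvement = 0
            return "improved"
        self.since_improvement += 1
        if self.since_improvement >= self.patience:
            self.events += 1
            self.since_improvement = 0
            return "stop" if self.events >= self.max_events else "decay"
        return "wait"


# ---------------------------------------------------------------------------
# Multi-session sampling
# ---------------------------------------------------------------------------

class _SessionPool:
    """Without-replacement batch sampler over one session's train images."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch_size = batch_size
        self.rng = rng
        self._order = rng.permutation(n)
        self._cursor = 0

    def draw(self) -> np.ndarray:
        if self._cursor >= self.n:
            self._order = self.rng.permutation(self.n)
            self._cursor = 0
        take = min(self.batch_size, self.n - self._cursor)
        idx = self._order[self._cursor:self._cursor + take]
        self._cursor += take
        return idx

    @property
    def exhausted(self) -> bool:
        return self._cursor >= self.n


def multi_session_step(model: EncodingModel, session_batches, l1: float,
                       optimizer: Adam, masks=None,
                       rng: np.random.Generator | None = None,
                       guard: float = DEFAULT_GUARD) -> float:
    """One gradient cycle: a batch from each session, one parameter update.

    ``session_batches`` yields ``(raws, counts, neuron_slice)`` triples, one
    per session.  Poisson gradients are summed over the cycle, the L1 term
    (weights only, bias excluded) is added once, and a single Adam update is
    applied.  Returns the accumulated objective value.
    """
    total: dict[str, np.ndarray] = {}
    loss = 0.0
    n_batches = 0
    for raws, counts, nslice in session_batches:
        l, grads = batch_loss_and_grads(model, raws, counts, neuron_slice=nslice,
                                        train=True, rng=rng, guard=guard)
        loss += l
        n_batches += 1
        for k, g in grads.items():
            if k in total:
                total[k] += g
            else:
                total[k] = g
    if n_batches == 0:
        raise RuntimeError("multi_session_step needs at least one session batch")
    w = model.readout.weights
    loss += l1 * float(np.abs(w).sum())
    total["weights"] = total["weights"] + l1 * np.sign(w)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss; aborting")
    optimizer.step(model.parameters(), total, masks)
    return loss


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------

def neuron_slices(sessions) -> list[slice]:
    """Contiguous global-neuron index ranges, one per session, in order."""
    out, start = [], 0
    for sess in sessions:
        n = sess.train_counts.shape[1]
        out.append(slice(start, start + n))
        start += n
    return out


def validation_loss(model: EncodingModel, sessions, raws_val: list,
                    slices: list[slice], guard: float = DEFAULT_GUARD) -> float:
    """Eval-mode Poisson loss per validation trial (L1 excluded).

    Sum over neurons, mean over single-trial validation images, averaged
    across sessions weighted by their image counts.
    """
    total = 0.0
    n_images = 0
    for sess, raws, s in zip(sessions, raws_val, slices):
        rates = model.predict(raws=raws, train=False)[:, s]
        total += poisson_loss(rates, sess.validation_counts, guard)
        n_images += sess.validation_counts.shape[0]
    return total / n_images


def fit(model: EncodingModel, sessions, schedule: TrainSchedule | None = None,
        masks=None, verbose: bool = False):
    """Fit head(s) and readouts on multi-session data with early stopping.

    Parameters
    ----------
    model
        An :class:`EncodingModel` whose neuron count equals the total across
        ``sessions`` (session neuron blocks stacked in order).
    sessions
        Sequence of objects with ``train_images``, ``train_counts``,
        ``validation_images``, ``validation_counts``.
    masks
        Optional parameter-name -> multiplicative mask dict declaring frozen
        entries (used by warm-start strategies).

    Returns
    -------
    (model, FitHistory)
        The model carries the best-validation-loss weights on return.
    """
    if schedule is None:
        schedule = TrainSchedule()
    slices = neuron_slices(sessions)
    if slices[-1].stop != model.n_neurons:
        raise ValueError(
            f"model has {model.n_neurons} neurons, sessions provide {slices[-1].stop}"
        )
    rng = np.random.default_rng(schedule.seed)

    core_fp_before = model.core_fingerprint()
    raws_train = [model.raw_features(s.train_images) for s in sessions]
    raws_val = [model.raw_features(s.validation_images) for s in sessions]
    if schedule.position_init == "correlation":
        correlation_position_init(model, sessions, raws_train, slices)
    elif schedule.position_init != "none":
        raise ValueError(f"unknown position_init {schedule.position_init!r}")

    optimizer = Adam(lr=schedule.learning_rate, beta1=schedule.beta1,
                     beta2=schedule.beta2)
    stopper = EarlyStopping(schedule.patience, schedule.max_decay_events)
    history = FitHistory()
    longest = int(np.argmax([s.train_counts.shape[0] for s in sessions]))
    best_state = model.get_state()
    best_epoch = 0

    for epoch in range(schedule.max_epochs):
        # fresh pools each epoch; shorter sessions refill (are resampled)
        # inside the epoch whenever they run out before the longest one
        pools = [_SessionPool(s.train_counts.shape[0], schedule.batch_size, rng)
                 for s in sessions]
        epoch_loss = 0.0
        n_cycles = 0
        while True:
            batches = []
            for sess, pool, raws, nslice in zip(sessions, pools, raws_train, slices):
                idx = pool.draw()
                batches.append(([r[idx] for r in raws],
                                sess.train_counts[idx], nslice))
            epoch_loss += multi_session_step(model, batches, schedule.l1,
                                             optimizer, masks, rng, schedule.guard)
            n_cycles += 1
            if pools[longest].exhausted:
                break
        val = validation_loss(model, sessions, raws_val, slices, schedule.guard)
        history.train_loss.append(epoch_loss / n_cycles)
        history.val_loss.append(val)
        history.learning_rate.append(optimizer.lr)
        action = stopper.update(val)
        if action == "improved":
            best_state = model.get_state()
            best_epoch = epoch
        elif action in ("decay", "stop"):
            model.set_state(best_state)
            optimizer.lr *= schedule.decay_factor
            history.decay_epochs.append(epoch)
            if action == "stop":
                break
        if verbose:
            print(f"epoch {epoch}: train {epoch_loss / n_cycles:.4f} "
                  f"val {val:.4f} lr {optimizer.lr:.2e} [{action}]")

    model.set_state(best_state)
    history.best_epoch = best_epoch
    assert model.core_fingerprint() == core_fp_before, "frozen core mutated"
    return model, history
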