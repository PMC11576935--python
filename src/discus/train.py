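"""Training loop: augmentations, λ-weighted loss, LR schedule, early stopping.

Two augmentations are applied independently per training sample:

* a fresh rotation drawn uniformly from SO(3), applied jointly to observation
  and query vectors (the reconstruction depends only on relative geometry);
* a random observation subset of size Uniform{min_obs, …, K}, encoded as a
  binary mask applied inside every pooling operation; the remaining vectors
  are supervised as queries.

Because the signal is normalized, s(q ≡ 0) = 1, so a synthetic b0 query with
target 1 is appended to every sample.  The loss splits squared residuals into
the observation partition O and the query-only partition Q \\ O:

    L = (1 - λ) · mean_{s ∈ O}(ŝ - s)² + λ · mean_{s ∈ Q\\O}(ŝ - s)²

The per-partition *means* (rather than sums) keep λ's meaning independent of
the randomly drawn subset sizes.  Validation loss is the query-only term
(λ = 1) on a fixed, pre-drawn augmentation, so model selection targets
generalization to unseen q-vectors.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .network import DiscusNet, NetworkConfig
from .qspace import AcquisitionScheme, sample_uniform_rotation

__all__ = [
    "LossConfig",
    "TrainingConfig",
    "TrainingBatch",
    "make_training_batch",
    "discus_loss",
    "LRScheduler",
    "lr_schedule_step",
    "early_stopping_check",
    "train",
]


@dataclasses.dataclass
class LossConfig:
    """λ weighs query-only against observation reconstruction error."""

    lambda_weight: float = 0.4
    include_b0_query: bool = True

    def __post_init__(self):
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")


@dataclasses.dataclass
class TrainingConfig:
    """Optimization hyper-parameters.

    The learning rate is multiplied by 0.1 whenever the validation loss has
    plateaued for ``plateau_epochs``; early stopping triggers after
    ``min_epochs`` once the validation loss has not improved for
    ``early_stop_patience`` successive epochs.  The default optimizer is Adam
    at 1e-3: at desk-scale step counts it fits this architecture where
    momentum-SGD stalls at the voxel-independent predictor.  The published
    schedule (momentum-SGD 0.9, initial rate 0.01) is available via
    ``optimizer="sgd", initial_lr=0.01``.
    """

    initial_lr: float = 1e-3
    lr_factor: float = 0.1
    plateau_epochs: int = 20
    min_epochs: int = 40
    early_stop_patience: int = 40
    max_epochs: int = 200
    batch_size: int = 4096
    min_obs: int = 5
    optimizer: str = "adam"  # "adam" or "sgd" (momentum-SGD)
    momentum: float = 0.9
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    validation_fraction: float = 0.1
    per_batch_subsampling: bool = False  # ablation: one shared mask per batch
    rotation_augmentation: bool = True
    seed: int = 0
    plateau_rel_tol: float = 1e-4

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.min_obs < 5:
            raise ValueError("min_obs must be at least 5")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclasses.dataclass
class TrainingBatch:
    """Padded per-voxel training arrays.

    Path layout: the K diffusion-weighted scheme vectors followed by one
    q ≡ 0 slot (target 1).  ``obs_mask`` marks encoder inputs, ``query_mask``
    the query-only (withheld) paths; the two are disjoint per item.
    """

    qvectors: np.ndarray  # (B, P, 3), jointly rotated per item
    signals: np.ndarray  # (B, P) targets
    obs_mask: np.ndarray  # (B, P) bool
    query_mask: np.ndarray  # (B, P) bool

    def __post_init__(self):
        if np.any(self.obs_mask & self.query_mask):
            raise ValueError("observation and query masks must be disjoint")


def make_training_batch(
    qvectors: np.ndarray,
    signals: np.ndarray,
    config: TrainingConfig,
    rng: np.random.Generator,
    loss_config: LossConfig | None = None,
) -> TrainingBatch:
    """Assemble one augmented batch.

    ``qvectors`` (K, 3) are the scheme's diffusion-weighted vectors and
    ``signals`` (B, K) the corresponding normalized voxel signals.  Each item
    receives its own uniform rotation and observation subset (one shared
    subset per batch in the per-batch ablation mode).
    """
    loss_config = loss_config or LossConfig()
    q = np.asarray(qvectors, dtype=np.float32)
    s = np.asarray(signals, dtype=np.float32)
    K = q.shape[0]
    if K < config.min_obs + 1:
        raise ValueError(f"scheme has only {K} vectors; need at least {config.min_obs + 1}")
    B = s.shape[0]
    P = K + 1 if loss_config.include_b0_query else K

    if config.rotation_augmentation:
        rots = np.stack([sample_uniform_rotation(rng) for _ in range(B)]).astype(np.float32)
        q_rot = np.einsum("bij,kj->bki", rots, q)
    else:
        q_rot = np.broadcast_to(q, (B, K, 3)).copy()

    obs_mask = np.zeros((B, P), dtype=bool)
    if config.per_batch_subsampling:
        n = int(rng.integers(config.min_obs, K + 1))
        keep = rng.choice(K, size=n, replace=False)
        obs_mask[:, keep] = True
    else:
        sizes = rng.integers(config.min_obs, K + 1, size=B)
        scores = rng.random((B, K))
        ranks = np.argsort(scores, axis=1)
        for b in range(B):
            obs_mask[b, ranks[b, : sizes[b]]] = True

    qv = np.zeros((B, P, 3), dtype=np.float32)
    qv[:, :K] = q_rot
    targets = np.zeros((B, P), dtype=np.float32)
    targets[:, :K] = s
    query_mask = ~obs_mask
    if loss_config.include_b0_query:
        targets[:, K] = 1.0
        query_mask[:, K] = True
        obs_mask[:, K] = False
    return TrainingBatch(qv, targets, obs_mask, query_mask)


def discus_loss(predictions, targets, obs_mask, query_mask, lambda_weight: float):
    """λ-weighted mean squared error over the two signal partitions.

    Returns ``(loss, grad)`` where ``grad`` is d(loss)/d(predictions), ready
    for the network's backward pass.
    """
    preds = np.asarray(predictions)
    t = np.asarray(targets)
    om = np.asarray(obs_mask, dtype=bool)
    qm = np.asarray(query_mask, dtype=bool)
    if np.any(om & qm):
        raise ValueError("observation and query masks must be disjoint")
    n_obs = int(om.sum())
    n_query = int(qm.sum())
    if n_obs + n_query == 0:
        raise ValueError("both loss partitions are empty")
    resid = preds - t
    loss = 0.0
    grad = np.zeros_like(resid)
    if n_obs and lambda_weight < 1.0:
        loss += (1.0 - lambda_weight) * float(np.mean(resid[om] ** 2))
        grad[om] += (1.0 - lambda_weight) * 2.0 * resid[om] / n_obs
    if n_query and lambda_weight > 0.0:
        loss += lambda_weight * float(np.mean(resid[qm] ** 2))
        grad[qm] += lambda_weight * 2.0 * resid[qm] / n_query
    return loss, grad


@dataclasses.dataclass
class LRScheduler:
    """Reduce-on-plateau state: lr ← lr × factor after ``plateau_epochs``
    epochs without a relative validation improvement of ``rel_tol``."""

    lr: float
    factor: float = 0.1
    plateau_epochs: int = 20
    rel_tol: float = 1e-4
    best: float = np.inf
    stale: int = 0

    def step(self, validation_loss: float) -> "LRScheduler":
        if validation_loss < self.best * (1.0 - self.rel_tol) or not np.isfinite(self.best):
            self.best = validation_loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.plateau_epochs:
                self.lr *= self.factor
                self.stale = 0
        return self


def lr_schedule_step(state: LRScheduler, validation_loss: float) -> LRScheduler:
    """Functional wrapper around :meth:`LRScheduler.step`."""
    return state.step(validation_loss)


@dataclasses.dataclass
class EarlyStopState:
    epoch: int = 0
    best: float = np.inf
    stale: int = 0

    def update(self, validation_loss: float, rel_tol: float = 1e-4) -> "EarlyStopState":
        self.epoch += 1
        if validation_loss < self.best * (1.0 - rel_tol) or not np.isfinite(self.best):
            self.best = validation_loss
            self.stale = 0
        else:
            self.stale += 1
        return self


def early_stopping_check(state: EarlyStopState, min_epochs: int = 40, patience: int = 40) -> bool:
    """True once ``min_epochs`` have run and the validation error has not
    improved for ``patience`` successive epochs."""
    return state.epoch >= min_epochs and state.stale >= patience


def train(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    net_config: NetworkConfig | None = None,
    train_config: TrainingConfig | None = None,
    loss_config: LossConfig | None = None,
    net: DiscusNet | None = None,
    verbose: bool = False,
):
    """Train a :class:`DiscusNet` on per-voxel signal rows.

    ``signals`` is (V, K) **normalized** voxel signals on ``scheme``; b0
    columns are dropped internally (the q ≡ 0 target is supplied by the loss).
    Deterministic for a fixed ``train_config.seed``.  Returns ``(net,
    history)`` with a per-epoch DataFrame of losses and learning rate; the
    network carries the best-validation parameters seen.
    """
    net_config = net_config or NetworkConfig()
    tc = train_config or TrainingConfig()
    lc = loss_config or LossConfig()
    rng = np.random.default_rng(tc.seed)
    if net is None:
        net = DiscusNet(net_config, seed=int(rng.integers(2**31)))

    dwi = scheme.dwi_indices
    q = scheme.qvectors[dwi].astype(np.float32)
    s = np.asarray(signals, dtype=np.float32)[:, dwi]
    V = s.shape[0]
    n_val = max(1, int(round(tc.validation_fraction * V)))
    perm = rng.permutation(V)
    val_rows, train_rows = perm[:n_val], perm[n_val:]
    if len(train_rows) == 0:
        raise ValueError("no training voxels left after the validation split")

    # fixed validation batch: frozen augmentation so epochs are comparable
    val_rng = np.random.default_rng(int(rng.integers(2**31)))
    val_batch = make_training_batch(q, s[val_rows], tc, val_rng, lc)

    velocity = {k: np.zeros_like(v) for k, v in net.params.items()}
    adam_m = {k: np.zeros_like(v) for k, v in net.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in net.params.items()}
    adam_t = 0
    sched = LRScheduler(
        lr=tc.initial_lr,
        factor=tc.lr_factor,
        plateau_epochs=tc.plateau_epochs,
        rel_tol=tc.plateau_rel_tol,
    )
    stopper = EarlyStopState()
    history = []
    best_val = np.inf
    best_params = {k: v.copy() for k, v in net.params.items()}
    best_state = {k: v.copy() for k, v in net.state.items()}

    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(train_rows))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), tc.batch_size):
            rows = train_rows[order[start : start + tc.batch_size]]
            batch = make_training_batch(q, s[rows], tc, rng, lc)
            preds, cache = net.forward_paths(
                batch.qvectors, batch.signals, batch.obs_mask, training=True
            )
            loss, grad = discus_loss(
                preds, batch.signals, batch.obs_mask, batch.query_mask, lc.lambda_weight
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r}; "
                    "reduce the learning rate or check input scaling"
                )
            grads = net.backward_paths(grad, cache)
            if tc.optimizer == "adam":
                adam_t += 1
                b1, b2 = tc.adam_betas
                bc1 = 1.0 - b1**adam_t
                bc2 = 1.0 - b2**adam_t
                for k, g in grads.items():
                    g = g.astype(adam_m[k].dtype)
                    m, v = adam_m[k], adam_v[k]
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    net.params[k] -= sched.lr * (m / bc1) / (
                        np.sqrt(v / bc2) + tc.adam_eps
                    )
            else:
                for k, g in grads.items():
                    v = velocity[k]
                    v *= tc.momentum
                    v -= sched.lr * g.astype(v.dtype)
                    net.params[k] += v
            epoch_loss += loss
            n_batches += 1

        # validation: query-only error on the frozen batch, inference-mode BN
        val_preds = net.forward_paths(
            val_batch.qvectors, val_batch.signals, val_batch.obs_mask, training=False
        )
        val_loss, _ = discus_loss(
            val_preds, val_batch.signals, val_batch.obs_mask, val_batch.query_mask, 1.0
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in net.params.items()}
            best_state = {k: v.copy() for k, v in net.state.items()}
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": val_loss,
                "lr": sched.lr,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  train {history[-1]['train_loss']:.5f}  "
                f"val {val_loss:.5f}  lr {sched.lr:.2e}"
            )
        sched.step(val_loss)
        stopper.update(val_loss, tc.plateau_rel_tol)
        if early_stopping_check(stopper, tc.min_epochs, tc.early_stop_patience):
            break

    net.params = best_params
    net.state = best_state
    return net, pd.DataFrame(history)
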