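"""Set encoder / conditional decoder for continuous q-space signal reconstruction.

The model maps an arbitrary-length observation set ``x_obs = {(q_i, s_i)}`` to
a latent code ``z`` (encoder) and predicts the signal at arbitrary query
q-vectors conditioned on ``z`` (decoder):

    ŝ = D(q | E(x_obs)).

Architectural invariances, by construction rather than by training:

* **Sign invariance** — both encoder and decoder start with a shared
  sign-invariance module ``SI(q) = MLP(q) + MLP(-q)``, so ``SI(q) = SI(-q)``
  bit-exactly (IEEE addition is commutative).
* **Permutation invariance** — observations are processed along independent
  per-path MLPs ("transform" modules) and merged only through masked
  max-pooling; the pooled "global" features are concatenated back onto every
  path by "assembly" modules.  The encoder's single output is the latent code.
* **Flexible cardinality** — one processing path is allocated per observation
  or query vector, so any N ≥ 5 observations and any M ≥ 1 queries are
  accepted without re-instantiation.

Transform-MLP layers are linear → batch-normalization → tanh; sign-invariance
and decoder layers are linear → ReLU, except the decoder's final layer, which
is purely linear.  Batch-normalization statistics pool over (batch × active
paths) — a permutation-invariant set — with running statistics used at
inference, so inference-mode outputs are exactly permutation invariant.

The whole model is implemented in NumPy with hand-written backward passes;
the architecture is small and static, so explicit reverse-mode code stays
simple and keeps the package free of deep-learning framework dependencies.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

__all__ = [
    "NetworkConfig",
    "DiscusNet",
    "masked_max_pool",
    "assembly_concat",
    "count_parameters",
]


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    Defaults follow the published design: width 128, latent dimension 16,
    sign-invariance MLP with 3 hidden + 1 output layers, transform and decoder
    MLPs with 2 hidden + 1 output layers.  ``encoder_stages`` (transform/pool
    stages with interleaved assemblies) defaults to 2, which places the total
    trainable parameter count (186,385) within the ~170k budget of the
    reference implementation; batch normalization is affine-free by default
    (see ``count_parameters``).
    """

    width: int = 128
    latent_dim: int = 16
    si_hidden_layers: int = 3
    transform_hidden_layers: int = 2
    decoder_hidden_layers: int = 2
    encoder_stages: int = 2
    norm_affine: bool = False
    min_observations: int = 5

    def __post_init__(self):
        if self.width < 1 or self.latent_dim < 1:
            raise ValueError("width and latent_dim must be positive")
        if self.encoder_stages < 1:
            raise ValueError("need at least one encoder stage")

    # -- layer width tables ------------------------------------------------
    def si_widths(self) -> list[tuple[int, int]]:
        w = self.width
        dims = [3] + [w] * (self.si_hidden_layers + 1)
        return list(zip(dims[:-1], dims[1:]))

    def stage_widths(self, stage: int) -> list[tuple[int, int]]:
        w = self.width
        n_in = w + 1 if stage == 0 else 2 * w
        n_out = self.latent_dim if stage == self.encoder_stages - 1 else w
        dims = [n_in] + [w] * self.transform_hidden_layers + [n_out]
        return list(zip(dims[:-1], dims[1:]))

    def decoder_widths(self) -> list[tuple[int, int]]:
        w = self.width
        dims = [w + self.latent_dim] + [w] * self.decoder_hidden_layers + [1]
        return list(zip(dims[:-1], dims[1:]))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


def count_parameters(config: NetworkConfig) -> int:
    """Exact count of trainable scalars (weights, biases, and batch-norm
    affine parameters when enabled)."""
    total = 0
    for fan_in, fan_out in config.si_widths():
        total += fan_in * fan_out + fan_out
    for stage in range(config.encoder_stages):
        for fan_in, fan_out in config.stage_widths(stage):
            total += fan_in * fan_out + fan_out
            if config.norm_affine:
                total += 2 * fan_out
    for fan_in, fan_out in config.decoder_widths():
        total += fan_in * fan_out + fan_out
    return total


# ---------------------------------------------------------------------------
# Stateless building blocks
# ---------------------------------------------------------------------------

def masked_max_pool(features: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-feature maximum over active paths only.

    ``features`` is (batch, N, F) and ``mask`` (batch, N) boolean.  Inactive
    paths are replaced by ``-inf`` before the maximum, so no finite feature
    value of a masked path can ever be selected.
    """
    features = np.asarray(features)
    mask = np.asarray(mask, dtype=bool)
    if features.shape[:2] != mask.shape:
        raise ValueError("mask shape must match the first two feature axes")
    if not np.all(mask.any(axis=1)):
        raise ValueError("every item needs at least one active path")
    sentinel = np.where(mask[..., None], features, -np.inf)
    return sentinel.max(axis=1)


def assembly_concat(per_path: np.ndarray, global_features: np.ndarray) -> np.ndarray:
    """Broadcast pooled global features onto every path and concatenate."""
    per_path = np.asarray(per_path)
    global_features = np.asarray(global_features)
    if per_path.shape[0] != global_features.shape[0]:
        raise ValueError("batch dimensions must match")
    tiled = np.broadcast_to(
        global_features[:, None, :], per_path.shape[:2] + global_features.shape[1:]
    )
    return np.concatenate([per_path, tiled], axis=-1)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


def _relu(x):
    return np.maximum(x, 0)


class DiscusNet:
    """Encoder/decoder with explicit parameters and hand-written backprop.

    Parameters are stored in ``self.params`` (name → array); batch-norm
    running statistics in ``self.state``.  ``dtype`` defaults to float32;
    float64 is useful for gradient checking.
    """

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0, dtype=np.float32):
        self.config = config or NetworkConfig()
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        for name, widths, has_bn in self._module_table():
            for i, (fan_in, fan_out) in enumerate(widths):
                bound = 1.0 / np.sqrt(fan_in)
                self.params[f"{name}.{i}.W"] = rng.uniform(
                    -bound, bound, (fan_in, fan_out)
                ).astype(self.dtype)
                self.params[f"{name}.{i}.b"] = rng.uniform(-bound, bound, fan_out).astype(
                    self.dtype
                )
                if has_bn:
                    if self.config.norm_affine:
                        self.params[f"{name}.{i}.gamma"] = np.ones(fan_out, self.dtype)
                        self.params[f"{name}.{i}.beta"] = np.zeros(fan_out, self.dtype)
                    self.state[f"{name}.{i}.mean"] = np.zeros(fan_out, self.dtype)
                    self.state[f"{name}.{i}.var"] = np.ones(fan_out, self.dtype)
        self.bn_momentum = 0.1
        self.bn_eps = 1e-5

    def _module_table(self):
        cfg = self.config
        table = [("si", cfg.si_widths(), False)]
        for t in range(cfg.encoder_stages):
            table.append((f"enc{t}", cfg.stage_widths(t), True))
        table.append(("dec", cfg.decoder_widths(), False))
        return table

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- primitive layers --------------------------------------------------

    def _dense(self, name, x, cache=None):
        W, b = self.params[f"{name}.W"], self.params[f"{name}.b"]
        y = x @ W
        y += b
        if cache is not None:
            cache[f"{name}.x"] = x
        return y

    def _dense_bwd(self, name, gy, cache, grads, need_input_grad=True):
        x = cache[f"{name}.x"]
        grads[f"{name}.W"] = grads.get(f"{name}.W", 0) + x.T @ gy
        grads[f"{name}.b"] = grads.get(f"{name}.b", 0) + gy.sum(axis=0)
        if not need_input_grad:
            return None
        return gy @ self.params[f"{name}.W"].T

    def _bn(self, name, x, training, cache=None):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            invstd = 1.0 / np.sqrt(var + self.bn_eps)
            xhat = x - mean
            xhat *= invstd
            m = self.bn_momentum
            self.state[f"{name}.mean"] = ((1 - m) * self.state[f"{name}.mean"] + m * mean).astype(
                self.dtype
            )
            self.state[f"{name}.var"] = ((1 - m) * self.state[f"{name}.var"] + m * var).astype(
                self.dtype
            )
        else:
            invstd = 1.0 / np.sqrt(self.state[f"{name}.var"] + self.bn_eps)
            xhat = x - self.state[f"{name}.mean"]
            xhat *= invstd
        if cache is not None:
            cache[f"{name}.xhat"] = xhat
            cache[f"{name}.invstd"] = invstd
        if self.config.norm_affine:
            return xhat * self.params[f"{name}.gamma"] + self.params[f"{name}.beta"]
        return xhat

    def _bn_bwd(self, name, gy, cache, grads):
        xhat, invstd = cache[f"{name}.xhat"], cache[f"{name}.invstd"]
        if self.config.norm_affine:
            grads[f"{name}.gamma"] = grads.get(f"{name}.gamma", 0) + (gy * xhat).sum(axis=0)
            grads[f"{name}.beta"] = grads.get(f"{name}.beta", 0) + gy.sum(axis=0)
            gy = gy * self.params[f"{name}.gamma"]
        return invstd * (gy - gy.mean(axis=0) - xhat * (gy * xhat).mean(axis=0))

    # -- sign-invariance module -------------------------------------------

    def sign_invariant_features(self, q: np.ndarray, training=False, cache=None) -> np.ndarray:
        """SI(q) = MLP(q) + MLP(-q); exactly symmetric under q → -q.

        ``q`` is (..., 3); returns (..., width).
        """
        q = np.asarray(q, dtype=self.dtype)
        shape = q.shape[:-1]
        flat = q.reshape(-1, 3)
        x = np.concatenate([flat, -flat], axis=0)
        n_layers = len(self.config.si_widths())
        for i in range(n_layers):
            x = self._dense(f"si.{i}", x, cache)
            x = np.maximum(x, 0, out=x)
            if cache is not None:
                cache[f"si.{i}.y"] = x
        n = flat.shape[0]
        out = x[:n] + x[n:]
        return out.reshape(*shape, self.config.width)

    def _si_bwd(self, g_out, cache, grads):
        g = np.concatenate([g_out, g_out], axis=0)
        for i in reversed(range(len(self.config.si_widths()))):
            g *= cache[f"si.{i}.y"] > 0
            g = self._dense_bwd(f"si.{i}", g, cache, grads, need_input_grad=i > 0)
        return None  # gradient w.r.t. q not needed

    # -- transform MLP (one stage) ----------------------------------------

    def transform_apply(self, stage: int, features: np.ndarray, training=False, cache=None):
        """Apply stage ``stage``'s MLP independently to each path.

        ``features`` is (paths, F_in); every layer is linear → batch-norm →
        tanh.  Batch-norm statistics are taken over all supplied paths.
        """
        x = np.asarray(features, dtype=self.dtype)
        widths = self.config.stage_widths(stage)
        if x.shape[-1] != widths[0][0]:
            raise ValueError(
                f"stage {stage} expects feature width {widths[0][0]}, got {x.shape[-1]}"
            )
        for i in range(len(widths)):
            name = f"enc{stage}.{i}"
            x = self._dense(name, x, cache)
            x = self._bn(name, x, training, cache)
            # not in-place: the cached pre-activation xhat is needed for backprop
            x = np.tanh(x)
            if cache is not None:
                cache[f"{name}.y"] = x
        return x

    def _transform_bwd(self, stage, g, cache, grads):
        for i in reversed(range(len(self.config.stage_widths(stage)))):
            name = f"enc{stage}.{i}"
            y = cache[f"{name}.y"]
            dtanh = 1.0 - y * y
            g = g * dtanh
            g = self._bn_bwd(name, g, cache, grads)
            g = self._dense_bwd(name, g, cache, grads)
        return g

    # -- full forward/backward over a padded batch -------------------------

    def forward_paths(
        self,
        qvectors: np.ndarray,
        signals: np.ndarray,
        obs_mask: np.ndarray,
        training: bool = False,
        want_cache: bool = False,
    ):
        """Predict signals at every path of a padded batch.

        ``qvectors`` (B, P, 3), ``signals`` (B, P), ``obs_mask`` (B, P): each
        item's active observation paths feed the encoder; the decoder predicts
        a signal at *every* path's q-vector.  Returns (B, P) predictions and,
        optionally, the cache required by :meth:`backward_paths`.
        """
        cfg = self.config
        q = np.asarray(qvectors, dtype=self.dtype)
        s = np.asarray(signals, dtype=self.dtype)
        mask = np.asarray(obs_mask, dtype=bool)
        B, P, _ = q.shape
        counts = mask.sum(axis=1)
        if np.any(counts < 1):
            raise ValueError("every item needs at least one active observation")
        if training and np.any(counts < cfg.min_observations):
            raise ValueError(f"need at least {cfg.min_observations} observations per item")
        if not np.all(np.isfinite(s[mask])):
            raise ValueError("non-finite observation signals")
        cache: dict = {} if (want_cache or training) else None

        si = self.sign_invariant_features(q, training, cache)  # (B, P, w)
        si_flat = si.reshape(B * P, cfg.width)

        flat_idx = np.flatnonzero(mask.ravel())  # batch-major, sorted
        seg_ids = flat_idx // P
        starts = np.concatenate([[0], np.cumsum(np.bincount(seg_ids, minlength=B))[:-1]])
        x = np.concatenate([si_flat[flat_idx], s.ravel()[flat_idx, None]], axis=1)

        pools = []
        for t in range(cfg.encoder_stages):
            x = self.transform_apply(t, x, training, cache)
            pooled, argmax_rows = self._pool(x, seg_ids, starts)
            pools.append((x.shape, argmax_rows))
            if t < cfg.encoder_stages - 1:
                x = np.concatenate([x, pooled[seg_ids]], axis=1)
        z = pooled  # (B, L)

        dec_in = np.concatenate(
            [si_flat, np.repeat(z, P, axis=0)], axis=1
        )  # (B*P, w + L)
        y = dec_in
        n_dec = len(cfg.decoder_widths())
        for i in range(n_dec):
            y = self._dense(f"dec.{i}", y, cache)
            if i < n_dec - 1:
                y = _relu(y)
                if cache is not None:
                    cache[f"dec.{i}.y"] = y
        preds = y.reshape(B, P)

        if cache is not None:
            cache["_meta"] = (B, P, flat_idx, seg_ids, starts, pools)
        if want_cache or training:
            return preds, cache
        return preds

    @staticmethod
    def _pool(x, seg_ids, starts):
        """Masked max over each item's active paths (compact, contiguous layout).

        Returns the pooled (n_seg, F) array and, per pooled entry, the row in
        ``x`` whose value was selected (first attaining row, for backprop).
        Segments are contiguous runs, so ``reduceat`` applies.
        """
        pooled = np.maximum.reduceat(x, starts, axis=0)
        big = np.iinfo(np.int32).max
        rows = np.where(
            x == pooled[seg_ids], np.arange(x.shape[0], dtype=np.int32)[:, None], np.int32(big)
        )
        argmax_rows = np.minimum.reduceat(rows, starts, axis=0)
        return pooled, argmax_rows

    @staticmethod
    def _pool_bwd(g_pooled, argmax_rows, n_rows):
        # each (row, col) pair is selected by at most one segment → plain scatter
        g = np.zeros((n_rows, g_pooled.shape[1]), dtype=g_pooled.dtype)
        cols = np.broadcast_to(np.arange(g_pooled.shape[1]), argmax_rows.shape)
        g[argmax_rows.ravel(), cols.ravel()] = g_pooled.ravel()
        return g

    def backward_paths(self, g_preds: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Reverse-mode gradients of a scalar loss w.r.t. all parameters,
        given d(loss)/d(predictions) from :meth:`forward_paths`."""
        cfg = self.config
        B, P, flat_idx, seg_ids, starts, pools = cache["_meta"]
        grads: dict[str, np.ndarray] = {}

        g = np.array(g_preds, dtype=self.dtype).reshape(B * P, 1)
        n_dec = len(cfg.decoder_widths())
        for i in reversed(range(n_dec)):
            if i < n_dec - 1:
                g *= cache[f"dec.{i}.y"] > 0
            g = self._dense_bwd(f"dec.{i}", g, cache, grads)
        g_si_flat = g[:, : cfg.width].copy()  # (B*P, w)
        g_z = g[:, cfg.width :].reshape(B, P, cfg.latent_dim).sum(axis=1)

        # encoder backward, last stage first
        g_x = None
        for t in reversed(range(cfg.encoder_stages)):
            x_shape, argmax_rows = pools[t]
            if t == cfg.encoder_stages - 1:
                g_stage_out = self._pool_bwd(g_z, argmax_rows, x_shape[0])
            else:
                g_direct = g_x[:, : cfg.width]
                g_pooled = np.add.reduceat(g_x[:, cfg.width :], starts, axis=0)
                g_stage_out = g_direct + self._pool_bwd(g_pooled, argmax_rows, x_shape[0])
            g_x = self._transform_bwd(t, g_stage_out, cache, grads)

        # stage-0 input was [SI || signal]
        g_si_flat[flat_idx] += g_x[:, : cfg.width]
        self._si_bwd(g_si_flat, cache, grads)
        return grads

    # -- inference API -----------------------------------------------------

    def encode(self, qvectors, signals, mask=None, training: bool = False) -> np.ndarray:
        """Latent code of one observation set or a batch of them.

        ``qvectors`` (N, 3) or (B, N, 3) with matching ``signals``; ``mask``
        marks active paths (all active by default).  Inference mode uses
        running normalization statistics, making the result exactly invariant
        to path permutation and to sign flips of any subset of q-vectors.
        """
        cfg = self.config
        q = np.asarray(qvectors, dtype=self.dtype)
        s = np.asarray(signals, dtype=self.dtype)
        single = q.ndim == 2
        if single:
            q, s = q[None], s[None]
            if mask is not None:
                mask = np.asarray(mask, dtype=bool)[None]
        B, N, _ = q.shape
        if mask is None:
            mask = np.ones((B, N), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if np.any(mask.sum(axis=1) < cfg.min_observations):
            raise ValueError(f"need at least {cfg.min_observations} observations")
        if not np.all(np.isfinite(s[mask])):
            raise ValueError("non-finite observation signals")

        si = self.sign_invariant_features(q, training)
        flat_idx = np.flatnonzero(mask.ravel())
        seg_ids = flat_idx // N
        starts = np.concatenate([[0], np.cumsum(np.bincount(seg_ids, minlength=B))[:-1]])
        x = np.concatenate(
            [si.reshape(B * N, cfg.width)[flat_idx], s.ravel()[flat_idx, None]], axis=1
        )
        for t in range(cfg.encoder_stages):
            x = self.transform_apply(t, x, training)
            pooled, _ = self._pool(x, seg_ids, starts)
            if t < cfg.encoder_stages - 1:
                x = np.concatenate([x, pooled[seg_ids]], axis=1)
        z = pooled
        return z[0] if single else z

    def decode(self, query_qvectors, z, training: bool = False) -> np.ndarray:
        """Predict signals at query q-vectors given latent code(s).

        ``query_qvectors`` (M, 3) with ``z`` (L,), or (B, M, 3) with (B, L).
        Each query is processed on its own path; predictions are independent
        of the other queries in the batch.
        """
        cfg = self.config
        q = np.asarray(query_qvectors, dtype=self.dtype)
        z = np.asarray(z, dtype=self.dtype)
        single = q.ndim == 2
        if single:
            q, z = q[None], z[None]
        B, M, _ = q.shape
        si = self.sign_invariant_features(q, training).reshape(B * M, cfg.width)
        y = np.concatenate([si, np.repeat(z, M, axis=0)], axis=1)
        n_dec = len(cfg.decoder_widths())
        for i in range(n_dec):
            y = self._dense(f"dec.{i}", y)
            if i < n_dec - 1:
                y = _relu(y)
        preds = y.reshape(B, M)
        return preds[0] if single else preds

    def reconstruct(self, obs_qvectors, obs_signals, query_qvectors, obs_mask=None) -> np.ndarray:
        """encode + decode: ŝ = D(q | E(x_obs))."""
        z = self.encode(obs_qvectors, obs_signals, obs_mask)
        return self.decode(query_qvectors, z)

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        """Single-archive checkpoint: config (JSON) + named parameter arrays."""
        payload = {f"param:{k}": v for k, v in self.params.items()}
        payload.update({f"state:{k}": v for k, v in self.state.items()})
        np.savez(path, __config__=json.dumps(self.config.to_dict()), **payload)

    @classmethod
    def load(cls, path) -> "DiscusNet":
        with np.load(path, allow_pickle=False) as archive:
            config = NetworkConfig.from_dict(json.loads(str(archive["__config__"])))
            net = cls(config)
            for key in archive.files:
                if key.startswith("param:"):
                    net.params[key[6:]] = archive[key].astype(net.dtype)
                elif key.startswith("state:"):
                    net.state[key[6:]] = archive[key].astype(net.dtype)
        return net
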