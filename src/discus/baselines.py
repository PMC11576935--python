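"""Reference reconstruction methods: spherical harmonics and discrete MLPs.

The SH baseline fits a real, symmetric (even-order) spherical-harmonics series
to single-shell signals by regularized least squares with a Laplace–Beltrami
smoothness penalty,

    c = argmin ‖B c − s‖² + α · cᵀ L c,       L = diag((l(l+1))²),

and evaluates the series at arbitrary query directions.  The basis follows the
real symmetric convention common in diffusion MRI (Descoteaux-type):

    Y_lm^real = √2 (−1)^m Im(Y_l^|m|)   for m < 0
              = Y_l^0                   for m = 0
              = √2 (−1)^m Re(Y_l^m)     for m > 0

restricted to even l (antipodal symmetry), columns ordered by l ascending and
m ascending within l; at order 8 there are 45 coefficients.

The discrete MLP baseline maps a *fixed* observation-signal vector through one
566-unit ReLU hidden layer to output signals; its wiring is tied to the
observation set, so it is neither permutation-invariant nor applicable to
other schemes — the contrast case for the set encoder.  The MLP-SH hybrid has
45 output neurons interpreted as order-8 SH coefficients and is trained
end-to-end on reconstructed signals, which makes it output-continuous.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import sph_harm_y

from .train import LRScheduler, EarlyStopState, early_stopping_check

__all__ = [
    "SHModel",
    "sh_basis",
    "sh_fit",
    "sh_predict",
    "MLPBaseline",
    "mlp_baseline_build",
    "mlp_sh_build",
    "train_mlp",
]


def n_sh_coeffs(max_order: int) -> int:
    return (max_order + 1) * (max_order + 2) // 2


@dataclasses.dataclass
class SHModel:
    """A fitted even-order spherical-harmonics series."""

    max_order: int
    coefficients: np.ndarray
    regularization_weight: float = 0.0

    def __post_init__(self):
        if self.max_order % 2:
            raise ValueError("max_order must be even")
        expected = n_sh_coeffs(self.max_order)
        if len(self.coefficients) != expected:
            raise ValueError(f"expected {expected} coefficients, got {len(self.coefficients)}")


def _sh_degrees(max_order: int) -> tuple[np.ndarray, np.ndarray]:
    ls, ms = [], []
    for l in range(0, max_order + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def sh_basis(directions, max_order: int) -> np.ndarray:
    """Real symmetric SH design matrix, (n_dirs × n_coeffs).

    Orthonormal on the sphere; even orders only, so B(−g) == B(g).
    """
    if max_order % 2:
        raise ValueError("max_order must be even (antipodal symmetry)")
    g = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(g, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("directions must be unit vectors")
    theta = np.arccos(np.clip(g[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(g[:, 1], g[:, 0])  # azimuth
    ls, ms = _sh_degrees(max_order)
    cols = []
    for l, m in zip(ls, ms):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
        elif m == 0:
            cols.append(y.real)
        else:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
    return np.stack(cols, axis=1)


def _laplace_beltrami(max_order: int) -> np.ndarray:
    ls, _ = _sh_degrees(max_order)
    return np.diag((ls * (ls + 1.0)) ** 2)


def sh_fit(signals, directions, max_order: int = 8, reg_weight: float = 0.006) -> SHModel:
    """Regularized least-squares SH fit on one shell (closed-form solve)."""
    s = np.asarray(signals, dtype=float)
    B = sh_basis(directions, max_order)
    if reg_weight < 0:
        raise ValueError("reg_weight must be non-negative")
    A = B.T @ B + reg_weight * _laplace_beltrami(max_order)
    try:
        coeffs = np.linalg.solve(A, B.T @ s)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular SH system — too few directions for this order; "
            "raise reg_weight or lower max_order"
        ) from exc
    if reg_weight == 0.0 and np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError(
            "ill-conditioned SH system with reg_weight=0 — raise reg_weight"
        )
    return SHModel(max_order, coeffs, reg_weight)


def sh_predict(model: SHModel, directions) -> np.ndarray:
    """Evaluate a fitted SH series at query directions (antipodally symmetric)."""
    return sh_basis(directions, model.max_order) @ model.coefficients


# ---------------------------------------------------------------------------
# Discrete MLP baselines
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MLPBaseline:
    """One-hidden-layer MLP tied to a fixed observation layout.

    ``sh_order`` > 0 marks the MLP-SH hybrid: the ``n_sh_coeffs(sh_order)``
    outputs are SH coefficients and predictions are basis evaluations at query
    directions; training remains end-to-end on reconstructed signals.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    sh_order: int = 0

    @property
    def n_parameters(self) -> int:
        return int(self.W1.size + self.b1.size + self.W2.size + self.b2.size)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Raw network output for input rows (signal vectors)."""
        h = np.maximum(np.atleast_2d(x) @ self.W1 + self.b1, 0.0)
        return h @ self.W2 + self.b2

    def predict(self, x: np.ndarray, query_directions=None) -> np.ndarray:
        """Signal predictions; MLP-SH evaluates its coefficient output at
        ``query_directions`` through the SH basis."""
        out = self.forward(x)
        if self.sh_order:
            if query_directions is None:
                raise ValueError("MLP-SH prediction requires query directions")
            return out @ sh_basis(query_directions, self.sh_order).T
        return out


_HIDDEN = 566  # ablated baseline width at ≈170k-parameter budget


def mlp_baseline_build(n_in: int, n_out: int, seed: int = 0) -> MLPBaseline:
    """Discrete MLP: linear(n_in→566) + ReLU + linear(566→n_out)."""
    if n_in < 1 or n_out < 1:
        raise ValueError("n_in and n_out must be positive")
    rng = np.random.default_rng(seed)
    def init(fan_in, shape):
        return rng.uniform(-1, 1, shape) / np.sqrt(fan_in)
    return MLPBaseline(
        W1=init(n_in, (n_in, _HIDDEN)),
        b1=init(n_in, _HIDDEN),
        W2=init(_HIDDEN, (_HIDDEN, n_out)),
        b2=init(_HIDDEN, n_out),
    )


def mlp_sh_build(n_in: int, max_order: int = 8, seed: int = 0) -> MLPBaseline:
    """MLP-SH hybrid: same trunk, 45 SH-coefficient outputs at order 8."""
    model = mlp_baseline_build(n_in, n_sh_coeffs(max_order), seed)
    model.sh_order = max_order
    return model


def train_mlp(
    model: MLPBaseline,
    inputs: np.ndarray,
    targets: np.ndarray,
    query_directions=None,
    epochs: int = 100,
    batch_size: int = 512,
    initial_lr: float = 0.01,
    momentum: float = 0.9,
    validation_fraction: float = 0.1,
    min_epochs: int = 40,
    patience: int = 40,
    seed: int = 0,
) -> MLPBaseline:
    """Momentum-SGD training with the same plateau schedule and early stopping
    as the set encoder.  For MLP-SH, the ℓ2 loss is computed on signals
    reconstructed at ``query_directions``, not on coefficients.
    """
    x = np.asarray(inputs, dtype=float)
    t = np.asarray(targets, dtype=float)
    basis = None
    if model.sh_order:
        if query_directions is None:
            raise ValueError("MLP-SH training requires query directions")
        basis = sh_basis(query_directions, model.sh_order)
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(validation_fraction * len(x))))
    perm = rng.permutation(len(x))
    vi, ti = perm[:n_val], perm[n_val:]
    sched = LRScheduler(lr=initial_lr)
    stopper = EarlyStopState()
    params = [model.W1, model.b1, model.W2, model.b2]
    vel = [np.zeros_like(p) for p in params]
    for _ in range(epochs):
        order = rng.permutation(len(ti))
        for start in range(0, len(order), batch_size):
            rows = ti[order[start : start + batch_size]]
            xb, tb = x[rows], t[rows]
            h_pre = xb @ model.W1 + model.b1
            h = np.maximum(h_pre, 0.0)
            out = h @ model.W2 + model.b2
            pred = out @ basis.T if basis is not None else out
            g_pred = 2.0 * (pred - tb) / pred.size
            g_out = g_pred @ basis if basis is not None else g_pred
            gW2 = h.T @ g_out
            gb2 = g_out.sum(axis=0)
            gh = (g_out @ model.W2.T) * (h_pre > 0)
            gW1 = xb.T @ gh
            gb1 = gh.sum(axis=0)
            for p, v, g in zip(params, vel, [gW1, gb1, gW2, gb2]):
                v *= momentum
                v -= sched.lr * g
                p += v
        val_pred = model.predict(x[vi], query_directions)
        val_loss = float(np.mean((val_pred - t[vi]) ** 2))
        sched.step(val_loss)
        stopper.update(val_loss)
        if early_stopping_check(stopper, min_epochs, patience):
            break
    return model
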