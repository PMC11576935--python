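"""Evaluation: signal/metric error formulas, DTI fitting, benchmark harness.

Per-voxel reconstruction quality is the mean squared relative error over the
J query signals,

    Error_signal(ŝ, s) = (1/J) Σ_j (ŝ_j − s_j)² / s_j²,

and downstream metric quality the squared relative error

    Error_metric(m̂, m) = (m̂ − m)² / m².

Voxel-wise errors are aggregated as distributions (median, quartiles,
1.5-IQR whiskers capped at the extremes — the boxplot convention used in the
figures these benchmarks mirror).

The DTI fit is standard log-linear (weighted) least squares of the
mono-exponential tensor model log s = c₀ − b gᵀ D g, with the intercept c₀
absorbing any residual normalization offset; FA and MD are the usual
closed-form eigenvalue invariants.  Reference fits for metric errors use only
measurements *outside* the observation set, so a method cannot be rewarded
for reproducing observation noise.
"""

from __future__ import annotations

import dataclasses
from typing import Protocol

import numpy as np
import pandas as pd

from .qspace import AcquisitionScheme, NestedObservationSets, QuerySet
from .simulate import fa_md_from_tensor

__all__ = [
    "ErrorReport",
    "DTIFit",
    "error_signal",
    "error_metric",
    "dti_fit",
    "independent_reference_fit",
    "run_benchmark",
    "ReconstructionMethod",
    "SHReconstruction",
    "DiscusReconstruction",
    "MLPReconstruction",
    "OracleReconstruction",
]

#: reference signals with magnitude below this are excluded from Error_signal
SIGNAL_FLOOR = 1e-6


def error_signal(predicted, reference) -> float:
    """Mean squared relative signal error over the query vectors of one voxel."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("predicted and reference must be equal-length and non-empty")
    if np.any(np.abs(r) < SIGNAL_FLOOR):
        raise ValueError("reference signal at or below the degeneracy floor")
    return float(np.mean((p - r) ** 2 / r**2))


def error_metric(predicted: float, reference: float) -> float:
    """Squared relative error of one scalar metric."""
    if reference == 0:
        raise ValueError("reference metric is zero")
    return float((predicted - reference) ** 2 / reference**2)


@dataclasses.dataclass
class DTIFit:
    """A fitted diffusion tensor with its rotation-invariant scalars."""

    tensor: np.ndarray  # symmetric 3×3, mm²/s
    fa: float
    md: float
    eigenvalues: np.ndarray  # ascending


def dti_fit(signals, scheme: AcquisitionScheme, method: str = "wls") -> DTIFit:
    """Log-linear (weighted) least-squares fit of the diffusion tensor.

    Requires ≥ 6 diffusion-weighted measurements spanning all six independent
    b-matrix components.  Non-positive signals are clipped at 1e-6 before the
    log transform.  ``method`` is "ols" or "wls" (weights s², the standard
    first-order variance correction for log-transformed magnitudes).
    """
    s = np.asarray(signals, dtype=float)
    if s.shape[0] != len(scheme):
        raise ValueError("signal count does not match scheme length")
    if np.any(s <= 0):
        import warnings

        warnings.warn("non-positive signals clipped at 1e-6 for the log transform")
        s = np.maximum(s, 1e-6)
    g = scheme.directions
    b = scheme.bvalues
    if int(np.sum(~scheme.b0_mask)) < 6:
        raise ValueError("need at least 6 diffusion-weighted measurements")
    # design: log s = c0 - b * (gx² Dxx + gy² Dyy + gz² Dzz + 2 gx gy Dxy + ...)
    # On a single shell without b0 the intercept is collinear with the diagonal
    # columns (gx²+gy²+gz² = 1); signals are normalized (log s(0) = 0), so the
    # intercept is dropped in that case.
    tensor_cols = np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    X = np.column_stack([np.ones(len(b)), tensor_cols])

    def _normalized_rank(M):
        norms = np.linalg.norm(M, axis=0)
        if np.any(norms == 0):
            return 0
        return np.linalg.matrix_rank(M / norms)

    with_intercept = _normalized_rank(X) >= 7
    if not with_intercept:
        X = tensor_cols
        if _normalized_rank(X) < 6:
            raise ValueError(
                "rank-deficient design: directions do not span the tensor space"
            )
    y = np.log(s)
    if method == "wls":
        w = s**2
        Xw = X * w[:, None]
        beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    elif method == "ols":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        raise ValueError(f"unknown method {method!r}")
    dxx, dyy, dzz, dxy, dxz, dyz = beta[1:] if with_intercept else beta
    D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    fa, md = fa_md_from_tensor(D)
    return DTIFit(tensor=D, fa=fa, md=md, eigenvalues=np.linalg.eigvalsh(D))


def independent_reference_fit(
    full_signals, scheme: AcquisitionScheme, observation_indices
) -> DTIFit:
    """DTI reference fit on the complement of the observation set only."""
    obs = np.asarray(observation_indices, dtype=int)
    keep = np.setdiff1d(np.arange(len(scheme)), obs)
    return dti_fit(np.asarray(full_signals, dtype=float)[keep], scheme.subset(keep))


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------


class ReconstructionMethod(Protocol):
    """Anything that can predict query signals from one voxel's observations."""

    name: str

    def predict(
        self,
        obs_indices: np.ndarray,
        obs_signals: np.ndarray,
        query_qvectors: np.ndarray,
        scheme: AcquisitionScheme,
    ) -> np.ndarray: ...


@dataclasses.dataclass
class SHReconstruction:
    """Order-8 regularized SH fit per voxel (single-shell only)."""

    max_order: int = 8
    reg_weight: float = 0.006
    name: str = "SH"

    def predict(self, obs_indices, obs_signals, query_qvectors, scheme):
        from .baselines import sh_fit, sh_predict

        dirs = scheme.directions[obs_indices]
        model = sh_fit(obs_signals, dirs, self.max_order, self.reg_weight)
        qdirs = np.asarray(query_qvectors, dtype=float)
        qnorm = np.linalg.norm(qdirs, axis=1, keepdims=True)
        return sh_predict(model, qdirs / qnorm)


@dataclasses.dataclass
class DiscusReconstruction:
    """A trained set encoder/decoder; input- and output-continuous."""

    net: object
    name: str = "DISCUS"
    rotation: np.ndarray | None = None  # optional joint test-time rotation

    def predict(self, obs_indices, obs_signals, query_qvectors, scheme):
        q_obs = scheme.qvectors[obs_indices]
        q_query = np.asarray(query_qvectors, dtype=float)
        if self.rotation is not None:
            q_obs = q_obs @ self.rotation.T
            q_query = q_query @ self.rotation.T
        return self.net.reconstruct(q_obs, obs_signals, q_query)

    def predict_batch(self, obs_indices, signals_matrix, query_qvectors, scheme):
        """Vectorized prediction for many voxels sharing one observation set."""
        q_obs = scheme.qvectors[obs_indices]
        q_query = np.asarray(query_qvectors, dtype=float)
        if self.rotation is not None:
            q_obs = q_obs @ self.rotation.T
            q_query = q_query @ self.rotation.T
        V = signals_matrix.shape[0]
        z = self.net.encode(
            np.broadcast_to(q_obs, (V,) + q_obs.shape).copy(), signals_matrix
        )
        return self.net.decode(np.broadcast_to(q_query, (V,) + q_query.shape).copy(), z)


@dataclasses.dataclass
class MLPReconstruction:
    """A trained discrete MLP tied to one observation layout."""

    model: object
    trained_indices: np.ndarray | None = None
    name: str = "MLP"

    def predict(self, obs_indices, obs_signals, query_qvectors, scheme):
        qdirs = np.asarray(query_qvectors, dtype=float)
        qdirs = qdirs / np.linalg.norm(qdirs, axis=1, keepdims=True)
        return self.model.predict(obs_signals, qdirs)[0]


@dataclasses.dataclass
class OracleReconstruction:
    """Returns the reference signals — a perfect-method control."""

    reference: np.ndarray  # (V, K) full signals per voxel
    query_indices: np.ndarray
    name: str = "oracle"
    _row: int = 0

    def predict(self, obs_indices, obs_signals, query_qvectors, scheme):
        return self.reference[self._row][self.query_indices]


@dataclasses.dataclass
class ErrorReport:
    """Per-voxel error distributions for one (method, N) cell."""

    method: str
    n_obs: int
    error_signal: np.ndarray
    error_metric: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    n_failed: int = 0

    def summary(self) -> dict:
        return boxplot_summary(self.error_signal) | {
            "method": self.method,
            "n_obs": self.n_obs,
            "n_failed": self.n_failed,
        }


def boxplot_summary(values: np.ndarray) -> dict:
    """Median, quartiles and 1.5-IQR whiskers capped at the extremes."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = float(v[v >= q1 - 1.5 * iqr].min())
    hi = float(v[v <= q3 + 1.5 * iqr].max())
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": lo,
        "whisker_high": hi,
        "n": int(v.size),
    }


def run_benchmark(
    methods: dict[str, ReconstructionMethod],
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    nested_sets: NestedObservationSets,
    query_set: QuerySet,
) -> dict[tuple[str, int], ErrorReport]:
    """Reconstruct the query signals of every voxel for each (method, N).

    ``signals`` is (V, K) on ``scheme``; the query set must carry reference
    signals.  Voxels where a method fails are recorded as missing, not
    silently dropped.  Voxels whose reference signal falls below the
    degeneracy floor are excluded for all methods alike.
    """
    if query_set.reference_signals is None:
        raise ValueError("query set needs reference signals for evaluation")
    sig = np.asarray(signals, dtype=float)
    ref = np.asarray(query_set.reference_signals, dtype=float)
    valid = np.all(np.abs(ref) > SIGNAL_FLOOR, axis=1)
    reports: dict[tuple[str, int], ErrorReport] = {}
    for n in nested_sets.sizes:
        obs_idx = nested_sets.sets[n]
        for name, method in methods.items():
            if hasattr(method, "predict_batch"):
                preds = method.predict_batch(obs_idx, sig[:, obs_idx], query_set.qvectors, scheme)
                errs = np.array(
                    [
                        error_signal(preds[v], ref[v]) if valid[v] else np.nan
                        for v in range(sig.shape[0])
                    ]
                )
                n_failed = 0
            else:
                errs = np.full(sig.shape[0], np.nan)
                n_failed = 0
                for v in range(sig.shape[0]):
                    if not valid[v]:
                        continue
                    if hasattr(method, "_row"):
                        method._row = v
                    try:
                        pred = method.predict(
                            obs_idx, sig[v, obs_idx], query_set.qvectors, scheme
                        )
                        errs[v] = error_signal(np.ravel(pred), ref[v])
                    except Exception:
                        n_failed += 1
            reports[(name, n)] = ErrorReport(
                method=name,
                n_obs=int(n),
                error_signal=errs[np.isfinite(errs)],
                n_failed=n_failed,
            )
    return reports


def reports_to_frame(reports: dict[tuple[str, int], ErrorReport]) -> pd.DataFrame:
    """Tabular summary, one row per (method, N)."""
    return pd.DataFrame([r.summary() for r in reports.values()])
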