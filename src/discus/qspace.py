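"""q-space sampling schemes, gradient-table I/O, and observation/query set construction.

A diffusion acquisition is described here by its *q-vectors*: unit gradient
directions scaled by ``sqrt(b / b_ref)``, so that the vector magnitude encodes
the diffusion weighting relative to a reference b-value.  This keeps network
inputs bounded while preserving the physical proportionality ``|q| ∝ sqrt(b)``.

Signals are antipodally symmetric, ``s(q) = s(-q)``, so all angular distances
used for uniform-coverage constructions identify antipodes:
``d(u, v) = arccos |u·v|``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AcquisitionScheme",
    "ObservationSet",
    "QuerySet",
    "NestedObservationSets",
    "DegenerateVoxelError",
    "load_gradient_table",
    "save_gradient_table",
    "normalize_signals",
    "build_shell_scheme",
    "build_grid_scheme",
    "draw_nested_observation_sets",
    "grid_sort_and_draw",
    "sample_uniform_rotation",
    "rotate_scheme",
    "load_dwi_volume",
]

#: b-values below this (s/mm²) are treated as q ≡ 0 acquisitions.
B0_THRESHOLD = 50.0


class DegenerateVoxelError(ValueError):
    """Raised when a voxel cannot be normalized (mean b0 intensity is zero)."""


@dataclasses.dataclass(frozen=True)
class AcquisitionScheme:
    """A q-space sampling scheme.

    Parameters
    ----------
    qvectors : (K, 3) array
        Dimensionless q-vectors, ``direction * sqrt(b / b_ref)``.
    bvalues : (K,) array
        Diffusion weightings in s/mm².
    directions : (K, 3) array
        Unit gradient directions; the zero vector is permitted for b0 entries.
    b_ref : float
        Reference b-value (s/mm²) used for magnitude scaling.
    """

    qvectors: np.ndarray
    bvalues: np.ndarray
    directions: np.ndarray
    b_ref: float

    def __post_init__(self):
        q = np.asarray(self.qvectors, dtype=float)
        b = np.asarray(self.bvalues, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        object.__setattr__(self, "qvectors", q)
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", g)
        if not (len(q) == len(b) == len(g)):
            raise ValueError("qvectors, bvalues and directions must have equal length")
        if np.any(b < 0):
            raise ValueError("negative b-values are not physical")
        nonb0 = b >= B0_THRESHOLD
        norms = np.linalg.norm(g[nonb0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-b0 directions must have unit norm")
        expected = np.sqrt(b / self.b_ref)
        if np.any(np.abs(np.linalg.norm(q, axis=1) - expected) > 1e-6):
            raise ValueError("|q| must equal sqrt(b / b_ref)")

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask of q ≡ 0 entries (b below :data:`B0_THRESHOLD`)."""
        return self.bvalues < B0_THRESHOLD

    @property
    def dwi_indices(self) -> np.ndarray:
        """Indices of diffusion-weighted (non-b0) entries."""
        return np.flatnonzero(~self.b0_mask)

    def subset(self, indices) -> "AcquisitionScheme":
        idx = np.asarray(indices, dtype=int)
        return AcquisitionScheme(
            self.qvectors[idx], self.bvalues[idx], self.directions[idx], self.b_ref
        )


@dataclasses.dataclass
class ObservationSet:
    """Indices into a scheme together with the (normalized) signals there."""

    indices: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.signals = np.asarray(self.signals, dtype=float)
        if len(self.indices) != len(self.signals):
            raise ValueError("indices and signals must have equal length")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("observation indices must be distinct")


@dataclasses.dataclass
class QuerySet:
    """Query q-vectors, optionally paired with reference signals for evaluation."""

    qvectors: np.ndarray
    reference_signals: np.ndarray | None = None
    indices: np.ndarray | None = None  # indices into the source scheme, if drawn from one

    def __post_init__(self):
        self.qvectors = np.atleast_2d(np.asarray(self.qvectors, dtype=float))
        if self.reference_signals is not None:
            self.reference_signals = np.asarray(self.reference_signals, dtype=float)
            # last axis indexes queries; leading axes may index voxels
            if self.reference_signals.shape[-1] != len(self.qvectors):
                raise ValueError("reference_signals last axis must match qvectors")
        if self.indices is not None:
            self.indices = np.asarray(self.indices, dtype=int)


@dataclasses.dataclass
class NestedObservationSets:
    """Nested index sets (sets[n1] ⊂ sets[n2] ⊂ …), disjoint from a query set."""

    sizes: list[int]
    sets: dict[int, np.ndarray]

    def __post_init__(self):
        self.sizes = sorted(int(s) for s in self.sizes)
        for a, b in zip(self.sizes[:-1], self.sizes[1:]):
            if not set(self.sets[a]).issubset(set(self.sets[b])):
                raise ValueError("observation sets must be nested")


# ---------------------------------------------------------------------------
# Gradient-table I/O (FSL dialect: 1×K bval row, 3×K bvec rows)
# ---------------------------------------------------------------------------

def load_gradient_table(bval_path, bvec_path, b_ref: float | None = None) -> AcquisitionScheme:
    """Read an FSL-dialect bval/bvec pair into an :class:`AcquisitionScheme`.

    ``b_ref`` defaults to the maximum b-value in the table.
    """
    bvals = np.loadtxt(bval_path, dtype=float, ndmin=2)
    if bvals.shape[0] != 1:
        bvals = bvals.reshape(1, -1) if bvals.size == max(bvals.shape) else bvals
    if bvals.ndim != 2 or bvals.shape[0] != 1:
        raise ValueError(f"bval file must contain a single row, got shape {bvals.shape}")
    bvals = bvals[0]
    bvecs = np.loadtxt(bvec_path, dtype=float, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must contain exactly three rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.shape[0]:
        raise ValueError(
            f"bval/bvec column counts differ: {bvals.shape[0]} vs {bvecs.shape[1]}"
        )
    if np.any(bvals < 0):
        raise ValueError("negative b-value in bval file")
    directions = bvecs.T.copy()
    nonb0 = bvals >= B0_THRESHOLD
    norms = np.linalg.norm(directions[nonb0], axis=1)
    if np.any(norms == 0):
        raise ValueError("zero direction for a non-b0 entry")
    directions[nonb0] /= norms[:, None]
    directions[~nonb0] = 0.0
    if b_ref is None:
        b_ref = float(np.max(bvals))
        if b_ref <= 0:
            raise ValueError("cannot infer b_ref from an all-b0 table")
    qvectors = directions * np.sqrt(bvals / b_ref)[:, None]
    return AcquisitionScheme(qvectors, bvals, directions, float(b_ref))


def save_gradient_table(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write the scheme in the same FSL dialect (directions with 6 decimals)."""
    with open(bval_path, "w") as f:
        f.write(" ".join(f"{b:g}" for b in scheme.bvalues) + "\n")
    with open(bvec_path, "w") as f:
        for axis in range(3):
            f.write(" ".join(f"{g:.6f}" for g in scheme.directions[:, axis]) + "\n")


# ---------------------------------------------------------------------------
# Signal normalization (T2-shinethrough removal)
# ---------------------------------------------------------------------------

def normalize_signals(raw_dwi, scheme: AcquisitionScheme) -> np.ndarray:
    """Divide a voxel's signals by the mean of its b0 signals.

    Removes the T2-weighted component, after which the signal at q ≡ 0 is 1.
    Voxels whose mean b0 intensity is zero carry no usable diffusion contrast
    and raise :class:`DegenerateVoxelError`.
    """
    raw = np.asarray(raw_dwi, dtype=float)
    b0 = scheme.b0_mask
    if raw.shape[-1] != len(scheme):
        raise ValueError("signal count does not match scheme length")
    if not np.any(b0):
        raise ValueError("scheme contains no b0 entry to normalize against")
    mean_b0 = np.mean(raw[..., b0], axis=-1)
    if np.any(mean_b0 == 0):
        raise DegenerateVoxelError("voxel with zero mean b0 intensity")
    return raw / mean_b0[..., None]


# ---------------------------------------------------------------------------
# Scheme constructions
# ---------------------------------------------------------------------------

def _repel_directions(n: int, rng: np.random.Generator, n_iter: int = 200) -> np.ndarray:
    """Approximately uniform unit directions under antipodal symmetry.

    Greedy electrostatic repulsion: points interact with both the other points
    and their antipodes via an inverse-square force, followed by projection
    back onto the sphere.  Deterministic for a fixed generator state.
    """
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]  # (n, n, 3)
            dist2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            dist2 = np.maximum(dist2, 1e-12)
            force += np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        x = x + step * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step *= 0.99
    return x


def build_shell_scheme(
    n_per_shell: Sequence[int],
    bvalues: Sequence[float],
    seed: int = 0,
    n_b0: int = 0,
    b_ref: float | None = None,
) -> AcquisitionScheme:
    """Build a (multi-)shell scheme with approximately uniform directions.

    One electrostatic-repulsion point set per shell; ``n_b0`` zero-weighted
    entries are prepended.  ``b_ref`` defaults to the maximum shell b-value.
    """
    if len(n_per_shell) != len(bvalues):
        raise ValueError("n_per_shell and bvalues must have equal length")
    rng = np.random.default_rng(seed)
    dirs, bs = [], []
    if n_b0:
        dirs.append(np.zeros((n_b0, 3)))
        bs.append(np.zeros(n_b0))
    for n, b in zip(n_per_shell, bvalues):
        if n < 1:
            raise ValueError("need at least one direction per shell")
        dirs.append(_repel_directions(int(n), rng))
        bs.append(np.full(int(n), float(b)))
    directions = np.concatenate(dirs)
    bvals = np.concatenate(bs)
    if b_ref is None:
        b_ref = float(np.max(bvals))
    qvectors = directions * np.sqrt(bvals / b_ref)[:, None]
    return AcquisitionScheme(qvectors, bvals, directions, b_ref)


def build_grid_scheme(
    grid_half_width: int, n_points: int, b_max: float, seed: int = 0
) -> AcquisitionScheme:
    """Sparse Cartesian-grid scheme (diffusion-spectrum-imaging style).

    Candidate q-vectors are the integer lattice points inside the ball of
    radius ``grid_half_width``; coordinates are rescaled so the largest lattice
    norm maps to ``b_max`` (b ∝ |q|²).  The origin is always included and a
    seeded draw selects the remaining points.
    """
    hw = int(grid_half_width)
    ax = np.arange(-hw, hw + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1).astype(float)
    norms = np.linalg.norm(grid, axis=1)
    grid = grid[norms <= hw + 1e-9]
    norms = np.linalg.norm(grid, axis=1)
    if n_points > len(grid):
        raise ValueError(f"n_points={n_points} exceeds the {len(grid)} grid points in the ball")
    origin = np.flatnonzero(norms == 0)[0]
    rng = np.random.default_rng(seed)
    others = np.delete(np.arange(len(grid)), origin)
    chosen = rng.choice(others, size=n_points - 1, replace=False) if n_points > 1 else []
    sel = np.concatenate([[origin], np.sort(chosen)]).astype(int)
    lattice = grid[sel]
    r = np.linalg.norm(lattice, axis=1)
    bvals = b_max * (r / hw) ** 2
    directions = np.zeros_like(lattice)
    nz = r > 0
    directions[nz] = lattice[nz] / r[nz, None]
    qvectors = directions * np.sqrt(bvals / b_max)[:, None]
    return AcquisitionScheme(qvectors, bvals, directions, float(b_max))


# ---------------------------------------------------------------------------
# Observation / query set construction
# ---------------------------------------------------------------------------

def _axial_distance(u: np.ndarray, v: np.ndarray, antipodal: bool = True) -> np.ndarray:
    """Spherical distance; antipodal identification (arccos |û·v̂|, the
    default, consistent with s(q) = s(−q)) or plain great-circle arccos û·v̂."""
    dots = u @ v.T
    if antipodal:
        dots = np.abs(dots)
    return np.arccos(np.clip(dots, -1.0, 1.0))


def _greedy_order(
    directions: np.ndarray, rng: np.random.Generator, antipodal: bool = True
) -> np.ndarray:
    """Order directions by greedily maximizing the minimum spherical distance
    to the already-chosen set, from a seeded random start."""
    n = len(directions)
    start = int(rng.integers(n))
    order = [start]
    remaining = set(range(n)) - {start}
    min_dist = _axial_distance(directions, directions[[start]], antipodal)[:, 0]
    while remaining:
        rem = np.array(sorted(remaining))
        nxt = rem[int(np.argmax(min_dist[rem]))]
        order.append(int(nxt))
        remaining.discard(int(nxt))
        min_dist = np.minimum(
            min_dist, _axial_distance(directions, directions[[nxt]], antipodal)[:, 0]
        )
    return np.asarray(order, dtype=int)


def _even_spaced(order: np.ndarray, n: int) -> np.ndarray:
    """n distinct entries evenly spaced along an ordering."""
    pos = np.unique(np.round(np.linspace(0, len(order) - 1, n)).astype(int))
    i = 0
    while len(pos) < n:  # fix collisions from rounding
        if i not in pos:
            pos = np.sort(np.append(pos, i))
        i += 1
    return order[pos]


def grid_sort_and_draw(qvectors, bvalues, n: int, seed_or_rng=0, antipodal: bool = True) -> np.ndarray:
    """Draw ``n`` indices with uniform angular and radial coverage.

    Vectors are grouped into b-bins of 1,000 s/mm²; within each bin they are
    ordered greedily (seeded random start, then repeatedly the vector with
    maximum minimum spherical distance to the chosen set); ``n`` entries are
    then drawn evenly spaced from the concatenated ordering.  The distance
    identifies antipodes by default (``antipodal=False`` for plain
    great-circle distance).
    """
    q = np.atleast_2d(np.asarray(qvectors, dtype=float))
    b = np.asarray(bvalues, dtype=float)
    if len(q) == 0:
        raise ValueError("empty input")
    if n > len(q):
        raise ValueError(f"cannot draw {n} from {len(q)} vectors")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    bins = np.floor(b / 1000.0).astype(int)
    ordering = []
    for bin_id in np.unique(bins):
        idx = np.flatnonzero(bins == bin_id)
        dirs = q[idx]
        norms = np.linalg.norm(dirs, axis=1)
        unit = np.where(norms[:, None] > 0, dirs / np.maximum(norms, 1e-12)[:, None], 0.0)
        ordering.extend(idx[_greedy_order(unit, rng, antipodal)])
    return _even_spaced(np.asarray(ordering, dtype=int), n)


def draw_nested_observation_sets(
    scheme: AcquisitionScheme,
    query_size: int,
    sizes: Sequence[int],
    seed: int = 0,
    signals: np.ndarray | None = None,
) -> tuple[QuerySet, NestedObservationSets]:
    """Draw an evaluation query set and nested observation sets.

    The query set is drawn first from all diffusion-weighted vectors for best
    uniform coverage; observation sets are drawn from the remainder starting
    with the largest, each smaller set nested inside the next larger one.
    b0 entries are excluded (they serve normalization, not reconstruction).
    ``signals`` (…, K) optionally attaches reference signals to the query set.
    """
    sizes = sorted(int(s) for s in sizes)
    dwi = scheme.dwi_indices
    if query_size + sizes[-1] > len(dwi):
        raise ValueError(
            f"query_size + max(sizes) = {query_size + sizes[-1]} exceeds the "
            f"{len(dwi)} diffusion-weighted vectors"
        )
    rng = np.random.default_rng(seed)
    q = scheme.qvectors[dwi]
    b = scheme.bvalues[dwi]
    query_local = grid_sort_and_draw(q, b, query_size, rng)
    query_idx = dwi[query_local]
    rem_local = np.setdiff1d(np.arange(len(dwi)), query_local)
    sets: dict[int, np.ndarray] = {}
    pool = rem_local
    for size in reversed(sizes):
        chosen = grid_sort_and_draw(q[pool], b[pool], size, rng)
        pool = pool[chosen]
        sets[size] = np.sort(dwi[pool])
    query = QuerySet(
        scheme.qvectors[query_idx],
        None if signals is None else np.asarray(signals)[..., query_idx],
        indices=query_idx,
    )
    return query, NestedObservationSets(sizes=list(sizes), sets=sets)


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

def sample_uniform_rotation(seed_or_rng=None) -> np.ndarray:
    """A proper rotation matrix drawn uniformly from SO(3) (quaternion method)."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    quat = rng.standard_normal(4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix()


def rotate_scheme(scheme_or_vectors, R: np.ndarray):
    """Apply a rotation jointly to all q-vectors (b-values unchanged)."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8 or np.linalg.det(R) < 0:
        raise ValueError("R must be a proper rotation matrix")
    if isinstance(scheme_or_vectors, AcquisitionScheme):
        s = scheme_or_vectors
        return AcquisitionScheme(s.qvectors @ R.T, s.bvalues, s.directions @ R.T, s.b_ref)
    return np.asarray(scheme_or_vectors, dtype=float) @ R.T


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def load_dwi_volume(dwi_path, mask_path=None):
    """Load a 4D DWI NIfTI (and optional binary mask) as float arrays.

    Returns ``(data, mask)`` where ``data`` has shape (x, y, z, K) and ``mask``
    is boolean (all-true when no mask is given).
    """
    import nibabel as nib

    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return data, mask
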