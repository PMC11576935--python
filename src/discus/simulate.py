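"""Synthetic diffusion phantom: multi-tensor voxels with known ground truth.

Each voxel is a mixture of Gaussian diffusion compartments,

    s(b, g) = Σ_k f_k · exp(-b gᵀ D_k g),      Σ_k f_k = 1,

which is exactly antipodally symmetric and rotation-equivariant, and already
normalized (s(0) = 1), i.e. the T2-weighted component is divided out.  Optional
Rician noise emulates magnitude-MR acquisition noise.  Ground-truth FA/MD of
the fraction-weighted mean tensor are stored per voxel so downstream
metric-recovery can be scored against known values.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .qspace import AcquisitionScheme, save_gradient_table

__all__ = [
    "TensorCompartment",
    "VoxelGroundTruth",
    "PopulationConfig",
    "fa_md_from_tensor",
    "multi_tensor_signal",
    "add_noise",
    "generate_voxel_population",
    "write_phantom",
]


def _orthonormal_frame(e1: np.ndarray) -> np.ndarray:
    """Deterministic right-handed frame with first axis ``e1``."""
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)


@dataclasses.dataclass
class TensorCompartment:
    """One Gaussian compartment of a voxel.

    ``eigenvalues`` in mm²/s, sorted λ1 ≥ λ2 ≥ λ3 > 0; ``principal_direction``
    is the λ1 eigenvector; fractions across a voxel sum to 1.
    """

    eigenvalues: np.ndarray
    principal_direction: np.ndarray
    volume_fraction: float

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, dtype=float)
        if ev.shape != (3,) or np.any(ev <= 0):
            raise ValueError("eigenvalues must be three positive scalars")
        if np.any(np.diff(ev) > 0):
            raise ValueError("eigenvalues must be sorted descending")
        self.eigenvalues = ev
        d = np.asarray(self.principal_direction, dtype=float)
        self.principal_direction = d / np.linalg.norm(d)
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError("volume fraction must lie in [0, 1]")

    @property
    def tensor(self) -> np.ndarray:
        """The 3×3 diffusion tensor R diag(λ) Rᵀ in mm²/s."""
        R = _orthonormal_frame(self.principal_direction)
        return R @ np.diag(self.eigenvalues) @ R.T


def fa_md_from_tensor(D: np.ndarray) -> tuple[float, float]:
    """Closed-form fractional anisotropy and mean diffusivity of a tensor."""
    ev = np.linalg.eigvalsh((D + D.T) / 2)
    md = float(np.mean(ev))
    denom = float(np.sum(ev**2))
    if denom == 0:
        return 0.0, md
    fa = float(np.sqrt(1.5 * np.sum((ev - md) ** 2) / denom))
    return fa, md


@dataclasses.dataclass
class VoxelGroundTruth:
    """Generative parameters of one synthetic voxel.

    ``true_fa``/``true_md`` are the closed-form values of the fraction-weighted
    mean tensor — the reference against which recovered metrics are scored.
    """

    compartments: list[TensorCompartment]
    snr: float = np.inf
    configuration: str = ""
    true_fa: float = dataclasses.field(init=False)
    true_md: float = dataclasses.field(init=False)

    def __post_init__(self):
        fracs = sum(c.volume_fraction for c in self.compartments)
        if abs(fracs - 1.0) > 1e-9:
            raise ValueError(f"volume fractions must sum to 1, got {fracs}")
        self.true_fa, self.true_md = fa_md_from_tensor(self.mean_tensor)

    @property
    def mean_tensor(self) -> np.ndarray:
        return sum(c.volume_fraction * c.tensor for c in self.compartments)


def multi_tensor_signal(voxel: VoxelGroundTruth, scheme: AcquisitionScheme) -> np.ndarray:
    """Noiseless normalized signals of a voxel on a scheme.

    s(b, g) = Σ_k f_k exp(-b gᵀ D_k g); exactly 1 at b = 0 and symmetric
    under g → -g.
    """
    g = scheme.directions
    b = scheme.bvalues
    norms = np.linalg.norm(g, axis=1)
    if np.any((b > 0) & (np.abs(norms - 1.0) > 1e-6)):
        raise ValueError("non-unit direction for a diffusion-weighted entry")
    s = np.zeros(len(scheme))
    for c in voxel.compartments:
        adc = np.einsum("ki,ij,kj->k", g, c.tensor, g)
        s += c.volume_fraction * np.exp(-b * adc)
    return s


def add_noise(signals, snr: float, model: str = "rician", seed_or_rng=0) -> np.ndarray:
    """Add magnitude-MR noise at the given b0 signal-to-noise ratio.

    ``rician``: |s + n₁ + i·n₂|, ``gaussian``: s + n₁, with n ~ N(0, (1/snr)²)
    on the normalized scale.  ``snr = inf`` returns the input unchanged.
    """
    s = np.asarray(signals, dtype=float)
    if np.isinf(snr):
        return s.copy()
    if snr <= 0:
        raise ValueError("snr must be positive (or inf for noiseless)")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    sigma = 1.0 / snr
    if model == "rician":
        n1 = rng.normal(0.0, sigma, s.shape)
        n2 = rng.normal(0.0, sigma, s.shape)
        return np.hypot(s + n1, n2)
    if model == "gaussian":
        return s + rng.normal(0.0, sigma, s.shape)
    raise ValueError(f"unknown noise model {model!r}")


@dataclasses.dataclass
class PopulationConfig:
    """Composition of a synthetic voxel cohort.

    Fiber-configuration proportions plus white-matter-plausible diffusivity
    ranges (mm²/s): axial 1.4–2.0e-3 and radial 0.2–0.6e-3 cover the
    mono-exponential decay regime of the emulated b-ranges; isotropic voxels
    draw a single diffusivity from ``iso_range``.
    """

    mix: dict = dataclasses.field(
        default_factory=lambda: {"single": 0.45, "crossing2": 0.3, "crossing3": 0.15, "isotropic": 0.1}
    )
    axial_range: tuple[float, float] = (1.4e-3, 2.0e-3)
    radial_range: tuple[float, float] = (0.2e-3, 0.6e-3)
    iso_range: tuple[float, float] = (0.7e-3, 3.0e-3)
    snr: float = 30.0
    noise_model: str = "rician"


_CONFIG_N_FIBERS = {"single": 1, "crossing2": 2, "crossing3": 3, "isotropic": 0}


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _draw_voxel(config: PopulationConfig, kind: str, rng: np.random.Generator) -> VoxelGroundTruth:
    if kind == "isotropic":
        d = rng.uniform(*config.iso_range)
        comp = TensorCompartment(np.array([d, d, d]), np.array([0.0, 0.0, 1.0]), 1.0)
        return VoxelGroundTruth([comp], snr=config.snr, configuration=kind)
    n_fib = _CONFIG_N_FIBERS[kind]
    fracs = rng.dirichlet(np.full(n_fib, 8.0))  # near-equal fractions with jitter
    comps = []
    for k in range(n_fib):
        ax = rng.uniform(*config.axial_range)
        rad = rng.uniform(*config.radial_range)
        comps.append(
            TensorCompartment(np.array([ax, rad, rad]), _random_unit(rng), float(fracs[k]))
        )
    # renormalize exactly against float error
    total = sum(c.volume_fraction for c in comps)
    for c in comps:
        c.volume_fraction /= total
    return VoxelGroundTruth(comps, snr=config.snr, configuration=kind)


def generate_voxel_population(
    n_voxels: int,
    scheme: AcquisitionScheme,
    config: PopulationConfig | None = None,
    seed: int = 0,
):
    """Draw a cohort of synthetic voxels and their signals on a scheme.

    Returns ``(truths, clean, noisy)`` where ``clean``/``noisy`` have shape
    (n_voxels, K).  Fiber directions are uniform on the sphere; configuration
    kinds are drawn with the proportions in ``config.mix``.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be at least 1")
    config = config or PopulationConfig()
    kinds = [k for k, w in config.mix.items() if w > 0]
    if not kinds:
        raise ValueError("configuration mix is empty")
    weights = np.array([config.mix[k] for k in kinds], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    truths: list[VoxelGroundTruth] = []
    clean = np.empty((n_voxels, len(scheme)))
    for i in range(n_voxels):
        kind = kinds[rng.choice(len(kinds), p=weights)]
        vox = _draw_voxel(config, kind, rng)
        truths.append(vox)
        clean[i] = multi_tensor_signal(vox, scheme)
    noisy = add_noise(clean, config.snr, config.noise_model, rng)
    return truths, clean, noisy


def write_phantom(
    truths: Sequence[VoxelGroundTruth],
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    shape: tuple[int, int, int],
    out_dir,
    prefix: str = "phantom",
    b0_intensity: float | None = None,
):
    """Write a phantom as 4D NIfTI + bval/bvec + mask + ground-truth table.

    Voxels fill the volume in C order; the mask marks occupied voxels.  When
    ``b0_intensity`` is given, signals are rescaled to raw intensities (so the
    normalization path can be exercised); otherwise they are written as-is on
    the normalized scale.  Returns the paths written.
    """
    import nibabel as nib
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_voxels, K = np.asarray(signals).shape
    if np.prod(shape) < n_voxels:
        raise ValueError("shape too small for the population")
    if K != len(scheme):
        raise ValueError("signal count does not match scheme")
    data = np.zeros((int(np.prod(shape)), K), dtype=np.float32)
    sig = np.asarray(signals, dtype=np.float32)
    if b0_intensity is not None:
        sig = sig * np.float32(b0_intensity)
    data[:n_voxels] = sig
    data = data.reshape(*shape, K)
    mask = np.zeros(int(np.prod(shape)), dtype=np.uint8)
    mask[:n_voxels] = 1
    mask = mask.reshape(shape)
    affine = np.eye(4)
    paths = {
        "dwi": out / f"{prefix}_dwi.nii",
        "mask": out / f"{prefix}_mask.nii",
        "bval": out / f"{prefix}.bval",
        "bvec": out / f"{prefix}.bvec",
        "truth": out / f"{prefix}_truth.tsv",
    }
    nib.save(nib.Nifti1Image(data, affine), str(paths["dwi"]))
    nib.save(nib.Nifti1Image(mask, affine), str(paths["mask"]))
    save_gradient_table(scheme, paths["bval"], paths["bvec"])
    rows = []
    for i, t in enumerate(truths):
        rows.append(
            {
                "voxel": i,
                "configuration": t.configuration,
                "fa": t.true_fa,
                "md": t.true_md,
                "snr": t.snr,
                "fractions": ";".join(f"{c.volume_fraction:.6f}" for c in t.compartments),
                "directions": ";".join(
                    ",".join(f"{x:.6f}" for x in c.principal_direction) for c in t.compartments
                ),
            }
        )
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
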