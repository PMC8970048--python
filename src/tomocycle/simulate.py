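"""Classical physics-based subtomogram simulation and synthetic fixtures.

This is the conventional cryo-ET forward model that the learned translator is
benchmarked against: take a clean density map, apply a random rigid pose, blur
it with a detector modulation-transfer function (MTF), remove the single-tilt
missing wedge in Fourier space, and add Gaussian noise to a target
signal-to-noise ratio. Defaults follow common acquisition conditions:
SNR 0.5 and a 30 degree missing wedge.

A toy structure factory provides four geometrically distinct macromolecule
stand-ins (sphere, shell, dumbbell, rod) so that two unpaired domains — clean
density maps ``D`` and degraded subtomograms ``S`` — can be generated entirely
in memory for training and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume import DomainDataset, Volume, normalize_volume, save_dataset

__all__ = [
    "SimulationParams",
    "ToyStructureSpec",
    "TOY_CLASSES",
    "make_toy_density",
    "rotate_translate",
    "apply_mtf",
    "add_noise_to_snr",
    "apply_missing_wedge",
    "wedge_mask",
    "simulate_subtomogram",
    "generate_fixture_datasets",
]

TOY_CLASSES = ("sphere", "shell", "dumbbell", "rod")


@dataclass
class SimulationParams:
    """Settings for the classical degradation pipeline.

    ``snr`` is the variance ratio var(signal)/var(noise); ``None`` means
    noise-free. ``wedge_angle_deg`` is the half-angle of the missing wedge
    about the k_z axis (0 disables it). ``mtf_sigma`` is the width of the
    radial Gaussian MTF in cycles/voxel (``None`` disables it). ``rotation``
    is three Euler angles in degrees (x-y-z intrinsic) or ``"random"``;
    ``translation`` is three voxel offsets or ``"random"``.
    """

    snr: float | None = 0.5
    wedge_angle_deg: float = 30.0
    mtf_sigma: float | None = 0.25
    rotation: str | Sequence[float] = "random"
    translation: str | Sequence[float] = "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.snr is not None and not self.snr > 0:
            raise ValueError("snr must be positive or None")
        if not 0 <= self.wedge_angle_deg < 90:
            raise ValueError("wedge_angle_deg must lie in [0, 90)")
        if self.mtf_sigma is not None and not self.mtf_sigma > 0:
            raise ValueError("mtf_sigma must be positive or None")


@dataclass
class ToyStructureSpec:
    """One synthetic macromolecule: a named shape family plus size and seed."""

    class_id: str
    size: int = 16
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_id not in TOY_CLASSES:
            raise ValueError(f"unknown class_id {self.class_id!r}; choose from {TOY_CLASSES}")
        if self.size < 8:
            raise ValueError("size must be at least 8 voxels")


def _soft_ball(r: np.ndarray, radius: float, edge: float) -> np.ndarray:
    """Smooth indicator of r <= radius with a sigmoidal edge."""
    return 1.0 / (1.0 + np.exp((r - radius) / edge))


def make_toy_density(spec: ToyStructureSpec) -> Volume:
    """Build a clean, nonnegative toy density map; deterministic for a seed.

    The seed jitters the instance geometry (radii, lobe separation, rod tilt)
    by a few percent so that volumes within a class differ while remaining
    linearly separable between classes.
    """
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    c = (n - 1) / 2.0
    z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(np.float64)
    z, y, x = z - c, y - c, x - c
    r = np.sqrt(x * x + y * y + z * z)
    edge = 0.06 * n
    jitter = 1.0 + 0.08 * rng.standard_normal()

    if spec.class_id == "sphere":
        vol = _soft_ball(r, 0.30 * n * jitter, edge)
    elif spec.class_id == "shell":
        outer = _soft_ball(r, 0.38 * n * jitter, edge)
        inner = _soft_ball(r, 0.22 * n * jitter, edge)
        vol = outer - 0.9 * inner
    elif spec.class_id == "dumbbell":
        sep = 0.22 * n * jitter
        r1 = np.sqrt((x - sep) ** 2 + y * y + z * z)
        r2 = np.sqrt((x + sep) ** 2 + y * y + z * z)
        vol = _soft_ball(r1, 0.16 * n, edge) + _soft_ball(r2, 0.16 * n, edge)
    elif spec.class_id == "rod":
        tilt = 0.15 * rng.standard_normal()
        axial = x + tilt * y
        radial = np.sqrt((y - tilt * x) ** 2 + z * z)
        vol = _soft_ball(radial, 0.10 * n * jitter, edge) * _soft_ball(
            np.abs(axial), 0.42 * n, edge
        )
    else:  # pragma: no cover - guarded by spec validation
        raise ValueError(spec.class_id)

    vol = np.clip(vol, 0.0, None) * spec.amplitude
    return Volume(vol.astype(np.float32), provenance=f"toy:{spec.class_id}:{spec.seed}")


def _resolve_pose(rotation, translation, side: int, rng: np.random.Generator):
    if isinstance(rotation, str):
        if rotation != "random":
            raise ValueError(f"rotation must be angles or 'random', got {rotation!r}")
        matrix = Rotation.random(rng=rng).as_matrix()
    else:
        matrix = Rotation.from_euler("xyz", rotation, degrees=True).as_matrix()
    if isinstance(translation, str):
        if translation != "random":
            raise ValueError(f"translation must be offsets or 'random', got {translation!r}")
        shift = rng.uniform(-0.08 * side, 0.08 * side, size=3)
    else:
        shift = np.asarray(translation, dtype=np.float64)
    return matrix, shift


def rotate_translate(
    volume: Volume,
    rotation: str | Sequence[float] = "random",
    translation: str | Sequence[float] = (0.0, 0.0, 0.0),
    seed: int | None = None,
) -> Volume:
    """Apply a rigid pose with trilinear interpolation.

    The forward map sends voxel ``i`` to ``R (i - c) + c + t`` about the grid
    centre ``c``; voxels pulled from outside the support are filled with the
    volume's minimum (background) value. ``"random"`` draws a uniform rotation
    (Haar measure) and a translation within ±8% of the side length.
    """
    rng = np.random.default_rng(seed)
    matrix, shift = _resolve_pose(rotation, translation, volume.side, rng)
    c = (volume.side - 1) / 2.0
    centre = np.full(3, c)
    # snap ~1e-16 trig residue so right-angle poses hit grid points exactly
    inv = np.round(matrix.T, 12)  # rotations: inverse is transpose
    offset = np.round(centre - inv @ (centre + shift), 9)
    out = ndimage.affine_transform(
        volume.data.astype(np.float64), inv, offset=offset, order=1,
        mode="grid-constant", cval=float(volume.data.min()),
    )
    return Volume(out.astype(np.float32), volume.voxel_spacing, volume.provenance)


def _radial_freq(n: int) -> np.ndarray:
    f = np.fft.fftfreq(n)
    fz, fy, fx = np.meshgrid(f, f, f, indexing="ij")
    return np.sqrt(fx * fx + fy * fy + fz * fz)


def apply_mtf(volume: Volume, mtf_sigma: float | None) -> Volume:
    """Attenuate high frequencies with a radial Gaussian MTF.

    Multiplies the 3D spectrum by ``exp(-f^2 / (2 sigma^2))`` where ``f`` is
    spatial frequency in cycles/voxel. ``None`` is the identity. The operator
    is linear and preserves realness.
    """
    if mtf_sigma is None:
        return volume.copy()
    freq = _radial_freq(volume.side)
    mtf = np.exp(-(freq**2) / (2.0 * mtf_sigma**2))
    out = np.fft.ifftn(np.fft.fftn(volume.data.astype(np.float64)) * mtf).real
    return Volume(out.astype(np.float32), volume.voxel_spacing, volume.provenance)


def add_noise_to_snr(volume: Volume, snr: float | None, seed: int | None = None) -> Volume:
    """Add zero-mean Gaussian noise with variance ``var(signal)/snr``.

    SNR here is the variance-ratio convention. ``None`` (noise-free) is the
    identity; a zero-variance signal has no defined SNR and raises.
    """
    if snr is None:
        return volume.copy()
    if not snr > 0:
        raise ValueError("snr must be positive")
    sig_var = float(volume.data.astype(np.float64).var())
    if sig_var == 0:
        raise ValueError("SNR undefined for a zero-variance (constant) signal")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(sig_var / snr), size=volume.data.shape)
    out = volume.data.astype(np.float64) + noise
    return Volume(out.astype(np.float32), volume.voxel_spacing, volume.provenance)


def wedge_mask(n: int, wedge_angle_deg: float) -> np.ndarray:
    """Boolean mask of the *missing* region in an ``n^3`` FFT grid.

    Single-tilt convention: the specimen tilts about the y-axis, so the
    unmeasured wedge is centred on the k_z axis in the k_x/k_z plane. A
    frequency is missing when the angle between its (k_x, k_z) component and
    the k_z axis is at most ``wedge_angle_deg`` and k_z is nonzero (the
    untilted plane k_z = 0, which carries the DC term, is always measured).
    """
    f = np.fft.fftfreq(n)
    fz, fy, fx = np.meshgrid(f, f, f, indexing="ij")
    theta = np.degrees(np.arctan2(np.abs(fx), np.abs(fz)))
    return (theta <= wedge_angle_deg) & (np.abs(fz) > 0)


def apply_missing_wedge(volume: Volume, wedge_angle_deg: float) -> Volume:
    """Zero all Fourier coefficients inside the missing wedge (idempotent)."""
    if wedge_angle_deg == 0:
        return volume.copy()
    if not 0 <= wedge_angle_deg < 90:
        raise ValueError("wedge_angle_deg must lie in [0, 90)")
    mask = wedge_mask(volume.side, wedge_angle_deg)
    spec = np.fft.fftn(volume.data.astype(np.float64))
    spec[mask] = 0.0
    out = np.fft.ifftn(spec).real
    return Volume(out.astype(np.float32), volume.voxel_spacing, volume.provenance)


def simulate_subtomogram(density: Volume, params: SimulationParams) -> Volume:
    """Full classical pipeline: pose -> MTF -> missing wedge -> noise -> normalize.

    The stage order follows physical acquisition: the particle sits at a
    random orientation, the optics blur it, the limited tilt range removes the
    wedge, and detector/shot noise is added last. With a fixed seed the result
    is a pure function of its inputs.
    """
    seq = np.random.SeedSequence(params.seed)
    pose_seed, noise_seed = seq.spawn(2)
    vol = rotate_translate(
        density, params.rotation, params.translation,
        seed=pose_seed.generate_state(1)[0],
    )
    vol = apply_mtf(vol, params.mtf_sigma)
    vol = apply_missing_wedge(vol, params.wedge_angle_deg)
    if params.snr is not None:
        vol = add_noise_to_snr(vol, params.snr, seed=noise_seed.generate_state(1)[0])
    return normalize_volume(vol, "minmax_sym")


def generate_fixture_datasets(
    n_per_class: int = 10,
    classes: Sequence[str] = TOY_CLASSES,
    size: int = 16,
    params: SimulationParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[DomainDataset, DomainDataset]:
    """Two unpaired, class-balanced domains: clean maps D and subtomograms S.

    Domain D holds normalized clean toy densities at random poses; domain S
    holds *independently* generated and posed instances of the same classes
    pushed through the classical degradation pipeline, so no volume in S is a
    degraded copy of a volume in D. When ``out_dir`` is given, both domains
    and their CSV manifests are written there.

    Returns ``(dataset_D, dataset_S)``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    params = params or SimulationParams()
    root = np.random.SeedSequence(seed)
    seed_d, seed_s = root.spawn(2)

    def build(domain_seq: np.random.SeedSequence, degrade: bool) -> DomainDataset:
        vols, labels = [], []
        child_iter = iter(domain_seq.spawn(len(classes) * n_per_class))
        for cls in classes:
            for _ in range(n_per_class):
                child = next(child_iter)
                s_struct, s_pose, s_sim = (s.generate_state(1)[0] for s in child.spawn(3))
                density = make_toy_density(
                    ToyStructureSpec(cls, size=size, seed=int(s_struct))
                )
                if degrade:
                    p = SimulationParams(
                        snr=params.snr, wedge_angle_deg=params.wedge_angle_deg,
                        mtf_sigma=params.mtf_sigma, rotation=params.rotation,
                        translation=params.translation, seed=int(s_sim),
                    )
                    vols.append(simulate_subtomogram(density, p))
                else:
                    posed = rotate_translate(
                        density, params.rotation, params.translation, seed=int(s_pose)
                    )
                    vols.append(normalize_volume(posed, "minmax_sym"))
                labels.append(cls)
        return DomainDataset(vols, domain="S" if degrade else "D", labels=labels)

    data_d = build(seed_d, degrade=False)
    data_s = build(seed_s, degrade=True)
    if out_dir is not None:
        save_dataset(data_d, out_dir)
        save_dataset(data_s, out_dir)
    return data_d, data_s
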