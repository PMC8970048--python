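"""Cubic 3D volumes, domain datasets and intensity normalization.

A :class:`Volume` holds one cubic grayscale grid — either an experimental-style
subtomogram (domain ``S``) or a clean macromolecule density map (domain ``D``).
Volumes are stored on disk as MRC2014 maps (mode 2, 32-bit float) via gemmi, or
as raw ``.npy`` arrays; datasets are a directory of volumes plus a CSV manifest
with columns ``path,domain,label``.

Generators in this package emit values through a final tanh, so every volume
entering a model is first mapped into ``[-1, 1]`` by :func:`normalize_volume`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "DomainDataset",
    "read_volume",
    "write_volume",
    "normalize_volume",
    "load_dataset",
    "save_dataset",
]

_MRC_SUFFIXES = {".mrc", ".map", ".mrcs", ".ccp4"}
# MRC headers carry cell dimensions in Angstrom; the package convention is nm.
_NM_PER_ANGSTROM = 0.1


@dataclass
class Volume:
    """One cubic ``n x n x n`` grayscale grid with physical voxel spacing.

    Parameters
    ----------
    data:
        Rank-3 float array with equal side lengths.
    voxel_spacing:
        Edge length of one voxel in nanometres (default 1.0).
    provenance:
        Free-text tag describing where the volume came from.
    """

    data: np.ndarray
    voxel_spacing: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be rank-3, got rank {self.data.ndim}")
        nx, ny, nz = self.data.shape
        if not (nx == ny == nz):
            raise ValueError(f"volume must be cubic, got axes {nx}x{ny}x{nz}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")

    @property
    def side(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_spacing, self.provenance)


@dataclass
class DomainDataset:
    """Unordered, unpaired collection of volumes from one domain.

    ``domain`` is ``"S"`` (subtomograms) or ``"D"`` (density maps); ``labels``
    are optional class tags, but when present must cover every volume.
    """

    volumes: list[Volume]
    domain: str
    labels: list[str] | None = None
    manifest_path: Path | None = None

    def __post_init__(self) -> None:
        if self.domain not in ("S", "D"):
            raise ValueError(f"domain must be 'S' or 'D', got {self.domain!r}")
        sides = {v.side for v in self.volumes}
        if len(sides) > 1:
            raise ValueError(f"all volumes must share one side length, got {sorted(sides)}")
        if self.labels is not None and len(self.labels) != len(self.volumes):
            raise ValueError(
                f"labels ({len(self.labels)}) must cover every volume ({len(self.volumes)})"
            )

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def side(self) -> int:
        if not self.volumes:
            raise ValueError("empty dataset has no side length")
        return self.volumes[0].side

    def stack(self) -> np.ndarray:
        """All volumes as one ``(N, n, n, n)`` float32 array."""
        return np.stack([v.data for v in self.volumes]).astype(np.float32)


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a cubic volume from an MRC2014 map or a raw ``.npy`` array.

    Voxel spacing is taken from the MRC header cell when present; ``.npy``
    files default to 1.0 nm. Non-cubic grids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    if path.suffix == ".npy":
        data = np.load(path)
        if data.ndim != 3 or len(set(data.shape)) != 1:
            raise ValueError(
                f"{path} holds a non-cubic grid with axes {'x'.join(map(str, data.shape))}"
            )
        return Volume(data, provenance=str(path))
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable MRC header in {path}: {exc}") from exc
    data = np.array(ccp4.grid, copy=True)
    if data.ndim != 3 or len(set(data.shape)) != 1:
        raise ValueError(
            f"{path} holds a non-cubic grid with axes {'x'.join(map(str, data.shape))}"
        )
    cell = ccp4.grid.unit_cell
    spacing = (cell.a / data.shape[0]) * _NM_PER_ANGSTROM if cell.a > 0 else 1.0
    return Volume(data, voxel_spacing=float(spacing), provenance=str(path))


def write_volume(volume: Volume, path: str | os.PathLike) -> Path:
    """Write a volume as MRC mode 2 (32-bit float) or raw ``.npy``.

    The MRC header cell encodes the voxel spacing, so a write/read round trip
    is voxel-exact and spacing-exact.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    if path.suffix == ".npy":
        np.save(path, volume.data.astype(np.float32))
        return path
    grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data, dtype=np.float32))
    edge = volume.voxel_spacing / _NM_PER_ANGSTROM * volume.side
    grid.unit_cell = gemmi.UnitCell(edge, edge, edge, 90.0, 90.0, 90.0)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    ccp4.write_ccp4_map(str(path))
    return path


def normalize_volume(volume: Volume, mode: str = "minmax_sym") -> Volume:
    """Map intensities into the generator's tanh range ``[-1, 1]``.

    ``minmax_sym`` sends min to -1 and max to +1 linearly; ``zscore_clip``
    standardizes, clips to ±3 sigma and rescales to ``[-1, 1]``. A constant
    volume maps to all zeros in either mode rather than erroring, so synthetic
    edge cases cannot abort a pipeline.
    """
    x = volume.data.astype(np.float64)
    if mode == "minmax_sym":
        lo, hi = x.min(), x.max()
        if hi == lo:
            out = np.zeros_like(x)
        else:
            out = (x - lo) / (hi - lo) * 2.0 - 1.0
    elif mode == "zscore_clip":
        mu, sd = x.mean(), x.std()
        if sd == 0:
            out = np.zeros_like(x)
        else:
            out = np.clip((x - mu) / sd, -3.0, 3.0) / 3.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Volume(out.astype(np.float32), volume.voxel_spacing, volume.provenance)


def save_dataset(dataset: DomainDataset, out_dir: str | os.PathLike,
                 prefix: str | None = None, fmt: str = "mrc") -> Path:
    """Write every volume plus a ``path,domain,label`` CSV manifest.

    Returns the manifest path. ``fmt`` is ``"mrc"`` or ``"npy"``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or dataset.domain.lower()
    suffix = ".mrc" if fmt == "mrc" else ".npy"
    rows = []
    for i, vol in enumerate(dataset.volumes):
        name = f"{prefix}_{i:04d}{suffix}"
        write_volume(vol, out_dir / name)
        label = dataset.labels[i] if dataset.labels is not None else ""
        rows.append({"path": name, "domain": dataset.domain, "label": label})
    manifest = out_dir / f"manifest_{dataset.domain}.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    dataset.manifest_path = manifest
    return manifest


def load_dataset(manifest: str | os.PathLike) -> DomainDataset:
    """Load a dataset from a CSV manifest; paths are relative to the manifest."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest, keep_default_na=False)
    required = {"path", "domain"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    domains = set(df["domain"])
    if len(domains) != 1:
        raise ValueError(f"manifest mixes domains: {sorted(domains)}")
    volumes = [read_volume(manifest.parent / p) for p in df["path"]]
    labels: list[str] | None = None
    if "label" in df.columns:
        raw = [str(x) for x in df["label"]]
        if any(raw):
            labels = raw
    return DomainDataset(volumes, domain=domains.pop(), labels=labels,
                         manifest_path=manifest)
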