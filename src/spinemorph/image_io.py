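"""Volume, seed and result I/O plus Gaussian denoising.

Conventions used throughout the package:

* axis order is ``(z, y, x)`` — axis 0 is the optical (stack) axis, matching
  multi-page TIFF ordering;
* all voxel coordinates are 0-based integer triplets ``(z, y, x)``;
* physical voxel spacing is a per-axis triple in micrometres and is used for
  every path length, width and volume (confocal stacks are anisotropic:
  a typical acquisition is 0.07 um laterally and 0.2 um between planes, so
  ignoring spacing would distort axial lengths by roughly 3x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import ValidationError

SEED_CLASSES = {"spine": 1, "dendrite": 2, "separator": 3}

#: Columns of the per-spine feature table, in output order.
FEATURE_COLUMNS = [
    "spine_id",
    "n_voxels",
    "volume_um3",
    "neck_length_um",
    "min_neck_width_um",
    "avg_head_width_um",
    "spine_length_um",
    "class",
    "flags",
    "cbp_z", "cbp_y", "cbp_x",
    "ch_z", "ch_y", "ch_x",
    "tip_z", "tip_y", "tip_x",
]


@dataclass(frozen=True)
class IntensityVolume:
    """A 3-D scalar image with anisotropic voxel spacing (um), axes (z, y, x)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValidationError(f"volume must be 3-D with all dims >= 1, got shape {data.shape}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValidationError(f"spacing must be 3 positive components, got {self.spacing!r}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", sp)

    @property
    def i_min(self) -> float:
        return float(self.data.min())

    @property
    def i_max(self) -> float:
        return float(self.data.max())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in um^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class SeedSet:
    """User-marked voxels for the spine class, the dendrite class and
    optional separators; the three sets are pairwise disjoint."""

    spine: frozenset
    dendrite: frozenset
    separators: frozenset = frozenset()

    def __post_init__(self):
        sp = frozenset(tuple(map(int, v)) for v in self.spine)
        de = frozenset(tuple(map(int, v)) for v in self.dendrite)
        se = frozenset(tuple(map(int, v)) for v in self.separators)
        for a, b, names in ((sp, de, "spine/dendrite"), (sp, se, "spine/separator"), (de, se, "dendrite/separator")):
            overlap = a & b
            if overlap:
                raise ValidationError(f"seed classes {names} overlap at voxel(s) {sorted(overlap)[:5]}")
        object.__setattr__(self, "spine", sp)
        object.__setattr__(self, "dendrite", de)
        object.__setattr__(self, "separators", se)

    def check_bounds(self, shape: Sequence[int]) -> "SeedSet":
        for name, voxels in (("spine", self.spine), ("dendrite", self.dendrite), ("separator", self.separators)):
            for v in voxels:
                if any(c < 0 or c >= s for c, s in zip(v, shape)):
                    raise ValidationError(f"{name} seed {v} outside volume bounds {tuple(shape)}")
        return self

    def mask(self, shape: Sequence[int], which: str) -> np.ndarray:
        out = np.zeros(tuple(shape), dtype=bool)
        voxels = getattr(self, which)
        if voxels:
            idx = np.array(sorted(voxels))
            out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return out


def read_stack(path, spacing) -> IntensityVolume:
    """Read a single- or multi-page grayscale TIFF as a (z, y, x) volume."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        warnings.warn(f"{path}: single 2-D page, promoting to shape (1, y, x)", stacklevel=2)
        data = data[None]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a grayscale z-stack, got shape {data.shape}")
    return IntensityVolume(data, tuple(spacing))


def write_stack(path, vol: IntensityVolume | np.ndarray) -> Path:
    data = vol.data if isinstance(vol, IntensityVolume) else np.asarray(vol)
    path = Path(path)
    tifffile.imwrite(str(path), data, photometric="minisblack")
    return path


def gaussian_denoise(vol: IntensityVolume, sigma) -> IntensityVolume:
    """Separable Gaussian smoothing with reflect boundary handling.

    ``sigma`` is per-axis in voxels; all-zero sigma returns the input
    unchanged.  Reflect padding avoids dark-edge artifacts that would bias
    the later foreground thresholding.
    """
    sig = tuple(float(s) for s in np.broadcast_to(sigma, (3,)))
    if any(s < 0 for s in sig):
        raise ValidationError(f"sigma must be nonnegative, got {sigma!r}")
    if all(s == 0 for s in sig):
        return vol
    smoothed = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=sig, mode="reflect")
    return IntensityVolume(smoothed, vol.spacing)


def _seeds_from_label_volume(labels: np.ndarray) -> SeedSet:
    groups: dict[int, set] = {1: set(), 2: set(), 3: set()}
    for value in np.unique(labels):
        if value == 0:
            continue
        if int(value) not in groups:
            raise ValidationError(f"seed label volume contains unexpected value {value}")
        coords = np.argwhere(labels == value)
        groups[int(value)].update(map(tuple, coords.tolist()))
    return SeedSet(spine=groups[1], dendrite=groups[2], separators=groups[3])


def read_seeds(path, shape: Sequence[int] | None = None) -> SeedSet:
    """Read seeds from a CSV (columns z,y,x,class) or an integer label TIFF.

    Label volumes use 1=spine, 2=dendrite, 3=separator.  Duplicate voxels
    assigned to two classes are rejected with the offending voxel named.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        seeds = _seeds_from_label_volume(tifffile.imread(str(path)))
    else:
        table = pd.read_csv(path)
        required = {"z", "y", "x", "class"}
        if not required.issubset(table.columns):
            raise ValidationError(f"{path}: seed CSV must have columns z,y,x,class")
        groups: dict[str, set] = {"spine": set(), "dendrite": set(), "separator": set()}
        for _, row in table.iterrows():
            cls = str(row["class"]).strip().lower()
            if cls not in groups:
                raise ValidationError(f"{path}: unknown seed class {cls!r}")
            groups[cls].add((int(row["z"]), int(row["y"]), int(row["x"])))
        seeds = SeedSet(spine=groups["spine"], dendrite=groups["dendrite"], separators=groups["separator"])
    if shape is not None:
        seeds.check_bounds(shape)
    return seeds


def write_seeds(path, seeds: SeedSet) -> Path:
    rows = []
    for cls, voxels in (("spine", seeds.spine), ("dendrite", seeds.dendrite), ("separator", seeds.separators)):
        for z, y, x in sorted(voxels):
            rows.append({"z": z, "y": y, "x": x, "class": cls})
    pd.DataFrame(rows, columns=["z", "y", "x", "class"]).to_csv(path, index=False)
    return Path(path)


def features_table(spines: Iterable) -> pd.DataFrame:
    """Assemble the per-spine feature table (one row per spine region)."""
    rows = []
    for s in spines:
        rows.append(s.feature_row())
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return table


def write_outputs(labels: np.ndarray, spines: Sequence, out_dir, spacing=None) -> dict[str, Path]:
    """Write the label TIFF (0=background, 1=dendrite, 2+i=spine i) and the
    feature CSV to ``out_dir``; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label_path = out_dir / "labels.tif"
    tifffile.imwrite(str(label_path), np.asarray(labels).astype(np.uint16), photometric="minisblack")
    csv_path = out_dir / "features.csv"
    features_table(spines).to_csv(csv_path, index=False)
    return {"labels": label_path, "features": csv_path}
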