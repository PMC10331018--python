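"""From raw lesion volumes to network-ready bags.

Pipeline per case: crop every modality to the in-plane ROI bounding box of
the lesion mask expanded by a metric margin (~10 mm beyond the tumor
boundary), keep only slices where the mask is nonzero, z-score each slice,
resample to 64x64, and re-standardize so every input slice enters the
network with zero mean and unit variance.  Training-time augmentation
applies the same random horizontal/vertical flip to every slice of every
modality of the bag, so instances stay anatomically aligned.

Crop boxes are 0-based half-open [lo, hi) intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from .phantom import MultiModalCase


@dataclass(frozen=True)
class PreprocessConfig:
    margin_mm: float = 10.0
    target_size: int = 64
    augment: bool = False
    augment_prob: float = 0.5
    rotate90: bool = False          # optional extra 90-degree rotation
    interpolation: str = "bilinear"  # or "nearest"

    def validate(self) -> None:
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be >= 0")
        if self.target_size < 8:
            raise ValueError("target_size must be >= 8")
        if not 0.0 <= self.augment_prob <= 1.0:
            raise ValueError("augment_prob must be in [0, 1]")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValueError("interpolation must be nearest or bilinear")


@dataclass
class PreparedBag:
    """Network input: (n_modalities, s', target, target) standardized slices."""

    slices: np.ndarray
    case_id: str
    label: int
    witness: np.ndarray | None = None   # per retained slice: carries signal?

    @property
    def n_slices(self) -> int:
        return self.slices.shape[1]


def crop_roi(case: MultiModalCase, config: PreprocessConfig) -> MultiModalCase:
    """Crop all modalities to the margin-expanded in-plane mask bounding box.

    The mask bounding box is expanded by ceil(margin_mm / pixel_spacing)
    pixels per side (per axis, using that axis' spacing), clipped to the
    volume; slices without lesion are dropped.
    """
    if not case.mask.any():
        raise ValueError(f"case {case.case_id}: empty mask")
    zs, ys, xs = np.nonzero(case.mask)
    my = ceil(config.margin_mm / case.voxel_spacing[1])
    mx = ceil(config.margin_mm / case.voxel_spacing[2])
    y0 = max(int(ys.min()) - my, 0)
    y1 = min(int(ys.max()) + 1 + my, case.mask.shape[1])
    x0 = max(int(xs.min()) - mx, 0)
    x1 = min(int(xs.max()) + 1 + mx, case.mask.shape[2])
    keep = np.unique(zs)
    new_sig = tuple(int(np.searchsorted(keep, z)) for z in case.signal_slices
                    if z in keep)
    return MultiModalCase(
        case_id=case.case_id,
        volumes=[v[keep][:, y0:y1, x0:x1] for v in case.volumes],
        mask=case.mask[keep][:, y0:y1, x0:x1],
        label=case.label,
        voxel_spacing=case.voxel_spacing,
        signal_slices=new_sig)


def normalize_slice(sl: np.ndarray) -> np.ndarray:
    """Z-score with population sd; a constant slice maps to all zeros."""
    sl = np.asarray(sl, dtype=np.float64)
    mu = sl.mean()
    sd = sl.std()
    # guard numerically-constant slices (sd at rounding-noise level)
    if sd <= 1e-12 * max(1.0, abs(mu)):
        return np.zeros_like(sl)
    return (sl - mu) / sd


def resize_slice(sl: np.ndarray, target_size: int,
                 interpolation: str = "bilinear") -> np.ndarray:
    """Resample one 2-D slice to target_size x target_size.

    Bilinear, no anti-alias filter: an exact 2x reduction then equals 2x2
    average pooling, which keeps the slice mean.
    """
    sl = np.asarray(sl, dtype=np.float64)
    if sl.size == 0:
        raise ValueError("cannot resize an empty slice")
    if sl.shape == (target_size, target_size):
        return sl.copy()
    order = 1 if interpolation == "bilinear" else 0
    return resize(sl, (target_size, target_size), order=order,
                  mode="edge", anti_aliasing=False, preserve_range=True)


def prepare_case(case: MultiModalCase, config: PreprocessConfig) -> PreparedBag:
    """crop -> per-slice z-score -> resize -> re-standardize -> stack."""
    config.validate()
    cropped = crop_roi(case, config)
    s = cropped.n_slices
    k = len(cropped.volumes)
    out = np.empty((k, s, config.target_size, config.target_size))
    for ki, vol in enumerate(cropped.volumes):
        for z in range(s):
            sl = resize_slice(normalize_slice(vol[z]), config.target_size,
                              config.interpolation)
            out[ki, z] = normalize_slice(sl)
    witness = np.zeros(s, dtype=bool)
    witness[list(cropped.signal_slices)] = True
    return PreparedBag(slices=out, case_id=case.case_id, label=case.label,
                       witness=witness)


def augment_bag(bag: PreparedBag, rng: np.random.Generator,
                config: PreprocessConfig) -> PreparedBag:
    """Random flips (and optional 90-degree rotation), identical across the bag.

    Two independent draws: horizontal flip with probability augment_prob,
    vertical flip with probability augment_prob.  Per-slice histograms are
    unchanged since flips only permute pixels.
    """
    sl = bag.slices
    if rng.random() < config.augment_prob:
        sl = sl[..., ::-1]            # horizontal flip (last axis = x)
    if rng.random() < config.augment_prob:
        sl = sl[..., ::-1, :]         # vertical flip (y axis)
    if config.rotate90 and rng.random() < config.augment_prob:
        sl = np.rot90(sl, axes=(-2, -1))
    return replace(bag, slices=np.ascontiguousarray(sl))


def prepare_cohort(cases: list[MultiModalCase],
                   config: PreprocessConfig) -> list[PreparedBag]:
    return [prepare_case(c, config) for c in cases]


# ---------------------------------------------------------------------------
# prepared-bag storage: one array archive per case + index CSV
# ---------------------------------------------------------------------------

def write_prepared(bags: list[PreparedBag], out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for bag in bags:
        p = out_dir / f"{bag.case_id}.npz"
        np.savez_compressed(p, slices=bag.slices.astype(np.float32),
                            witness=bag.witness, label=bag.label)
        rows.append({"case_id": bag.case_id, "label": bag.label,
                     "n_slices": bag.n_slices, "path": p.name})
    index = out_dir / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def read_prepared(index_path) -> list[PreparedBag]:
    index_path = Path(index_path)
    if not index_path.exists():
        raise FileNotFoundError(f"index not found: {index_path}")
    root = index_path.parent
    df = pd.read_csv(index_path)
    bags = []
    for _, row in df.iterrows():
        p = root / row["path"]
        if not p.exists():
            raise FileNotFoundError(f"prepared bag missing: {p}")
        npz = np.load(p)
        bags.append(PreparedBag(
            slices=npz["slices"].astype(np.float64),
            case_id=str(row["case_id"]), label=int(row["label"]),
            witness=npz["witness"].astype(bool)))
    return bags
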