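"""Synthetic multi-modality lesion phantoms with controlled MIL structure.

Each phantom case mimics one patient's cropped liver lesion: an ellipsoidal
lesion mask over a short stack of axial slices, observed in five
co-registered MRI sequences (T2, arterial, venous, delay, ADC).  A
*positive* bag carries a localized signal motif — a Gaussian intensity blob
at a random in-mask location — on a `witness_rate` fraction of its slices,
scaled per modality by `modality_signal_weights`; a negative bag has no
motif anywhere.  Independent Gaussian pixel noise is added everywhere, so
the bag label is decidable only from the witness slices, which is exactly
the MIL assumption (bag positive iff at least one instance is positive).

The default modality weights are arterial-dominant, so a correctly working
modality-attention module should learn to upweight the arterial channel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .model import MODALITY_NAMES

#: arterial-dominant relative informativeness of (t2, arterial, venous, delay, adc)
DEFAULT_MODALITY_WEIGHTS = (0.3, 1.0, 0.7, 0.4, 0.5)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic cohort.

    Defaults give a balanced 100-case cohort with a 5:1 signal-to-noise
    amplitude ratio and half of the slices of each positive bag carrying
    signal.  Slice spacing is coarse (5 mm) relative to in-plane spacing
    (1 mm), as in abdominal MRI, so mm-based margins are anisotropic.
    """

    n_cases: int = 100
    positive_fraction: float = 0.5
    slice_range: tuple[int, int] = (3, 8)
    image_size: int = 96
    n_modalities: int = 5
    modality_signal_weights: tuple[float, ...] = DEFAULT_MODALITY_WEIGHTS
    witness_rate: float = 0.5
    signal_amplitude: float = 5.0
    noise_sd: float = 1.0
    voxel_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        lo, hi = self.slice_range
        if lo < 1 or hi < lo:
            raise ValueError("slice_range must satisfy 1 <= min <= max")
        if not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must be in (0, 1]")
        if self.signal_amplitude < 0:
            raise ValueError("signal_amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        w = np.asarray(self.modality_signal_weights, dtype=float)
        if len(w) != self.n_modalities or (w < 0).any() or not (w > 0).any():
            raise ValueError("modality_signal_weights must be non-negative "
                             "with at least one positive entry, one per modality")


@dataclass
class MultiModalCase:
    """One patient bag: co-registered modality volumes, lesion mask, label."""

    case_id: str
    volumes: list[np.ndarray]          # n_modalities arrays, each (s, H, W)
    mask: np.ndarray                   # (s, H, W) binary lesion support
    label: int
    voxel_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    signal_slices: tuple[int, ...] = ()  # generator metadata: witness slices

    def validate(self) -> None:
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1 or self.mask.shape not in shapes:
            raise ValueError("all volumes and the mask must share one shape")
        if not self.mask.any():
            raise ValueError("empty lesion mask")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def n_slices(self) -> int:
        return self.mask.shape[0]


def _ellipsoid_mask(s: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Ellipsoidal lesion support; every one of the s slices is nonempty."""
    cy = size / 2 + rng.uniform(-size * 0.05, size * 0.05)
    cx = size / 2 + rng.uniform(-size * 0.05, size * 0.05)
    ry = rng.uniform(0.15, 0.30) * size
    rx = rng.uniform(0.15, 0.30) * size
    rz = s / 2.0 + 1.0          # > s/2 so the end slices keep area
    zc = (s - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((s, size, size), dtype=np.uint8)
    for z in range(s):
        shrink = np.sqrt(max(1.0 - ((z - zc) / rz) ** 2, 0.0))
        mask[z] = (((yy - cy) / (ry * shrink)) ** 2
                   + ((xx - cx) / (rx * shrink)) ** 2) <= 1.0
    return mask


def _gaussian_blob(size: int, cy: float, cx: float, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))


def generate_case(config: PhantomConfig, case_id: str, label: int,
                  rng: np.random.Generator) -> MultiModalCase:
    """Draw one bag: lesion mask, per-modality noise, optional witness motifs."""
    lo, hi = config.slice_range
    s = int(rng.integers(lo, hi + 1))
    size = config.image_size
    mask = _ellipsoid_mask(s, size, rng)
    sigma = max(2.0, size / 16.0)
    weights = np.asarray(config.modality_signal_weights, dtype=float)

    signal = np.zeros((s, size, size))
    witness: tuple[int, ...] = ()
    if label == 1:
        n_witness = max(1, int(round(config.witness_rate * s)))
        witness = tuple(sorted(rng.choice(s, size=n_witness, replace=False).tolist()))
        for z in witness:
            ys, xs = np.nonzero(mask[z])
            j = int(rng.integers(len(ys)))
            signal[z] = _gaussian_blob(size, ys[j], xs[j], sigma) * mask[z]

    volumes = []
    for k in range(config.n_modalities):
        noise = rng.normal(0.0, config.noise_sd, (s, size, size))
        vol = noise + config.signal_amplitude * weights[k] * signal
        volumes.append(vol.astype(np.float32))
    return MultiModalCase(case_id=case_id, volumes=volumes, mask=mask,
                          label=label, voxel_spacing=config.voxel_spacing,
                          signal_slices=witness)


def generate_cohort(config: PhantomConfig) -> list[MultiModalCase]:
    """Generate the full cohort, exactly stratified and seed-deterministic.

    The number of positives is round(positive_fraction * n_cases); labels
    are assigned to shuffled case slots so positives and negatives
    interleave.  All randomness flows from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pos = int(round(config.positive_fraction * config.n_cases))
    labels = np.array([1] * n_pos + [0] * (config.n_cases - n_pos))
    rng.shuffle(labels)
    width = len(str(config.n_cases))
    return [generate_case(config, f"case_{i:0{width}d}", int(labels[i]), rng)
            for i in range(config.n_cases)]


# ---------------------------------------------------------------------------
# on-disk layout: NIfTI volumes + CSV manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["case_id", "label", *MODALITY_NAMES, "mask", "signal_slices"]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_cohort(cases: list[MultiModalCase], out_dir) -> Path:
    """Write one .nii.gz per modality and mask per case, plus manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        case.validate()
        aff = _affine(case.voxel_spacing)
        row = {"case_id": case.case_id, "label": case.label,
               "signal_slices": ";".join(map(str, case.signal_slices))}
        for name, vol in zip(MODALITY_NAMES, case.volumes):
            p = out_dir / f"{case.case_id}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), p)
            row[name] = p.name
        p = out_dir / f"{case.case_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(case.mask.astype(np.uint8), aff), p)
        row["mask"] = p.name
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[MultiModalCase]:
    """Load a cohort back from its manifest; missing files raise."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False)
    cases = []
    for _, row in df.iterrows():
        vols = []
        for name in MODALITY_NAMES:
            p = root / row[name]
            if not p.exists():
                raise FileNotFoundError(
                    f"volume listed in manifest is missing: {p}")
            img = nib.load(p)
            vols.append(np.asarray(img.dataobj, dtype=np.float32))
        mask_p = root / row["mask"]
        if not mask_p.exists():
            raise FileNotFoundError(f"mask listed in manifest is missing: {mask_p}")
        mask_img = nib.load(mask_p)
        spacing = tuple(float(z) for z in mask_img.header.get_zooms()[:3])
        sig = tuple(int(t) for t in str(row["signal_slices"]).split(";") if t != "")
        cases.append(MultiModalCase(
            case_id=str(row["case_id"]),
            volumes=vols,
            mask=np.asarray(mask_img.dataobj).astype(np.uint8),
            label=int(row["label"]),
            voxel_spacing=spacing,
            signal_slices=sig))
    return cases


def config_to_dict(config: PhantomConfig) -> dict:
    return dataclasses.asdict(config)
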