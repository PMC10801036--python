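"""Deterministic multi-modal tumor phantoms with nested sub-regions.

Each phantom emulates the structure of a BraTS case at desk scale: four
co-registered modality channels (FLAIR / T1 / T1-CE / T2 analogs), an integer
label mask with the nested tumor sub-regions — enhancing tumor (label 4)
innermost, necrotic core ring (label 1), edema ring (label 2) — and heavy
background imbalance.  Geometry is a randomly deformed, anisotropically
scaled concentric ellipse (ellipsoid in 3-D); sharing one deformation field
across the three rings guarantees the nesting ET ⊆ TC ⊆ WT by construction.

Intensities are drawn per modality from a region mean table plus Gaussian
noise; the defaults make edema bright in the FLAIR analog and enhancing
tumor bright in the T1-CE analog, echoing the real modality contrasts.  All
randomness flows from explicit seeds, so the same configuration and seed
reproduce a case bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import DEFAULT_MODALITIES, MultiModalVolume, zscore
from .pseudo_label import ClassSchedule

__all__ = ["PhantomConfig", "Benchmark", "generate_case", "generate_dataset",
           "make_benchmark", "DEFAULT_INTENSITY_TABLE"]

#: Per-region mean intensity for (FLAIR, T1, T1CE, T2) analog channels.
DEFAULT_INTENSITY_TABLE: dict[int, tuple[float, ...]] = {
    0: (0.20, 0.30, 0.25, 0.20),  # background / normal tissue
    2: (0.90, 0.40, 0.35, 0.70),  # edema: bright in the FLAIR analog
    1: (0.50, 0.25, 0.30, 0.55),  # necrotic core
    4: (0.60, 0.50, 0.95, 0.60),  # enhancing: bright in the T1-CE analog
}


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, ...] = (64, 64)
    n_modalities: int = 4
    region_intensity_table: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_TABLE)
    )
    noise_sd: float = 0.05
    deformation_amplitude: float = 0.12
    #: fraction of the min spatial extent taken by the whole-tumor radius
    whole_radius_frac: float = 0.16
    core_frac: float = 0.65       # core radius as fraction of whole radius
    enhancing_frac: float = 0.35  # enhancing radius as fraction of whole radius
    class_labels: tuple[int, ...] = (1, 2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lab, means in self.region_intensity_table.items():
            if not all(np.isfinite(means)):
                raise ValueError(f"intensity table for label {lab} not finite")
        if self.whole_radius_frac * max(self.shape) * 1.5 > min(self.shape):
            raise ValueError("region radii exceed the grid")


def _labels_from_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    ndim = len(cfg.shape)
    extent = min(cfg.shape)
    center = [
        s / 2 + rng.uniform(-s / 8, s / 8) for s in cfg.shape
    ]
    aniso = rng.uniform(0.85, 1.15, size=ndim)
    size_jitter = rng.uniform(0.85, 1.15)
    r_whole = cfg.whole_radius_frac * extent * size_jitter

    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in cfg.shape],
                        indexing="ij")
    offs = [(g - c) / a for g, c, a in zip(grids, center, aniso)]
    rho = np.sqrt(sum(o ** 2 for o in offs))

    # one low-order angular deformation shared by all rings keeps nesting
    theta = np.arctan2(offs[1], offs[0])
    deform = np.ones_like(theta)
    for k in range(2, 5):
        amp = cfg.deformation_amplitude * rng.uniform(-1, 1) / (k - 1)
        phase = rng.uniform(0, 2 * np.pi)
        deform += amp * np.cos(k * theta + phase)
    deform = np.clip(deform, 0.5, 1.5)

    labels = np.zeros(cfg.shape, dtype=np.int16)
    labels[rho <= r_whole * deform] = 2
    labels[rho <= r_whole * cfg.core_frac * deform] = 1
    labels[rho <= r_whole * cfg.enhancing_frac * deform] = 4
    return labels


def generate_case(
    cfg: PhantomConfig, case_seed: int
) -> tuple[MultiModalVolume, np.ndarray]:
    """One phantom: modality channels ``M x (spatial)`` plus an integer mask."""
    rng = np.random.default_rng(case_seed)
    labels = _labels_from_geometry(cfg, rng)
    channels = np.empty((cfg.n_modalities, *cfg.shape), dtype=float)
    table = cfg.region_intensity_table
    for mi in range(cfg.n_modalities):
        chan = np.full(cfg.shape, table[0][mi], dtype=float)
        for lab in cfg.class_labels:
            chan[labels == lab] = table[lab][mi]
        channels[mi] = chan
    channels += rng.normal(0.0, cfg.noise_sd, size=channels.shape)
    names = DEFAULT_MODALITIES if cfg.n_modalities == 4 else tuple(
        f"mod{i}" for i in range(cfg.n_modalities)
    )
    return MultiModalVolume(channels, np.eye(4), names), labels


def generate_dataset(
    cfg: PhantomConfig, n_cases: int, seed: int, out_dir: str | Path
) -> dict:
    """Write ``n_cases`` phantoms as uncompressed NIfTI plus a JSON manifest.

    Per-case seeds are drawn deterministically from ``seed``; re-running with
    the same arguments reproduces every file byte for byte (fixed headers,
    no compression timestamps).
    """
    from .io_cli import write_nifti  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=n_cases)
    manifest = {"config_seed": seed, "n_cases": n_cases, "cases": []}
    for i, cs in enumerate(case_seeds):
        vol, labels = generate_case(cfg, int(cs))
        case_id = f"case_{i:04d}"
        img_path = out_dir / f"{case_id}_image.nii"
        lab_path = out_dir / f"{case_id}_mask.nii"
        # modalities stacked on the last axis, BraTS style
        write_nifti(np.moveaxis(vol.channels, 0, -1), vol.affine, img_path)
        write_nifti(labels.astype(np.int16), vol.affine, lab_path)
        hist = {int(k): int(v) for k, v in zip(*np.unique(labels, return_counts=True))}
        manifest["cases"].append(
            {"id": case_id, "seed": int(cs), "image": img_path.name,
             "mask": lab_path.name, "label_histogram": hist}
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


@dataclass
class Benchmark:
    """In-memory train/val split plus the incremental class schedule."""

    train: list[tuple[np.ndarray, np.ndarray]]
    val: list[tuple[np.ndarray, np.ndarray]]
    schedule: ClassSchedule
    config: PhantomConfig


def make_benchmark(
    schedule: Sequence[Sequence[int]] = ((1, 2), (4,)),
    n_train: int = 40,
    n_val: int = 10,
    seed: int = 0,
    cfg: PhantomConfig | None = None,
) -> Benchmark:
    """Default two-step continual benchmark: learn {necrotic, edema}, then
    {enhancing}.

    Images are z-score standardized per modality (the training-ready form);
    masks keep the full label set — the trainer remaps them per step.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_train + n_val)

    def build(case_seed: int) -> tuple[np.ndarray, np.ndarray]:
        vol, labels = generate_case(cfg, int(case_seed))
        std = zscore(vol)
        return std.channels.astype(np.float32), labels

    cases = [build(s) for s in seeds]
    return Benchmark(
        train=cases[:n_train],
        val=cases[n_train:],
        schedule=ClassSchedule(schedule),
        config=cfg,
    )
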