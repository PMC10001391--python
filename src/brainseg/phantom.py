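"""Synthetic BraTS-shaped phantoms with nested tumor compartments.

Each phantom is four co-registered modality volumes plus a label volume on
the BraTS file coding {0, 1, 2, 4}. The tumor is three nested ellipsoids:
an outer edema shell (2), an enhancing rim (4) and a necrotic centre (1),
all inside an elliptical "brain". Modality contrasts are chosen so t1ce is
brightest in the enhancing rim and flair brightest in edema — the clinical
appearance the network relies on — with additive Gaussian noise on top.
These phantoms exercise every pipeline stage without any download; they make
no claim to MRI physics realism.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .preprocess import MODALITIES, ModalityVolume

#: per-modality mean intensity of (brain tissue, necrotic core, edema, enhancing rim)
DEFAULT_CONTRASTS = {
    "t1":    {"brain": 1.0, "necrotic": 0.4, "edema": 0.7, "enhancing": 0.9},
    "t1ce":  {"brain": 1.0, "necrotic": 0.3, "edema": 0.8, "enhancing": 1.8},
    "t2":    {"brain": 0.8, "necrotic": 1.2, "edema": 1.4, "enhancing": 1.0},
    "flair": {"brain": 0.9, "necrotic": 1.0, "edema": 1.8, "enhancing": 1.1},
}

BRATS_SHAPE = (240, 240, 155)


class PhantomConfigError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise of one synthetic case.

    ``radii`` are the in-plane semi-axes (voxels) of the whole-tumor, core
    and enhancing-rim ellipsoids, strictly decreasing; the through-plane
    semi-axis is scaled by D/H so the default phantom keeps its aspect.
    """

    shape: tuple = (64, 64, 32)
    brain_radius: float = 0.46          # fraction of H
    tumor_center: tuple | None = None   # voxel triple; default: volume centre
    radii: tuple | None = None          # default: (0.20, 0.125, 0.06) of H
    modality_contrasts: dict = field(default_factory=lambda: {
        m: dict(v) for m, v in DEFAULT_CONTRASTS.items()})
    noise_std: float = 0.05
    seed: int = 0

    def __post_init__(self):
        h, w, d = self.shape
        if self.tumor_center is None:
            self.tumor_center = (h / 2.0, w / 2.0, d / 2.0)
        if self.radii is None:
            self.radii = (0.20 * h, 0.125 * h, 0.06 * h)
        if not (self.radii[0] > self.radii[1] > self.radii[2] > 0):
            raise PhantomConfigError(f"radii must be strictly decreasing, got {self.radii}")
        if self.noise_std < 0:
            raise PhantomConfigError(f"noise_std must be >= 0, got {self.noise_std}")
        cx, cy, _ = self.tumor_center
        offset = np.hypot(cx - h / 2.0, cy - w / 2.0)
        if offset + self.radii[0] > self.brain_radius * h:
            raise PhantomConfigError(
                "whole-tumor ellipsoid does not fit inside the brain mask")


def _ellipsoid_distance(shape, center, z_scale):
    h, w, d = shape
    x = np.arange(h)[:, None, None] - center[0]
    y = np.arange(w)[None, :, None] - center[1]
    z = (np.arange(d)[None, None, :] - center[2]) / z_scale
    return np.sqrt(x * x + y * y + z * z)


def generate_phantom(config: PhantomConfig | None = None
                     ) -> tuple[dict[str, ModalityVolume], np.ndarray]:
    """Generate one case: {modality: ModalityVolume} plus a label volume.

    The label volume uses BraTS file codes: necrotic centre 1, edema shell 2,
    enhancing rim 4, nested so EnT ⊆ TC ⊆ WT. Deterministic under the
    config seed.
    """
    config = config or PhantomConfig()
    h, w, d = config.shape
    z_scale = max(d / h, 1e-6)
    rng = np.random.default_rng(config.seed)

    brain_center = (h / 2.0, w / 2.0, d / 2.0)
    brain = _ellipsoid_distance(config.shape, brain_center, z_scale) <= config.brain_radius * h
    dist = _ellipsoid_distance(config.shape, config.tumor_center, z_scale)
    r_whole, r_core, r_enh = config.radii

    labels = np.zeros(config.shape, dtype=np.int16)
    labels[dist <= r_whole] = 2       # edema shell (outermost tumor tissue)
    labels[dist <= r_core] = 4        # enhancing rim
    labels[dist <= r_enh] = 1         # necrotic centre
    labels[~brain] = 0

    volumes = {}
    for modality in MODALITIES:
        contrast = config.modality_contrasts[modality]
        vox = np.zeros(config.shape, dtype=np.float64)
        vox[brain] = contrast["brain"]
        vox[labels == 2] = contrast["edema"]
        vox[labels == 4] = contrast["enhancing"]
        vox[labels == 1] = contrast["necrotic"]
        vox += rng.normal(0.0, config.noise_std, size=config.shape)
        vox[~brain] = np.abs(vox[~brain]) * 0.01  # near-zero air background
        volumes[modality] = ModalityVolume(vox, modality)
    return volumes, labels


def generate_dataset(n_cases: int, config: PhantomConfig | None = None, seed: int = 0,
                     jitter: float = 0.15) -> list[tuple[dict[str, ModalityVolume], np.ndarray]]:
    """``n_cases`` phantoms with per-case jittered geometry, all seeded from ``seed``."""
    base = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        scale = 1.0 + jitter * rng.uniform(-1.0, 1.0)
        h = base.shape[0]
        cx = h / 2.0 + rng.uniform(-0.05, 0.05) * h
        cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
        cfg = PhantomConfig(
            shape=base.shape,
            brain_radius=base.brain_radius,
            tumor_center=(cx, cy, base.shape[2] / 2.0),
            radii=tuple(r * scale for r in base.radii),
            modality_contrasts={m: dict(v) for m, v in base.modality_contrasts.items()},
            noise_std=base.noise_std,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(generate_phantom(cfg))
    return cases


# -- NIfTI round trip ---------------------------------------------------------


def write_case(volumes: dict[str, ModalityVolume], labels: np.ndarray, directory: str,
               case_id: str = "case", compress: bool = True) -> list[str]:
    """Write one case with BraTS suffix naming; returns the file paths."""
    import nibabel as nib

    os.makedirs(directory, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    paths = []
    for modality, volume in volumes.items():
        path = os.path.join(directory, f"{case_id}_{modality}{ext}")
        nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), np.eye(4)), path)
        paths.append(path)
    seg_path = os.path.join(directory, f"{case_id}_seg{ext}")
    nib.save(nib.Nifti1Image(np.asarray(labels).astype(np.int16), np.eye(4)), seg_path)
    paths.append(seg_path)
    return paths


def read_case(directory: str) -> tuple[dict[str, ModalityVolume], np.ndarray | None]:
    """Load a BraTS-style case directory; errors name any missing modality suffix."""
    import nibabel as nib

    entries = sorted(os.listdir(directory))
    found: dict[str, str] = {}
    for name in entries:
        stem = name
        for ext in (".nii.gz", ".nii"):
            if stem.endswith(ext):
                stem = stem[: -len(ext)]
                for suffix in MODALITIES + ("seg",):
                    if stem.endswith("_" + suffix):
                        found.setdefault(suffix, os.path.join(directory, name))
                break
    missing = [f"_{m}" for m in MODALITIES if m not in found]
    if missing:
        raise FileNotFoundError(
            f"case directory {directory!r} is missing modality files with suffixes: "
            + ", ".join(missing))
    volumes = {
        m: ModalityVolume(np.asanyarray(nib.load(found[m]).dataobj).astype(np.float64), m)
        for m in MODALITIES
    }
    labels = None
    if "seg" in found:
        labels = np.asanyarray(nib.load(found["seg"]).dataobj).astype(np.int16)
    return volumes, labels
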