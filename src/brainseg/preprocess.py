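"""From 3D multi-modal NIfTI volumes to normalised 2D network inputs.

The pipeline mirrors routine BraTS slice preparation: pick one axial slice
per modality, centre-crop to the network size, Gaussian-denoise, z-score each
channel, and stack the three modalities the network consumes in the fixed
order ``[t1, t1ce, t2]``. Label volumes ride along through the geometric
steps only, and the sparse BraTS file code 4 (enhancing tumor) is remapped to
the contiguous internal class 3 so a 4-way softmax can index classes densely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

MODALITIES = ("t1", "t1ce", "t2", "flair")
#: channel order of the network input
CHANNEL_ORDER = ("t1", "t1ce", "t2")
#: internal per-pixel classes (dense); file code 4 maps to 3
CLASS_CODES = {0: "background", 1: "necrotic core", 2: "edema/non-enhancing", 3: "enhancing"}
FILE_LABEL_VALUES = (0, 1, 2, 4)
NETWORK_SIZE = 224


class AlignmentError(ValueError):
    """Shapes or modality tags of paired inputs do not match."""


@dataclass
class ModalityVolume:
    """One co-registered 3D MRI acquisition."""

    voxels: np.ndarray
    modality: str
    voxel_spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if not all(s > 0 for s in self.voxels.shape):
            raise ValueError(f"degenerate volume shape {self.voxels.shape}")
        if not np.isfinite(self.voxels).all():
            raise ValueError("volume contains non-finite intensities")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")

    @property
    def depth(self) -> int:
        return self.voxels.shape[2]


@dataclass
class MultiModalSlice:
    """H×W×3 network input in modality order [t1, t1ce, t2]."""

    pixels: np.ndarray
    channel_order: tuple = CHANNEL_ORDER
    normalized: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got {self.pixels.shape}")
        if tuple(self.channel_order) != CHANNEL_ORDER:
            raise ValueError(f"channel order must be {CHANNEL_ORDER}")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class SegLabelMap:
    """Per-pixel tumor-compartment labels using the dense internal codes."""

    labels: np.ndarray
    class_codes: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"expected a 2D label map, got ndim={self.labels.ndim}")
        bad = set(np.unique(self.labels)) - set(self.class_codes)
        if bad:
            raise ValueError(f"unexpected label values {sorted(bad)}")


def remap_labels_from_file(labels: np.ndarray) -> np.ndarray:
    """BraTS file codes {0,1,2,4} -> dense internal classes {0,1,2,3}."""
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - set(FILE_LABEL_VALUES)
    if bad:
        raise ValueError(f"unexpected file label values {sorted(bad)}")
    out = labels.copy()
    out[labels == 4] = 3
    return out


def remap_labels_to_file(labels: np.ndarray) -> np.ndarray:
    """Dense internal classes {0,1,2,3} -> BraTS file codes {0,1,2,4}."""
    labels = np.asarray(labels)
    out = labels.copy()
    out[labels == 3] = 4
    return out


def extract_slice(volume: ModalityVolume | np.ndarray, index: int | None = None) -> np.ndarray:
    """Return the axial plane at ``index``.

    The default index is 90 for the canonical 155-slice BraTS depth (the
    slice where all tumor compartments are typically visible) and the middle
    plane ``floor(D/2)`` otherwise.
    """
    voxels = volume.voxels if isinstance(volume, ModalityVolume) else np.asarray(volume)
    depth = voxels.shape[2]
    if index is None:
        index = 90 if depth == 155 else depth // 2
    if not 0 <= index < depth:
        raise IndexError(f"slice index {index} out of range for volume depth {depth}")
    return voxels[:, :, index]


def crop_center(slice2d: np.ndarray, target: int = NETWORK_SIZE) -> np.ndarray:
    """Centred ``target``×``target`` window; odd margins favour the trailing side."""
    slice2d = np.asarray(slice2d)
    h, w = slice2d.shape[:2]
    if target > h or target > w:
        raise ValueError(f"crop target {target} exceeds slice shape ({h}, {w})")
    top = (h - target) // 2
    left = (w - target) // 2
    return slice2d[top:top + target, left:left + target]


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """(i - mean) / population-std; rejects constant images rather than emit NaN."""
    image = np.asarray(image, dtype=np.float64)
    sigma = image.std()
    if sigma == 0:
        raise ValueError("cannot z-score a constant image (zero standard deviation)")
    return (image - image.mean()) / sigma


def gaussian_denoise(image: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """Gaussian blur with standard deviation ``sigma`` pixels; 0 is a no-op."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma)


def _untag(arg, expected: str) -> np.ndarray:
    if isinstance(arg, tuple) and len(arg) == 2 and isinstance(arg[0], str):
        tag, arr = arg
        if tag != expected:
            raise AlignmentError(f"modality tag mismatch: got {tag!r} where {expected!r} required")
        return np.asarray(arr)
    return np.asarray(arg)


def assemble_input(t1, t1ce, t2, normalized: bool = True) -> MultiModalSlice:
    """Stack the three prepared channels in the fixed order [t1, t1ce, t2].

    Each argument may be a bare 2D array or a ``(modality, array)`` pair; a
    tagged array supplied under the wrong parameter is rejected.
    """
    arrays = [_untag(t1, "t1"), _untag(t1ce, "t1ce"), _untag(t2, "t2")]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise AlignmentError(f"channel shapes differ: {[a.shape for a in arrays]}")
    return MultiModalSlice(np.stack(arrays, axis=-1), normalized=normalized)


def preprocess_slices(slices: dict[str, np.ndarray], target: int = NETWORK_SIZE,
                      sigma: float = 0.5) -> MultiModalSlice:
    """Crop → denoise → z-score each required modality, then stack."""
    prepared = {}
    for mod in CHANNEL_ORDER:
        if mod not in slices:
            raise KeyError(f"missing modality {mod!r}; need {CHANNEL_ORDER}")
        prepared[mod] = zscore_normalize(gaussian_denoise(crop_center(slices[mod], target), sigma))
    return assemble_input(prepared["t1"], prepared["t1ce"], prepared["t2"])


def preprocess_case(volumes: dict[str, ModalityVolume], labels: np.ndarray | None = None,
                    slice_index: int | None = None, target: int = NETWORK_SIZE,
                    sigma: float = 0.5) -> tuple[MultiModalSlice, SegLabelMap | None]:
    """Full chain for one case: slice, crop, denoise, normalise, stack.

    ``labels`` (file codes {0,1,2,4}, same grid as the volumes) goes through
    the geometric steps only and is remapped to internal classes.
    """
    slices = {mod: extract_slice(vol, slice_index) for mod, vol in volumes.items()}
    mm = preprocess_slices(slices, target=target, sigma=sigma)
    seg = None
    if labels is not None:
        lab = crop_center(extract_slice(labels, slice_index), target)
        seg = SegLabelMap(remap_labels_from_file(lab).astype(np.int64))
    return mm, seg


# -- augmentation -------------------------------------------------------------


def _translate(arr: np.ndarray, dy: int, dx: int, order_axis0_first=True) -> np.ndarray:
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    ys, yd = (slice(dy, h), slice(0, h - dy)) if dy >= 0 else (slice(0, h + dy), slice(-dy, h))
    xs, xd = (slice(dx, w), slice(0, w - dx)) if dx >= 0 else (slice(0, w + dx), slice(-dx, w))
    out[ys, xs] = arr[yd, xd]
    return out


def augment(mm: MultiModalSlice, mask: SegLabelMap, seed: int = 0,
            noise_std: float = 0.05, max_shift: int = 10) -> list[tuple[MultiModalSlice, SegLabelMap]]:
    """Original plus flipped / rotated / noised / translated copies.

    Geometric transforms are applied identically to image and mask (labels
    stay integers — flips, right-angle rotations and integer shifts are pixel
    permutations or zero-fills, so no interpolation touches them); additive
    Gaussian noise perturbs the image only. Deterministic for a fixed seed.
    """
    if mm.pixels.shape[:2] != mask.labels.shape:
        raise AlignmentError(
            f"slice {mm.pixels.shape[:2]} and mask {mask.labels.shape} are not aligned")
    rng = np.random.default_rng(seed)
    img, lab = mm.pixels, mask.labels
    out = [(mm, mask)]

    def emit(i, m):
        out.append((MultiModalSlice(np.ascontiguousarray(i), normalized=mm.normalized),
                    SegLabelMap(np.ascontiguousarray(m))))

    emit(img[:, ::-1], lab[:, ::-1])                       # horizontal flip
    emit(img[::-1, :], lab[::-1, :])                       # vertical flip
    for k in (1, 2, 3):                                    # 90/180/270 degrees
        emit(np.rot90(img, k, axes=(0, 1)), np.rot90(lab, k, axes=(0, 1)))
    emit(img + rng.normal(0.0, noise_std, img.shape), lab)  # noise, image only
    dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
    emit(_translate(img, int(dy), int(dx)), _translate(lab, int(dy), int(dx)))
    return out


# -- file IO for preprocessed pairs -------------------------------------------


def save_pair(path: str, mm: MultiModalSlice, mask: SegLabelMap | None = None):
    """Persist a preprocessed pair; format chosen by extension (.npz or .nii[.gz])."""
    path = str(path)
    if path.endswith(".npz"):
        arrays = {"pixels": mm.pixels, "normalized": np.array(mm.normalized)}
        if mask is not None:
            arrays["labels"] = remap_labels_to_file(mask.labels)
        np.savez(path, **arrays)
    elif path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        stem = path[:-7] if path.endswith(".nii.gz") else path[:-4]
        ext = ".nii.gz" if path.endswith(".nii.gz") else ".nii"
        nib.save(nib.Nifti1Image(mm.pixels.astype(np.float32), np.eye(4)), stem + "_img" + ext)
        if mask is not None:
            nib.save(nib.Nifti1Image(remap_labels_to_file(mask.labels).astype(np.int16),
                                     np.eye(4)), stem + "_seg" + ext)
    else:
        raise ValueError(f"unsupported extension on {path!r} (use .npz, .nii or .nii.gz)")


def load_pair(path: str) -> tuple[MultiModalSlice, SegLabelMap | None]:
    path = str(path)
    if path.endswith(".npz"):
        data = np.load(path)
        mm = MultiModalSlice(data["pixels"], normalized=bool(data["normalized"]))
        mask = None
        if "labels" in data:
            mask = SegLabelMap(remap_labels_from_file(data["labels"]).astype(np.int64))
        return mm, mask
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        stem = path[:-7] if path.endswith(".nii.gz") else path[:-4]
        ext = ".nii.gz" if path.endswith(".nii.gz") else ".nii"
        mm = MultiModalSlice(np.asanyarray(nib.load(stem + "_img" + ext).dataobj),
                             normalized=True)
        mask = None
        try:
            lab = np.asanyarray(nib.load(stem + "_seg" + ext).dataobj)
            mask = SegLabelMap(remap_labels_from_file(lab).astype(np.int64))
        except FileNotFoundError:
            pass
        return mm, mask
    raise ValueError(f"unsupported extension on {path!r}")
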