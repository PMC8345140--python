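"""Dataset ingestion, ground-truth conversion, splitting and augmentation.

Patches are 8-bit RGB images paired with ground-truth masks by shared
basename (``x.png`` + ``x_mask.png``); masks may be binary or instance
label maps.  Coordinate convention throughout the package: row-major,
origin top-left, 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage as ndi

__all__ = [
    "IHCPatch",
    "SplitSpec",
    "load_patch_folder",
    "instances_to_binary",
    "split_dataset",
    "augment",
    "read_image",
    "read_mask",
    "AUGMENTATION_OPS",
]

_IMAGE_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")
_MASK_SUFFIX = "_mask"


@dataclass
class IHCPatch:
    """One RGB patch and its ground truth.

    ``gt_binary`` is always present; ``gt_instances`` only when the source
    mask was instance-labelled (any mask with values outside {0, 1}).  When
    both are present, ``gt_binary == (gt_instances > 0)`` by construction.
    """

    image: np.ndarray  # H x W x 3 uint8
    gt_binary: np.ndarray  # H x W bool
    gt_instances: np.ndarray | None = None  # H x W int
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"{self.source_id}: image must be H x W x 3")
        if self.image.shape[:2] != self.gt_binary.shape:
            raise ValueError(
                f"{self.source_id}: image {self.image.shape[:2]} and mask "
                f"{self.gt_binary.shape} dimensions differ")
        if self.gt_instances is not None:
            if self.gt_instances.shape != self.gt_binary.shape:
                raise ValueError(f"{self.source_id}: instance map shape mismatch")


@dataclass(frozen=True)
class SplitSpec:
    """Assignment of ids to the train / train-val / test partitions."""

    ratios: tuple[float, float, float]
    assignment: dict = field(default_factory=dict)
    seed: int = 0

    PARTITIONS = ("train", "train_val", "test")

    def ids(self, partition: str) -> list:
        return [k for k, v in self.assignment.items() if v == partition]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"id": list(self.assignment), "partition": list(self.assignment.values())}
        )


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    arr = read_image(path)
    if arr.ndim == 3:  # RGB-encoded binary masks: any channel on => fg
        arr = arr.max(axis=2)
    if arr.min() < 0:
        raise ValueError(f"{path}: negative labels in mask")
    return arr.astype(np.int32)


def instances_to_binary(labels: np.ndarray) -> np.ndarray:
    """Collapse an instance label map to the binary foreground mask.

    Raises ``ValueError`` on negative labels.  Idempotent on masks that are
    already binary (0/1 treated as labels).
    """
    labels = np.asarray(labels)
    if labels.size and labels.min() < 0:
        raise ValueError("instance labels must be non-negative")
    return labels > 0


def load_patch_folder(path: str | Path) -> list[IHCPatch]:
    """Load every image/mask pair under ``path``.

    Images pair with masks by shared basename plus a ``_mask`` suffix.
    Missing masks and dimension mismatches raise with the offending
    filename; stray mask files without an image are likewise reported.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(path)
    images: dict[str, Path] = {}
    masks: dict[str, Path] = {}
    for p in sorted(path.iterdir()):
        if p.suffix.lower() not in _IMAGE_EXTS:
            continue
        if p.stem.endswith(_MASK_SUFFIX):
            masks[p.stem[: -len(_MASK_SUFFIX)]] = p
        else:
            images[p.stem] = p
    unpaired_masks = sorted(set(masks) - set(images))
    if unpaired_masks:
        raise ValueError(f"masks without an image: {unpaired_masks}")
    patches = []
    for stem, img_path in images.items():
        if stem not in masks:
            raise ValueError(f"missing mask for image {img_path.name}")
        img = read_image(img_path)
        if img.ndim == 2:  # grayscale source: replicate to RGB
            img = np.stack([img] * 3, axis=2)
        mask = read_mask(masks[stem])
        if img.shape[:2] != mask.shape:
            raise ValueError(
                f"{img_path.name}: image {img.shape[:2]} vs mask {mask.shape}")
        is_instances = mask.max(initial=0) > 1
        patches.append(
            IHCPatch(
                image=img.astype(np.uint8),
                gt_binary=instances_to_binary(mask),
                gt_instances=mask if is_instances else None,
                source_id=stem,
            )
        )
    return patches


def _largest_remainder_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    quotas = [r * n for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(sizes)
    order = np.argsort([-(q - s) for q, s in zip(quotas, sizes)], kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    return sizes


def split_dataset(
    ids: Sequence,
    ratios: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
    groups: dict | None = None,
) -> SplitSpec:
    """Randomly partition ``ids`` into train / train-val / test.

    Partition sizes are the largest-remainder rounding of ``ratios * N``.
    When ``groups`` maps each id to a group key (e.g. patient or TMA core),
    whole groups are assigned to one partition to prevent leakage; sizes are
    then largest-remainder on groups, not ids.
    """
    ids = list(ids)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if len(ids) < 1:
        raise ValueError("need at least one id")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    rng = np.random.default_rng(seed)
    units: list = (
        sorted({groups[i] for i in ids}) if groups is not None else list(ids)
    )
    perm = rng.permutation(len(units))
    shuffled = [units[i] for i in perm]
    sizes = _largest_remainder_sizes(len(units), ratios)
    unit_part: dict = {}
    start = 0
    for size, name in zip(sizes, SplitSpec.PARTITIONS):
        for u in shuffled[start : start + size]:
            unit_part[u] = name
        start += size
    if groups is not None:
        assignment = {i: unit_part[groups[i]] for i in ids}
    else:
        assignment = {i: unit_part[i] for i in ids}
    return SplitSpec(ratios=tuple(ratios), assignment=assignment, seed=seed)


def _affine_warp(img: np.ndarray, matrix: np.ndarray, offset: np.ndarray,
                 order: int, cval: float) -> np.ndarray:
    if img.ndim == 2:
        return ndi.affine_transform(img, matrix, offset=offset, order=order,
                                    mode="constant", cval=cval)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = ndi.affine_transform(img[..., c], matrix, offset=offset,
                                           order=order, mode="constant", cval=cval)
    return out


def _shift_scale_rotate(rng: np.random.Generator, shape: tuple[int, int],
                        shift_limit: float, scale_limit: float,
                        rotate_limit_deg: float):
    angle = np.deg2rad(rng.uniform(-rotate_limit_deg, rotate_limit_deg))
    scale = 1.0 + rng.uniform(-scale_limit, scale_limit)
    shift = rng.uniform(-shift_limit, shift_limit, size=2) * np.array(shape)
    centre = (np.array(shape) - 1) / 2.0
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa], [sa, ca]]) / scale  # output->input mapping
    offset = centre - rot @ (centre + shift)
    return rot, offset


def _elastic_fields(rng: np.random.Generator, shape: tuple[int, int],
                    alpha: float, sigma: float):
    dr = ndi.gaussian_filter(rng.uniform(-1, 1, size=shape), sigma) * alpha
    dc = ndi.gaussian_filter(rng.uniform(-1, 1, size=shape), sigma) * alpha
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return rr + dr, cc + dc


def _map_coords(img: np.ndarray, coords, order: int, cval: float) -> np.ndarray:
    if img.ndim == 2:
        return ndi.map_coordinates(img, coords, order=order, mode="constant",
                                   cval=cval)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = ndi.map_coordinates(img[..., c], coords, order=order,
                                          mode="constant", cval=cval)
    return out


AUGMENTATION_OPS = ("hflip", "vflip", "elastic", "shift_scale_rotate")


def augment(
    patch: IHCPatch,
    ops: Iterable[str],
    seed: int = 0,
    *,
    elastic_alpha: float = 10.0,
    elastic_sigma: float = 4.0,
    shift_limit: float = 0.06,
    scale_limit: float = 0.1,
    rotate_limit_deg: float = 30.0,
) -> IHCPatch:
    """Apply geometric augmentations jointly to image and masks.

    Supported ops: ``hflip``, ``vflip``, ``elastic``, ``shift_scale_rotate``.
    The identical transform hits image and masks; images are interpolated
    bilinearly, masks with nearest-neighbour so labels stay integral.
    """
    image = patch.image.copy()
    gt_bin = patch.gt_binary.copy()
    gt_inst = None if patch.gt_instances is None else patch.gt_instances.copy()
    rng = np.random.default_rng(seed)
    shape = gt_bin.shape

    for op in ops:
        if op == "hflip":
            image = image[:, ::-1]
            gt_bin = gt_bin[:, ::-1]
            gt_inst = None if gt_inst is None else gt_inst[:, ::-1]
        elif op == "vflip":
            image = image[::-1]
            gt_bin = gt_bin[::-1]
            gt_inst = None if gt_inst is None else gt_inst[::-1]
        elif op == "shift_scale_rotate":
            mat, off = _shift_scale_rotate(rng, shape, shift_limit, scale_limit,
                                           rotate_limit_deg)
            image = _affine_warp(image, mat, off, order=1, cval=255)
            gt_bin = _affine_warp(gt_bin.astype(np.uint8), mat, off, order=0,
                                  cval=0).astype(bool)
            if gt_inst is not None:
                gt_inst = _affine_warp(gt_inst, mat, off, order=0, cval=0)
        elif op == "elastic":
            coords = _elastic_fields(rng, shape, elastic_alpha, elastic_sigma)
            image = _map_coords(image, coords, order=1, cval=255)
            gt_bin = _map_coords(gt_bin.astype(np.uint8), coords, order=0,
                                 cval=0).astype(bool)
            if gt_inst is not None:
                gt_inst = _map_coords(gt_inst, coords, order=0, cval=0)
        else:
            raise ValueError(f"unknown augmentation op: {op!r}")

    return IHCPatch(image=np.ascontiguousarray(image),
                    gt_binary=np.ascontiguousarray(gt_bin),
                    gt_instances=None if gt_inst is None
                    else np.ascontiguousarray(gt_inst),
                    source_id=patch.source_id)
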