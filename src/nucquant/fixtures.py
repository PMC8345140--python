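"""Synthetic IHC-like image patches and survival cohorts.

Real DAB-stained tissue cores are not redistributable, so this module
fabricates the two kinds of input the rest of the package consumes:

* RGB patches containing brown (DAB chromogen) elliptical nuclei on a pale
  hematoxylin/eosin-like background, together with an instance-labelled
  ground-truth map.  A configurable fraction of nuclei is placed as
  touching/overlapping pairs, the failure mode the watershed post-processing
  stage exists to fix.
* Right-censored survival cohorts in which the per-patient hazard depends
  log-linearly on the density of detected cells, so the downstream
  cutoff + Kaplan-Meier + log-rank chain has a known effect to recover.

All randomness flows from the single integer ``seed`` in each config via
``numpy.random.default_rng``; no global state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi

__all__ = [
    "SynthPatchConfig",
    "SynthCohortConfig",
    "generate_patch",
    "generate_touching_pair",
    "generate_cohort",
    "write_patch",
    "write_cohort",
]

# DAB chromogen renders target-expressing nuclei brown; counterstained
# tissue reads as a pale pink/lavender.  Values picked by eye from IHC
# imagery; they are free parameters, not measurements.
DAB_BROWN = (96, 60, 22)
TISSUE_BACKGROUND = (228, 205, 215)


@dataclass(frozen=True)
class SynthPatchConfig:
    """Parameters of one synthetic patch.

    ``touching_fraction`` is the proportion of nuclei laid down as members of
    an overlapping pair (so 0.4 with 10 nuclei gives 2 pairs + 6 singletons).
    ``radius`` bounds the ellipse semi-axes in pixels.
    """

    patch_size: int = 256
    n_nuclei: tuple[int, int] = (8, 16)
    radius: tuple[float, float] = (6.0, 11.0)
    touching_fraction: float = 0.25
    stain_foreground: tuple[int, int, int] = DAB_BROWN
    stain_background: tuple[int, int, int] = TISSUE_BACKGROUND
    noise_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if not (0.0 <= self.touching_fraction <= 1.0):
            raise ValueError("touching_fraction must lie in [0, 1]")
        lo, hi = self.radius
        if lo < 2 or hi < lo:
            raise ValueError("radii must satisfy 2 <= lo <= hi")
        lo_n, hi_n = self.n_nuclei
        if lo_n < 0 or hi_n < lo_n:
            raise ValueError("n_nuclei range must satisfy 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SynthCohortConfig:
    """Parameters of a synthetic survival cohort.

    Event times are exponential with per-patient rate
    ``baseline_hazard * exp(log_hazard_ratio_per_unit_density * z)`` where
    ``z`` is the patient's density standardised by the log-normal's median
    scale, so the effect size is per unit of log-scale spread rather than per
    single cell/mm^2.  Censoring is an independent exponential plus an
    administrative follow-up cap.
    """

    n_patients: int = 200
    density_lognorm_mu: float = np.log(150.0)  # cells/mm^2, median 150
    density_lognorm_sigma: float = 0.6
    baseline_hazard: float = 0.12  # events per year
    log_hazard_ratio_per_unit_density: float = 0.0
    censoring_rate: float = 0.05  # per year
    follow_up_cap: float = 10.0  # years
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("baseline_hazard", "censoring_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.follow_up_cap <= 0:
            raise ValueError("follow_up_cap must be positive")


def _ellipse_mask(
    shape: tuple[int, int],
    centre: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    """Boolean mask of a filled, rotated ellipse (row, col convention)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - centre[0]
    dc = cc - centre[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _draw_nucleus(rng: np.random.Generator, cfg: SynthPatchConfig,
                  centre: tuple[float, float]) -> np.ndarray:
    lo, hi = cfg.radius
    a = rng.uniform(lo, hi)
    # eccentricity capped so nuclei stay blob-like
    b = a * rng.uniform(0.65, 1.0)
    angle = rng.uniform(0, np.pi)
    size = cfg.patch_size
    return _ellipse_mask((size, size), centre, (a, b), angle)


def _background(rng: np.random.Generator, cfg: SynthPatchConfig) -> np.ndarray:
    """Background with low-frequency intensity texture, float in [0, 255]."""
    size = cfg.patch_size
    base = np.array(cfg.stain_background, dtype=np.float64)
    coarse = rng.normal(0.0, 1.0, size=(max(size // 16, 1),) * 2)
    texture = ndi.zoom(coarse, (size / coarse.shape[0], size / coarse.shape[1]),
                       order=1)[:size, :size]
    texture = 10.0 * texture / max(np.abs(texture).max(), 1e-9)
    img = base[None, None, :] + texture[:, :, None]
    return img


_MAX_PLACEMENT_RETRIES = 200


def generate_patch(config: SynthPatchConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic patch.

    Returns ``(rgb, labels)`` where ``rgb`` is uint8 H x W x 3 and ``labels``
    an int32 instance label map (0 background, 1..K nuclei).  Nuclei drawn as
    part of a touching pair overlap; the later label wins the shared pixels
    but the ground truth keeps two instances.  Deterministic given the seed.

    Raises ``RuntimeError`` when nuclei cannot be placed without exceeding a
    bounded retry budget (patch too crowded).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    size = config.patch_size
    labels = np.zeros((size, size), dtype=np.int32)

    lo_n, hi_n = config.n_nuclei
    n_total = int(rng.integers(lo_n, hi_n + 1))
    n_pairs = int(round(config.touching_fraction * n_total / 2.0))
    n_single = n_total - 2 * n_pairs

    occupied = np.zeros((size, size), dtype=bool)
    next_label = 1
    margin = config.radius[1] + 2

    def place(mask: np.ndarray) -> None:
        nonlocal next_label
        labels[mask] = next_label
        next_label += 1

    def free_spot(mask: np.ndarray) -> bool:
        # keep distinct objects separated by a 1-px dilation so that
        # "touching" is an explicit property of pairs, not an accident
        return not (ndi.binary_dilation(mask) & occupied).any()

    for _ in range(n_pairs):
        for attempt in range(_MAX_PLACEMENT_RETRIES + 1):
            if attempt == _MAX_PLACEMENT_RETRIES:
                raise RuntimeError(
                    "could not place touching pair: patch too crowded")
            centre = tuple(rng.uniform(margin, size - margin, size=2))
            m1 = _draw_nucleus(rng, config, centre)
            r = 0.5 * (config.radius[0] + config.radius[1])
            theta = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(1.2 * r, 1.7 * r)
            centre2 = (centre[0] + d * np.sin(theta), centre[1] + d * np.cos(theta))
            if not (margin <= centre2[0] < size - margin
                    and margin <= centre2[1] < size - margin):
                continue
            m2 = _draw_nucleus(rng, config, centre2)
            union = m1 | m2
            if not (m1 & m2).any():  # must genuinely overlap
                continue
            if not free_spot(union):
                continue
            place(m1)
            # later label wins contested pixels
            place(m2)
            occupied |= union
            break

    for _ in range(n_single):
        for attempt in range(_MAX_PLACEMENT_RETRIES + 1):
            if attempt == _MAX_PLACEMENT_RETRIES:
                raise RuntimeError("could not place nucleus: patch too crowded")
            centre = tuple(rng.uniform(margin, size - margin, size=2))
            m = _draw_nucleus(rng, config, centre)
            if not free_spot(m):
                continue
            place(m)
            occupied |= m
            break

    rgb = _background(rng, config)
    fg = labels > 0
    fg_colour = np.array(config.stain_foreground, dtype=np.float64)
    # mild per-nucleus stain-intensity variation
    for lab in range(1, next_label):
        m = labels == lab
        shade = rng.uniform(0.85, 1.15)
        rgb[m] = np.clip(fg_colour * shade, 0, 255)
    if config.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, config.noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    assert (labels[~fg] == 0).all()
    return rgb, labels


def generate_touching_pair(
    radius: float,
    centre_distance: float,
    seed: int = 0,
    patch_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two overlapping discs of equal ``radius`` with centres
    ``centre_distance`` apart: the canonical boundary-connected-nuclei stress
    case for watershed separation.

    The label map has exactly two instances whose binary union is a single
    connected component.  Raises ``ValueError`` unless
    ``0 < centre_distance < 2 * radius``.
    """
    if radius < 2:
        raise ValueError("radius must be >= 2 px")
    if not (0 < centre_distance < 2 * radius):
        raise ValueError(
            "centre_distance must lie in (0, 2*radius) for the discs to touch")
    rng = np.random.default_rng(seed)
    if patch_size is None:
        patch_size = int(np.ceil(2 * radius + centre_distance)) + 8
    size = patch_size
    mid = (size - 1) / 2.0
    theta = rng.uniform(0, np.pi)
    dr = 0.5 * centre_distance * np.sin(theta)
    dc = 0.5 * centre_distance * np.cos(theta)
    c1 = (mid - dr, mid - dc)
    c2 = (mid + dr, mid + dc)
    m1 = _ellipse_mask((size, size), c1, (radius, radius), 0.0)
    m2 = _ellipse_mask((size, size), c2, (radius, radius), 0.0)
    labels = np.zeros((size, size), dtype=np.int32)
    labels[m1] = 1
    labels[m2] = 2  # later label wins the overlap
    rgb = np.full((size, size, 3), TISSUE_BACKGROUND, dtype=np.float64)
    rgb[labels > 0] = DAB_BROWN
    return rgb.astype(np.uint8), labels


def generate_cohort(config: SynthCohortConfig) -> pd.DataFrame:
    """Simulate a right-censored survival cohort.

    Returns a DataFrame with columns
    ``patient_id, density, area_mm2, time_years, event``.  ``density`` is
    log-normal; the event hazard is ``baseline_hazard *
    exp(beta * z)`` with ``z`` the standardised log-density, so ``beta`` is
    directly a log hazard ratio per log-scale SD of density.  Observed time is
    ``min(event, censor, follow_up_cap)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    log_density = rng.normal(config.density_lognorm_mu,
                             config.density_lognorm_sigma, size=n)
    density = np.exp(log_density)
    z = (log_density - config.density_lognorm_mu) / config.density_lognorm_sigma
    hazard = config.baseline_hazard * np.exp(
        config.log_hazard_ratio_per_unit_density * z)
    event_time = rng.exponential(1.0 / np.maximum(hazard, 1e-12))
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    censor_time = np.minimum(censor_time, config.follow_up_cap)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    # nominal 1 mm-diameter core area; density fixed, cell count implied
    area = np.full(n, np.pi * 0.5**2)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "density": density,
            "area_mm2": area,
            "time_years": time,
            "event": event,
        }
    )


def write_patch(out_dir: str | Path, stem: str, rgb: np.ndarray,
                labels: np.ndarray) -> tuple[Path, Path]:
    """Write ``<stem>.png`` (RGB) and ``<stem>_mask.png`` (16-bit labels)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{stem}.png"
    mask_path = out_dir / f"{stem}_mask.png"
    Image.fromarray(rgb).save(img_path)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds 16-bit range")
    Image.fromarray(labels.astype(np.uint16)).save(mask_path)
    return img_path, mask_path


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def replace(config, **kwargs):
    """Convenience: dataclasses.replace that works for both config types."""
    return dataclasses.replace(config, **kwargs)
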