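"""Fluorescence image quantification.

Covers the histology readouts of the pipeline: excitatory/inhibitory
synapse counting by pre/post puncta colocalization with size exclusion,
glial coverage and intensity, the perimeter-based ramification index,
3D cell counts, and astrocytic synaptic-uptake volume fractions.

The fixed preprocessing order is: per-plane 3x3 median filter ("despeckle")
-> maximum-intensity projection -> rolling-ball background subtraction
(radius 10 px) -> Otsu binarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology as skmorph, restoration

from .core import ImageStack, ParameterError


@dataclass
class PunctaResult:
    n_colocalized: int
    density_per_100um2: float
    mean_object_area: float   # um^2
    area_covered: float       # um^2, summed over retained objects
    objects: list = field(default_factory=list)  # {centroid, area_um2}


@dataclass
class CoverageResult:
    percent_area: float
    mean_intensity_in_mask: float
    ramification_index: float = np.nan
    n_cells: int = 0
    cells_per_volume: float = np.nan  # per mm^3


def preprocess_channel(stack: ImageStack, channel: str,
                       rolling_ball_radius: int = 10,
                       median_size: int = 3) -> np.ndarray:
    """Median-filter each plane, max-project, subtract rolling-ball background."""
    vol = stack.channel(channel)
    filtered = ndimage.median_filter(vol, size=(1, median_size, median_size))
    mip = filtered.max(axis=0)
    background = restoration.rolling_ball(mip, radius=rolling_ball_radius)
    return mip - background


def _binarize_otsu(img: np.ndarray) -> np.ndarray:
    if np.allclose(img, img.flat[0]):
        return np.zeros(img.shape, dtype=bool)
    return img > filters.threshold_otsu(img)


def count_colocalized_synapses(pre_img: np.ndarray, post_img: np.ndarray,
                               pixel_size: float,
                               min_area_um2: float = 0.1,
                               max_area_um2: float = 1.2,
                               mask_mode: str = "and") -> PunctaResult:
    """Colocalized pre/post puncta as candidate synapses, size-filtered.

    Both preprocessed channels are Otsu-binarized; the additive mask is the
    pixel-wise AND (``mask_mode="sum"`` instead thresholds the summed
    binary masks, an alternative reading of the original plugin).
    8-connected components of the mask with area outside
    [``min_area_um2``, ``max_area_um2``] are excluded as unlikely to be
    synapses; bounds are inclusive.
    """
    if pre_img.shape != post_img.shape:
        raise ParameterError("channel images must share one shape")
    m_pre = _binarize_otsu(pre_img)
    m_post = _binarize_otsu(post_img)
    if mask_mode == "and":
        mask = m_pre & m_post
    elif mask_mode == "sum":
        mask = (m_pre.astype(int) + m_post.astype(int)) >= 2
    else:
        raise ParameterError(f"unknown mask_mode {mask_mode!r}")

    labels = measure.label(mask, connectivity=2)
    px_area = pixel_size ** 2
    objects = []
    for region in measure.regionprops(labels):
        area = region.area * px_area
        if min_area_um2 <= area <= max_area_um2:
            objects.append({"centroid": tuple(map(float, region.centroid)),
                            "area_um2": float(area)})
    field_area = mask.size * px_area
    n = len(objects)
    areas = [o["area_um2"] for o in objects]
    return PunctaResult(
        n_colocalized=n,
        density_per_100um2=n / field_area * 100.0,
        mean_object_area=float(np.mean(areas)) if areas else np.nan,
        area_covered=float(np.sum(areas)),
        objects=objects,
    )


def coverage_intensity(img: np.ndarray, pixel_size: float) -> CoverageResult:
    """Percent area above Otsu threshold and mean intensity within the mask."""
    mask = _binarize_otsu(img)
    percent = 100.0 * mask.sum() / mask.size
    mean_int = float(img[mask].mean()) if mask.any() else np.nan
    return CoverageResult(percent_area=float(percent), mean_intensity_in_mask=mean_int)


def _boundary_length_px(mask: np.ndarray, simplify_tol: float = 1.0) -> float:
    """Boundary length of a binary mask in pixel units.

    Marching-squares contours are polygon-simplified (tolerance ~1 px) to
    remove the pixelation staircase before summing segment lengths, so a
    rasterized disk measures close to its true circumference while corners
    of rectilinear shapes are preserved.
    """
    total = 0.0
    padded = np.pad(mask.astype(float), 1)
    for contour in measure.find_contours(padded, 0.5):
        poly = measure.approximate_polygon(contour, tolerance=simplify_tol)
        d = np.diff(poly, axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def ramification_index(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Perimeter-to-area ratio normalized to a circle of equal area.

    RI = P / (2 * sqrt(pi * A)); equals 1 for a circle and grows with
    morphological complexity (ramification) of the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty mask")
    area = mask.sum() * pixel_size ** 2
    perim = _boundary_length_px(mask) * pixel_size
    return float(perim / (2.0 * np.sqrt(np.pi * area)))


def count_cells_3d(stack: ImageStack, channel: str,
                   min_volume_um3: float = 50.0) -> tuple[int, float]:
    """3D Otsu threshold -> 26-connected components -> volume-filtered count.

    Returns the cell count and the density per mm^3 of imaged volume.
    Touching somata merged by a voxel bridge count as one object (no
    watershed splitting; documented limitation).
    """
    vol = stack.channel(channel)
    mask = _binarize_otsu(vol)
    labels = measure.label(mask, connectivity=3)
    vox = stack.voxel_volume
    n = sum(1 for r in measure.regionprops(labels) if r.area * vox >= min_volume_um3)
    total_mm3 = vol.size * vox * 1e-9
    return n, n / total_mm3


def astro_uptake(stack: ImageStack, glia_channel: str, puncta_channel: str,
                 glia_threshold: float, puncta_threshold: float | None = None) -> float:
    """Puncta volume inside the glial mask as a % of glial volume.

    The glial channel is thresholded at a configured value (standing in for
    the manual surface step of the original workflow); the puncta channel is
    binarized (Otsu unless ``puncta_threshold`` is given) within that mask.
    """
    glia = stack.channel(glia_channel) >= glia_threshold
    if not glia.any():
        raise ParameterError("empty glial mask at the configured threshold")
    pv = stack.channel(puncta_channel)
    if puncta_threshold is None:
        pmask = _binarize_otsu(pv)
    else:
        pmask = pv >= puncta_threshold
    inside = pmask & glia
    return 100.0 * inside.sum() / glia.sum()


def normalize_to_control(group_means: dict, control: str) -> dict:
    """Express group means relative to the mean of the control group."""
    if control not in group_means:
        raise ParameterError(f"control group {control!r} missing")
    ref = group_means[control]
    if ref == 0:
        raise ParameterError("control mean is zero")
    return {g: v / ref for g, v in group_means.items()}
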