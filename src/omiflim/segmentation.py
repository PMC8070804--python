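"""Single-cell segmentation of NAD(P)H intensity images.

In two-photon NAD(P)H images of organoid cross-sections the background is
dark, nuclei are dim (nuclei carry little NAD(P)H) and cytoplasm is
bright, so a three-class intensity threshold isolates nuclei as the
middle band.  Round mid-band objects become nucleus seeds, whole cells
are grown outward from each seed across foreground pixels, and cytoplasm
is the cell footprint minus its nucleus — the compartment over which all
metabolic features are measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_multiotsu, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "SegmentationParams",
    "LabelMasks",
    "detect_nuclei",
    "propagate_cells",
    "cytoplasm_mask",
    "segment_scene",
    "percent_positive",
    "object_f1",
]


@dataclass
class SegmentationParams:
    min_nucleus_area: int = 15
    max_nucleus_area: int = 2000
    max_eccentricity: float = 0.9
    min_solidity: float = 0.8
    # light denoise only: heavier smoothing bleeds bright cytoplasm into
    # small nuclei and lifts them out of the mid-intensity band
    smooth_sigma: float = 0.5
    split_min_distance: int = 4


@dataclass
class LabelMasks:
    """Nucleus / whole-cell / cytoplasm label images on one grid.

    Label i in ``nuclei`` is the nucleus of label i in ``cells``;
    ``cytoplasm`` is ``cells`` with nucleus pixels zeroed.
    """

    nuclei: np.ndarray
    cells: np.ndarray
    cytoplasm: np.ndarray

    def __post_init__(self) -> None:
        if not (self.nuclei.shape == self.cells.shape == self.cytoplasm.shape):
            raise ValueError("masks must share one shape")
        self.validate()

    def validate(self) -> None:
        nuc = self.nuclei
        inside = nuc > 0
        if np.any(self.cells[inside] != nuc[inside]):
            raise ValueError("each nucleus must lie inside its own cell")
        expected = np.where(inside, 0, self.cells)
        if np.any(self.cytoplasm != expected):
            raise ValueError("cytoplasm must equal cells minus nuclei")


def detect_nuclei(nadh_intensity: np.ndarray,
                  params: SegmentationParams | None = None) -> np.ndarray:
    """Label nucleus objects in an NAD(P)H intensity image.

    A three-class Otsu threshold splits background / nucleus / cytoplasm;
    connected components of the middle band are filtered by area and
    roundness (eccentricity, solidity), and touching nuclei are split by
    a distance-transform watershed.  A blank image yields zero labels.
    """
    params = params or SegmentationParams()
    img = np.asarray(nadh_intensity, dtype=float)
    if img.ndim != 2 or np.any(img < 0):
        raise ValueError("expected a 2-D non-negative intensity image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    smooth = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    try:
        t_lo, t_hi = threshold_multiotsu(smooth, classes=3)
    except ValueError:  # too few distinct gray levels for 3 classes
        return np.zeros(img.shape, dtype=np.int32)
    band = (smooth > t_lo) & (smooth <= t_hi)
    band = ndi.binary_opening(band, structure=np.ones((3, 3)))
    if not band.any():
        return np.zeros(img.shape, dtype=np.int32)

    # split touching nuclei on the distance transform
    dist = ndi.distance_transform_edt(band)
    peaks = peak_local_max(dist, min_distance=params.split_min_distance,
                           labels=band, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=band)

    keep = np.zeros(labels.max() + 1, dtype=bool)
    for prop in regionprops(labels):
        ok = (params.min_nucleus_area <= prop.area <= params.max_nucleus_area
              and prop.eccentricity <= params.max_eccentricity
              and prop.solidity >= params.min_solidity)
        keep[prop.label] = ok
    labels = np.where(keep[labels], labels, 0)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def propagate_cells(nuclei: np.ndarray, nadh_intensity: np.ndarray,
                    params: SegmentationParams | None = None) -> np.ndarray:
    """Grow whole-cell labels outward from nucleus seeds.

    Propagation is an intensity-guided watershed restricted to foreground
    pixels above a global two-class Otsu threshold, so cells never leak
    into background.  Every nucleus pixel keeps its seed label; abutting
    cells divide the shared foreground between the nearer seeds.
    """
    params = params or SegmentationParams()
    img = np.asarray(nadh_intensity, dtype=float)
    if img.shape != nuclei.shape:
        raise ValueError("image and nucleus mask shapes differ")
    if nuclei.max() == 0:
        return nuclei.astype(np.int32)
    smooth = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    if np.ptp(smooth) == 0:
        return nuclei.astype(np.int32)
    fg = smooth > threshold_otsu(smooth)
    mask = fg | (nuclei > 0)
    cells = watershed(-smooth, markers=nuclei.astype(np.int32), mask=mask)
    return cells.astype(np.int32)


def cytoplasm_mask(cells: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Cytoplasm labels: the cell footprint minus the nucleus pixels."""
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    if cells.shape != nuclei.shape:
        raise ValueError("masks must share one shape")
    inside = nuclei > 0
    if np.any(cells[inside] != nuclei[inside]):
        raise ValueError("each nucleus must lie inside its matching cell label")
    return np.where(inside, 0, cells).astype(np.int32)


def segment_scene(nadh_intensity: np.ndarray,
                  params: SegmentationParams | None = None) -> LabelMasks:
    """Full nucleus → cell → cytoplasm pipeline on one intensity image."""
    nuclei = detect_nuclei(nadh_intensity, params)
    cells = propagate_cells(nuclei, nadh_intensity, params)
    cyto = cytoplasm_mask(cells, nuclei)
    return LabelMasks(nuclei=nuclei, cells=cells, cytoplasm=cyto)


def percent_positive(primary_labels: np.ndarray, marker_mask: np.ndarray,
                     min_overlap_frac: float = 0.25) -> float:
    """Percent of labeled objects overlapping a marker mask.

    An object counts as positive when at least ``min_overlap_frac`` of
    its area overlaps the marker (e.g. DAPI nuclei scored against Ki67 or
    cleaved caspase-3 stain).
    """
    labels = np.asarray(primary_labels)
    marker = np.asarray(marker_mask).astype(bool)
    if labels.shape != marker.shape:
        raise ValueError("masks must share one shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no objects in the primary mask")
    areas = ndi.sum_labels(np.ones_like(labels), labels, ids)
    overlaps = ndi.sum_labels(marker.astype(float), labels, ids)
    positive = (overlaps / areas) >= min_overlap_frac
    return 100.0 * positive.sum() / ids.size


def object_f1(predicted: np.ndarray, truth: np.ndarray,
              iou_threshold: float = 0.5) -> float:
    """Object-level F1 between two label images (greedy IoU matching)."""
    pred_ids = np.unique(predicted)[1:] if predicted.max() else np.array([], int)
    true_ids = np.unique(truth)[1:] if truth.max() else np.array([], int)
    if pred_ids.size == 0 and true_ids.size == 0:
        return 1.0
    if pred_ids.size == 0 or true_ids.size == 0:
        return 0.0
    matched_pred: set = set()
    tp = 0
    for tid in true_ids:
        tmask = truth == tid
        cand = np.unique(predicted[tmask])
        best, best_iou = 0, 0.0
        for pid in cand:
            if pid == 0 or pid in matched_pred:
                continue
            pmask = predicted == pid
            inter = np.count_nonzero(tmask & pmask)
            union = np.count_nonzero(tmask | pmask)
            iou = inter / union
            if iou > best_iou:
                best, best_iou = pid, iou
        if best_iou >= iou_threshold:
            matched_pred.add(best)
            tp += 1
    precision = tp / pred_ids.size
    recall = tp / true_ids.size
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
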