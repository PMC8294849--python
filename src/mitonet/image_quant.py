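"""2D fluorescence quantification.

Masked intensity measurement, soma mitochondrial area fraction and
perinuclear-cluster detection, bouton (punctum) detection with occupancy and
mitochondrial content, and object-level pre/post synaptic colocalization
with the 33–100% overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, restoration

from .errors import InputError


# ---------------------------------------------------------------------------
# Preprocessing

def rolling_ball_subtract(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction; result clipped at zero."""
    if radius < 1:
        raise InputError("rolling-ball radius must be >= 1")
    image = np.asarray(image, dtype=float)
    background = restoration.rolling_ball(image, radius=radius)
    return np.clip(image - background, 0.0, None)


def threshold_value(image: np.ndarray, method: str | float = "otsu") -> float:
    """Binarisation threshold: 'otsu', 'isodata', or a fixed number."""
    if isinstance(method, (int, float)):
        return float(method)
    if method == "otsu":
        return float(filters.threshold_otsu(image))
    if method == "isodata":
        return float(filters.threshold_isodata(image))
    raise InputError(f"unknown threshold method {method!r}")


def binarize_stack(
    stack: np.ndarray,
    rolling_ball_radius: int = 50,
    median_size: int = 3,
    method: str | float = "otsu",
) -> np.ndarray:
    """Mitochondrial-channel preprocessing for shell counting.

    Per z-slice rolling-ball background subtraction, then a median filter,
    then a single global threshold over the filtered stack.
    """
    stack = np.asarray(stack, dtype=float)
    cleaned = np.stack(
        [rolling_ball_subtract(sl, rolling_ball_radius) for sl in stack]
    )
    cleaned = ndimage.median_filter(cleaned, size=(1, median_size, median_size))
    return cleaned > threshold_value(cleaned, method)


# ---------------------------------------------------------------------------
# Masked intensity and soma measurements

def region_mean_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean intensity of the image within the (non-empty) binary mask."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise InputError("image and mask shapes differ")
    n = int(mask.sum())
    if n == 0:
        raise InputError("empty mask")
    return float(image[mask].sum() / n)


def soma_mito_area_fraction(mito_mask: np.ndarray, soma_mask: np.ndarray) -> float:
    """Percent of the soma area occupied by mitochondrial signal."""
    mito_mask = np.asarray(mito_mask, dtype=bool)
    soma_mask = np.asarray(soma_mask, dtype=bool)
    if mito_mask.shape != soma_mask.shape:
        raise InputError("mask shapes differ")
    soma_area = int(soma_mask.sum())
    if soma_area == 0:
        raise InputError("empty soma mask")
    return 100.0 * int((mito_mask & soma_mask).sum()) / soma_area


def detect_soma_cluster(
    mito_mask: np.ndarray, soma_mask: np.ndarray, dominance: float = 0.5
) -> bool:
    """Perinuclear clustering: does one connected component dominate?

    True when the largest connected mitochondrial component inside the soma
    holds at least ``dominance`` of the total in-soma mitochondrial area.
    """
    inside = np.asarray(mito_mask, dtype=bool) & np.asarray(soma_mask, dtype=bool)
    total = int(inside.sum())
    if total == 0:
        return False
    labels, n = ndimage.label(inside)
    largest = int(np.max(ndimage.sum_labels(inside, labels, index=range(1, n + 1))))
    return largest >= dominance * total


def select_soma(image: np.ndarray, seed_point: tuple[int, int],
                method: str | float = "otsu") -> np.ndarray:
    """Deterministic analogue of wand-tool selection.

    Threshold the image, then keep the connected component containing the
    seed point (row, col).
    """
    binary = np.asarray(image, dtype=float) > threshold_value(np.asarray(image, float), method)
    labels, _ = ndimage.label(binary)
    lab = labels[seed_point]
    if lab == 0:
        raise InputError("seed point falls on background after thresholding")
    return labels == lab


# ---------------------------------------------------------------------------
# Puncta (boutons)

@dataclass
class PunctaSet:
    """Detected puncta with their label image for downstream measurements."""

    centroids: np.ndarray        # (n, 2) row/col pixels
    areas_um2: np.ndarray        # μm²
    positions_um: np.ndarray     # μm along the axon axis (x · pixel size)
    labels: np.ndarray           # label image, 0 = background, i -> punctum i
    label_ids: np.ndarray        # label value per punctum
    pixel_size: float            # μm per pixel

    @property
    def n(self) -> int:
        return self.label_ids.size


def detect_puncta(
    image: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 0.2,
    max_area_um2: float = 3.0,
    threshold: str | float = "otsu",
) -> PunctaSet:
    """Connected components of the thresholded image within area bounds.

    Default bounds 0.2–3.0 μm² bracket typical presynaptic bouton sizes;
    merged blobs larger than ``max_area_um2`` are rejected.
    """
    if pixel_size <= 0:
        raise InputError("pixel_size must be positive (calibrated image required)")
    image = np.asarray(image, dtype=float)
    binary = image > threshold_value(image, threshold)
    labels, _ = ndimage.label(binary)
    keep_labels, centroids, areas = [], [], []
    px_area = pixel_size**2
    for region in measure.regionprops(labels):
        area = region.area * px_area
        if min_area_um2 <= area <= max_area_um2:
            keep_labels.append(region.label)
            centroids.append(region.centroid)
            areas.append(area)
    out = np.zeros_like(labels)
    for newid, lab in enumerate(keep_labels, start=1):
        out[labels == lab] = newid
    centroids = np.array(centroids).reshape(-1, 2)
    return PunctaSet(
        centroids=centroids,
        areas_um2=np.array(areas),
        positions_um=centroids[:, 1] * pixel_size if centroids.size else np.empty(0),
        labels=out,
        label_ids=np.arange(1, len(keep_labels) + 1),
        pixel_size=pixel_size,
    )


def bouton_occupancy(puncta: PunctaSet, axon_path_length: float) -> float:
    """Bouton density along the axon: count per 10 μm of path."""
    if axon_path_length <= 0:
        raise InputError("axon path length must be positive")
    return 10.0 * puncta.n / axon_path_length


def bouton_mito_content(
    puncta: PunctaSet,
    mito_image: np.ndarray,
    criterion: float | None = None,
    background_mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Score each bouton for mitochondrial content.

    A punctum "contains" mitochondria when its mean intensity in the
    mitochondrial channel exceeds ``criterion``; the default criterion is
    the shaft background mean + 2·SD, estimated over ``background_mask``
    (all non-punctum pixels when no mask is given).

    Returns (percent containing, per-punctum boolean flags, per-punctum
    mean mitochondrial intensity).
    """
    if puncta.n == 0:
        raise InputError("no puncta to score")
    mito_image = np.asarray(mito_image, dtype=float)
    if mito_image.shape != puncta.labels.shape:
        raise InputError("mito image and puncta label image shapes differ")
    if criterion is None:
        bg = (puncta.labels == 0) if background_mask is None \
            else np.asarray(background_mask, dtype=bool) & (puncta.labels == 0)
        vals = mito_image[bg]
        if vals.size == 0:
            raise InputError("no background pixels available for the criterion")
        criterion = float(vals.mean() + 2.0 * vals.std())
    means = ndimage.mean(mito_image, labels=puncta.labels, index=puncta.label_ids)
    means = np.atleast_1d(np.asarray(means, dtype=float))
    flags = means > criterion
    return 100.0 * flags.mean(), flags, means


# ---------------------------------------------------------------------------
# Synapse colocalization

def segment_synapse_channel(
    image: np.ndarray,
    rolling_ball_radius: int = 7,
    max_filter_radius: int = 1,
    threshold: str | float = "otsu",
) -> np.ndarray:
    """Marker-channel segmentation: rolling ball 7 → max filter 1 → Otsu → label."""
    cleaned = rolling_ball_subtract(image, rolling_ball_radius)
    if max_filter_radius > 0:
        cleaned = ndimage.maximum_filter(cleaned, size=2 * max_filter_radius + 1)
    binary = cleaned > threshold_value(cleaned, threshold)
    labels, _ = ndimage.label(binary)
    return labels


def synapse_colocalization(
    pre_image: np.ndarray,
    post_image: np.ndarray,
    min_overlap: float = 0.33,
    max_overlap: float = 1.0,
    **segment_kwargs,
) -> tuple[int, int, int]:
    """Pre/post object counts and colocalized pair count.

    A pre/post object pair colocalizes when their overlap area divided by
    the smaller object's area lies within [min_overlap, max_overlap].
    Many-to-many candidates are reduced to a one-to-one matching by greedy
    best-overlap assignment, so pairs ≤ min(pre count, post count).
    """
    pre_image = np.asarray(pre_image, dtype=float)
    post_image = np.asarray(post_image, dtype=float)
    if pre_image.shape != post_image.shape:
        raise InputError("pre and post images must have the same shape")
    pre_labels = segment_synapse_channel(pre_image, **segment_kwargs)
    post_labels = segment_synapse_channel(post_image, **segment_kwargs)
    n_pre = int(pre_labels.max())
    n_post = int(post_labels.max())
    if n_pre == 0 or n_post == 0:
        return n_pre, n_post, 0
    pre_areas = np.bincount(pre_labels.ravel(), minlength=n_pre + 1)
    post_areas = np.bincount(post_labels.ravel(), minlength=n_post + 1)
    both = (pre_labels > 0) & (post_labels > 0)
    pairs = {}
    for a, b in zip(pre_labels[both], post_labels[both]):
        pairs[(a, b)] = pairs.get((a, b), 0) + 1
    candidates = []
    for (a, b), ov in pairs.items():
        frac = ov / min(pre_areas[a], post_areas[b])
        if min_overlap <= frac <= max_overlap:
            candidates.append((frac, a, b))
    candidates.sort(reverse=True)
    used_pre, used_post, n_pairs = set(), set(), 0
    for _, a, b in candidates:
        if a not in used_pre and b not in used_post:
            used_pre.add(a)
            used_post.add(b)
            n_pairs += 1
    return n_pre, n_post, n_pairs
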