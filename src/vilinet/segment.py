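"""Post-processing of pixel-class label images.

Turns externally segmented label images (injury / air / other /
background) into lobe masks, discrete injury nodes, class-fraction
morphometry, and confusion-matrix accuracy scores.

Processing order for node definition: remove sub-100-px injured islands
(noise), then merge nearby injured regions with five morphological
dilations followed by five erosions using a diameter-5 disk, then extract
8-connected injured components as nodes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .types import (
    AIR,
    BACKGROUND,
    INJURY,
    OTHER,
    TISSUE_CLASSES,
    ConfusionSummary,
    DegenerateClusterError,
    InjuryNode,
    InvalidInputError,
    InvalidParameterError,
    LobeMask,
)

#: 8-connectivity structuring element for component labeling.
_EIGHT = np.ones((3, 3), dtype=bool)


def exclude_background(
    intensity: np.ndarray, k: int = 2, seed: int = 0
) -> np.ndarray:
    """Flag non-background pixels of a grayscale image via k-means.

    Clusters pixel intensities into k groups; the brightest-mean cluster
    (bare slide / artifact outside the section) is marked background.
    Returns a boolean mask that is True on retained (tissue) pixels.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    values = np.asarray(intensity, dtype=float)
    if np.ptp(values) == 0:
        raise DegenerateClusterError("constant image: clusters are degenerate")
    flat = values.ravel()
    rng = np.random.default_rng(seed)
    # deterministic quantile init, then plain Lloyd iterations on 1-D data
    centers = np.quantile(flat, (np.arange(k) + 0.5) / k)
    centers = np.unique(centers)
    while len(centers) < k:  # duplicate quantiles on coarse histograms
        centers = np.unique(np.append(centers, centers[-1] + rng.random()))
    for _ in range(100):
        assign = np.argmin(np.abs(flat[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [flat[assign == i].mean() if np.any(assign == i) else centers[i]
             for i in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    if np.ptp(centers) == 0:
        raise DegenerateClusterError("all cluster means coincide")
    background_cluster = int(np.argmax(centers))
    return (assign != background_cluster).reshape(values.shape)


def build_lobe_masks(
    image: np.ndarray,
    gap_px: float = 100.0,
    min_mask_px: int = 100_000,
) -> list[LobeMask]:
    """Construct lobe masks from the 'other' tissue class.

    Connected 'other' regions are grouped together when their boundary-to-
    boundary distance is within ``gap_px`` (regions further apart become
    separate masks), interior holes (large airways, enclosed airspaces) are
    filled, and masks smaller than ``min_mask_px`` are discarded as
    artifact. Returns masks in raster order of first appearance; the list
    may be empty.
    """
    other = np.asarray(image) == OTHER
    if not other.any():
        return []
    # grow every region by gap_px/2: unions connect iff boundary gap <= gap_px
    dist = ndi.distance_transform_edt(~other)
    grown = dist <= gap_px / 2.0
    group_labels, n_groups = ndi.label(grown, structure=_EIGHT)

    masks: list[LobeMask] = []
    lobe_id = 0
    for g in range(1, n_groups + 1):
        member = other & (group_labels == g)
        if not member.any():
            continue
        filled = ndi.binary_fill_holes(member)
        if int(filled.sum()) < min_mask_px:
            continue
        masks.append(LobeMask(grid=filled, lobe_id=lobe_id))
        lobe_id += 1
    return masks


def filter_small_islands(image: np.ndarray, min_px: int = 100) -> np.ndarray:
    """Reassign 8-connected injured islands of area < min_px to 'other'.

    The threshold is strict: a 100-px island survives a min_px=100 filter.
    """
    if min_px < 1:
        raise InvalidParameterError("min_px must be >= 1")
    image = np.asarray(image)
    out = image.copy()
    labels, n = ndi.label(image == INJURY, structure=_EIGHT)
    if n == 0 or min_px == 1:
        return out
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    small = np.flatnonzero(sizes[1:] < min_px) + 1
    if small.size:
        out[np.isin(labels, small)] = OTHER
    return out


def merge_close_injuries(
    image: np.ndarray,
    disk_diameter_px: int = 5,
    iterations: int = 5,
    mode: str = "sequential",
) -> np.ndarray:
    """Merge nearby injured regions by morphological dilation then erosion.

    mode="sequential" (default) applies ``iterations`` successive dilations
    followed by ``iterations`` successive erosions with a disk of the given
    diameter — one large closing that bridges gaps up to roughly
    2*iterations*radius px. mode="repeated_closing" instead applies
    ``iterations`` closings (dilate-erode pairs), which bridges only gaps
    up to ~2*radius px.

    The result is extensive on the injured set: every originally injured
    pixel stays injured, and bridged gap pixels become injured; all other
    pixels keep their original class.
    """
    if disk_diameter_px < 1 or disk_diameter_px % 2 == 0:
        raise InvalidParameterError("disk_diameter_px must be odd and >= 1")
    if iterations < 0:
        raise InvalidParameterError("iterations must be >= 0")
    if mode not in ("sequential", "repeated_closing"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    image = np.asarray(image)
    injured = image == INJURY
    if iterations == 0 or not injured.any():
        return image.copy()
    radius = (disk_diameter_px - 1) // 2
    footprint = morphology.disk(radius)
    # pad beyond the dilation reach so the image border never truncates the
    # grown mask (which would leave erosion residue at the edges)
    pad = iterations * radius + 1
    work = np.pad(injured, pad)
    if mode == "sequential":
        grown = ndi.binary_dilation(work, structure=footprint,
                                    iterations=iterations)
        final = ndi.binary_erosion(grown, structure=footprint,
                                   iterations=iterations)
    else:
        final = work
        for _ in range(iterations):
            d = ndi.binary_dilation(final, structure=footprint)
            final = ndi.binary_erosion(d, structure=footprint)
    final = final[pad:-pad, pad:-pad]
    final |= injured  # guard: closing is extensive; keep original pixels
    out = image.copy()
    out[final] = INJURY
    return out


def extract_injury_nodes(
    image: np.ndarray, mask: LobeMask | np.ndarray | None = None
) -> list[InjuryNode]:
    """One node per 8-connected injured component intersecting the mask.

    Centroid is the unweighted mean of the component's pixel coordinates
    ((row, col), 0-based, origin at the top-left pixel center); area is the
    pixel count; ids run in raster-scan order of component discovery.
    """
    image = np.asarray(image)
    labels, n = ndi.label(image == INJURY, structure=_EIGHT)
    if n == 0:
        return []
    mask_grid = None
    if mask is not None:
        mask_grid = mask.grid if isinstance(mask, LobeMask) else np.asarray(mask)
        if not mask_grid.any():
            return []
        keep = np.unique(labels[mask_grid & (labels > 0)])
    else:
        keep = np.arange(1, n + 1)
    if keep.size == 0:
        return []

    areas = np.bincount(labels.ravel(), minlength=n + 1)
    rows, cols = np.nonzero(labels)
    lab = labels[rows, cols]
    sum_r = np.bincount(lab, weights=rows, minlength=n + 1)
    sum_c = np.bincount(lab, weights=cols, minlength=n + 1)
    # raster order of first pixel per label
    flat_first = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(flat_first, lab, rows.astype(np.int64) * image.shape[1] + cols)
    keep = keep[np.argsort(flat_first[keep], kind="stable")]

    nodes = []
    for node_id, label_val in enumerate(keep):
        a = int(areas[label_val])
        nodes.append(
            InjuryNode(
                id=node_id,
                centroid_row=float(sum_r[label_val] / a),
                centroid_col=float(sum_c[label_val] / a),
                area_m=float(a),
            )
        )
    return nodes


def process_label_image(
    image: np.ndarray,
    mask: LobeMask | np.ndarray | None = None,
    min_px: int = 100,
    disk_diameter_px: int = 5,
    iterations: int = 5,
) -> tuple[np.ndarray, list[InjuryNode]]:
    """filter_small_islands -> merge_close_injuries -> extract_injury_nodes."""
    filtered = filter_small_islands(image, min_px=min_px)
    merged = merge_close_injuries(
        filtered, disk_diameter_px=disk_diameter_px, iterations=iterations
    )
    return merged, extract_injury_nodes(merged, mask)


def class_fractions(
    image: np.ndarray, mask: LobeMask | np.ndarray
) -> tuple[float, float, float]:
    """(injury, air, other) pixel fractions over in-mask tissue pixels."""
    image = np.asarray(image)
    grid = mask.grid if isinstance(mask, LobeMask) else np.asarray(mask)
    if not grid.any():
        raise InvalidInputError("empty lobe mask")
    pix = image[grid]
    counts = np.array([(pix == c).sum() for c in TISSUE_CLASSES], dtype=float)
    total = counts.sum()
    if total == 0:
        raise InvalidInputError("mask contains no tissue-class pixels")
    f = counts / total
    return float(f[0]), float(f[1]), float(f[2])


def confusion_summary(
    predicted: np.ndarray, truth: np.ndarray
) -> ConfusionSummary:
    """Score sampled pixels: per-class one-vs-rest sensitivity/specificity.

    Rows of the counts matrix are truth, columns predicted, both ordered
    (injury, air, other). A class absent from the truth has undefined
    sensitivity, reported as NaN.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise InvalidInputError("predicted and truth must have equal length")
    classes = TISSUE_CLASSES
    bad = ~np.isin(predicted, classes) | ~np.isin(truth, classes)
    if bad.any():
        raise InvalidInputError("codes must be in {injury, air, other}")
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    for i, t in enumerate(classes):
        for j, p in enumerate(classes):
            counts[i, j] = int(np.sum((truth == t) & (predicted == p)))
    total = counts.sum()
    sens: dict[int, float] = {}
    spec: dict[int, float] = {}
    for i, c in enumerate(classes):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        spec[c] = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    accuracy = counts.trace() / total if total else float("nan")
    return ConfusionSummary(
        counts=counts,
        classes=classes,
        sensitivity=sens,
        specificity=spec,
        accuracy=float(accuracy),
    )
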