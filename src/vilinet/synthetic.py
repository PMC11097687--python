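"""Synthetic lung-lobe label images with power-law injury sizes.

The study's histology is not deposited, so this module generates label
images (and matching ground truth) with the statistical structure the
analysis assumes: injury regions whose pixel areas follow
P(m) ~ m**(-alpha), placed uniformly over an elliptical lobe or biased
toward existing injuries ("clustered"), with a configurable minimum gap so
the morphological merging rules can be exercised deliberately.

Blobs are rasterized disks: the downstream network analysis uses only a
region's centroid and pixel area, so blob shape is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    AIR,
    BACKGROUND,
    INJURY,
    OTHER,
    GroundTruth,
    InvalidParameterError,
    LobeMask,
    PlacementError,
)

#: Rejection-sampling cap per blob; exceeding it raises PlacementError.
MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class SyntheticLobeSpec:
    """Parameters of one synthetic lobe.

    alpha is the power-law exponent of injury pixel areas (> 1, continuous
    sizes rounded to >= 1 px); xmin_px the minimum area; min_gap_px the
    minimum edge-to-edge spacing enforced between blobs (0 permits
    touching/merging); cluster_strength biases placement toward existing
    blobs when placement == "clustered" (0 reduces to uniform).
    """

    width_px: int = 768
    height_px: int = 768
    n_injuries: int = 150
    alpha: float = 2.5
    xmin_px: float = 100.0
    placement: str = "uniform"  # "uniform" | "clustered"
    cluster_strength: float = 0.0
    min_gap_px: int = 25
    air_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise InvalidParameterError("alpha must be > 1 (non-normalizable tail)")
        if self.xmin_px < 1:
            raise InvalidParameterError("xmin_px must be >= 1")
        if self.n_injuries < 0:
            raise InvalidParameterError("n_injuries must be >= 0")
        if self.placement not in ("uniform", "clustered"):
            raise InvalidParameterError(f"unknown placement {self.placement!r}")
        if self.cluster_strength < 0 or self.min_gap_px < 0:
            raise InvalidParameterError("cluster_strength and min_gap_px must be >= 0")
        if not (0 <= self.air_fraction < 1):
            raise InvalidParameterError("air_fraction must be in [0, 1)")


def sample_powerlaw_sizes(
    n: int, alpha: float, xmin: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw n continuous sizes from P(x) ~ x**(-alpha), x >= xmin.

    Inverse-CDF sampling: x = xmin * (1 - u)**(-1 / (alpha - 1)) for u
    uniform on [0, 1).
    """
    if alpha <= 1:
        raise InvalidParameterError("alpha must be > 1 (non-normalizable tail)")
    if xmin <= 0:
        raise InvalidParameterError("xmin must be > 0")
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    rng = seed if hasattr(seed, "random") else np.random.default_rng(seed)
    u = np.asarray(rng.random(n), dtype=float)
    return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def _elliptical_lobe(height: int, width: int) -> np.ndarray:
    """Inscribed ellipse standing in for a lobe outline."""
    r = (np.arange(height) - (height - 1) / 2) / (height / 2)
    c = (np.arange(width) - (width - 1) / 2) / (width / 2)
    return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    k = int(np.ceil(radius))
    rr, cc = np.mgrid[-k : k + 1, -k : k + 1]
    keep = rr**2 + cc**2 <= radius**2
    return rr[keep], cc[keep]


def sample_injury_configuration(spec: SyntheticLobeSpec) -> GroundTruth:
    """Sample blob centers and areas only (no rasterization).

    Placement uses rejection sampling against the elliptical lobe and the
    pairwise minimum-gap constraint (edge-to-edge: center distance >=
    r_i + r_j + min_gap_px). Clustered placement proposes, with probability
    cluster_strength / (1 + cluster_strength), a point near an already
    placed blob instead of a uniform point.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = sample_powerlaw_sizes(spec.n_injuries, spec.alpha, spec.xmin_px, rng)
    areas = np.maximum(1, np.rint(sizes).astype(int))
    # place large blobs first: they are the hardest to fit
    order = np.argsort(-areas)
    radii = np.sqrt(areas / np.pi)

    lobe = _elliptical_lobe(spec.height_px, spec.width_px)
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    placed_idx: list[int] = []
    p_cluster = (
        spec.cluster_strength / (1.0 + spec.cluster_strength)
        if spec.placement == "clustered"
        else 0.0
    )
    for idx in order:
        r_blob = radii[idx]
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            if centers and rng.random() < p_cluster:
                j = rng.integers(len(centers))
                scale = placed_r[j] + r_blob + spec.min_gap_px + 2.0
                row = centers[j][0] + rng.normal(0, scale)
                col = centers[j][1] + rng.normal(0, scale)
            else:
                row = rng.uniform(0, spec.height_px)
                col = rng.uniform(0, spec.width_px)
            ir, ic = int(row), int(col)
            if not (0 <= ir < spec.height_px and 0 <= ic < spec.width_px):
                continue
            if not lobe[ir, ic]:
                continue
            # keep the whole disk inside the image frame
            if (
                row - r_blob < 0
                or col - r_blob < 0
                or row + r_blob >= spec.height_px
                or col + r_blob >= spec.width_px
            ):
                continue
            ok = True
            for (pr, pc), rr in zip(centers, placed_r):
                if np.hypot(row - pr, col - pc) < r_blob + rr + spec.min_gap_px:
                    ok = False
                    break
            if ok:
                centers.append((row, col))
                placed_r.append(r_blob)
                placed_idx.append(int(idx))
                break
        else:
            raise PlacementError(int(idx), MAX_PLACEMENT_ATTEMPTS)

    nodes = []
    for node_id, (c, a_idx) in enumerate(
        sorted(zip(centers, placed_idx), key=lambda t: t[1])
    ):
        nodes.append((node_id, c[0], c[1], int(areas[a_idx])))
    return GroundTruth(nodes=nodes)


def generate_lobe_image(
    spec: SyntheticLobeSpec,
) -> tuple[np.ndarray, LobeMask, GroundTruth]:
    """Rasterize a synthetic lobe into a class label image.

    Injury blobs are disks with the sampled areas; remaining lobe pixels
    are split between 'air' (a seeded Bernoulli speckle at
    spec.air_fraction) and 'other'; pixels outside the lobe are background.
    Returns (label image, lobe mask, ground truth with true centroids and
    intended areas; rasterized areas match within disk-rounding).
    """
    truth = sample_injury_configuration(spec)
    lobe = _elliptical_lobe(spec.height_px, spec.width_px)
    image = np.full((spec.height_px, spec.width_px), BACKGROUND, dtype=np.uint8)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA1B]))
    air = rng.random(image.shape) < spec.air_fraction
    image[lobe] = np.where(air[lobe], AIR, OTHER)

    for _, row, col, area in truth.nodes:
        radius = np.sqrt(area / np.pi)
        rr, cc = _disk_offsets(radius)
        pr = np.clip(np.rint(row).astype(int) + rr, 0, spec.height_px - 1)
        pc = np.clip(np.rint(col).astype(int) + cc, 0, spec.width_px - 1)
        image[pr, pc] = INJURY

    return image, LobeMask(grid=lobe, lobe_id=0), truth


def generate_toy_fixture() -> np.ndarray:
    """Deterministic small label image for exact post-processing tests.

    Manifest (rectangular injured islands on an all-'other' field, 200x200):

    ======  ===================  =========  ====================================
    island  placement (r, c)     area (px)  purpose
    ======  ===================  =========  ====================================
    A       rows 10-18, 10-20    9x11 = 99  removed by the 100-px island filter
    B       rows 50-59, 10-19    10x10=100  survives the filter (strict '<100')
    C       rows 90-99, 10-24    10x15=150  survives the filter
    D1      rows 140-149, 10-19  10x10=100  pair separated by a 4-px column gap:
    D2      rows 140-149, 24-33  10x10=100  merged by 5x dilation/erosion (r=2)
    E       rows 140-149,100-109 10x10=100  isolated control: unchanged by merge
    ======  ===================  =========  ====================================

    All other inter-island gaps exceed 20 px, the bridging reach of five
    dilations with a diameter-5 (radius-2) disk, so only D1/D2 merge into a
    single 8-connected component containing both squares and the bridged
    gap pixels.
    """
    image = np.full((200, 200), OTHER, dtype=np.uint8)
    image[10:19, 10:21] = INJURY    # A: 99 px
    image[50:60, 10:20] = INJURY    # B: 100 px
    image[90:100, 10:25] = INJURY   # C: 150 px
    image[140:150, 10:20] = INJURY  # D1
    image[140:150, 24:34] = INJURY  # D2 (gap columns 20-23: 4 px)
    image[140:150, 100:110] = INJURY  # E
    return image


TOY_FIXTURE_MANIFEST = {
    "A": dict(area=99, slice_=((10, 19), (10, 21))),
    "B": dict(area=100, slice_=((50, 60), (10, 20))),
    "C": dict(area=150, slice_=((90, 100), (10, 25))),
    "D1": dict(area=100, slice_=((140, 150), (10, 20))),
    "D2": dict(area=100, slice_=((140, 150), (24, 34))),
    "E": dict(area=100, slice_=((140, 150), (100, 110))),
}
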