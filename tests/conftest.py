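import numpy as np
import pytest

from vilinet import InjuryNode, ModelParams, pairwise_weight


@pytest.fixture
def random_nodes():
    """Factory: n nodes with uniform centroids and log-uniform areas."""

    def make(n: int, seed: int = 0, extent: float = 100.0) -> list[InjuryNode]:
        rng = np.random.default_rng(seed)
        return [
            InjuryNode(
                id=i,
                centroid_row=float(rng.uniform(0, extent)),
                centroid_col=float(rng.uniform(0, extent)),
                area_m=float(10 ** rng.uniform(2, 4)),
            )
            for i in range(n)
        ]

    return make


def brute_force_parents(nodes, params: ModelParams):
    """O(n^2) argmin oracle for the time-free network (child, parent) pairs."""
    out = []
    for child in nodes:
        best = None
        for cand in nodes:
            if cand.id == child.id:
                continue
            w = pairwise_weight(cand, child, params)
            key = (w, -cand.area_m, cand.id)
            if best is None or key < best[0]:
                best = (key, cand.id)
        out.append((child.id, best[1]))
    return out


def brute_force_timed_parents(nodes, times, params: ModelParams):
    """O(n^2) argmin oracle over strictly earlier events (child, parent)."""
    out = []
    for child in nodes:
        best = None
        for cand in nodes:
            dt = times[child.id] - times[cand.id]
            if cand.id == child.id or dt <= 0:
                continue
            w = pairwise_weight(cand, child, params) * dt
            if best is None or w < best[0]:
                best = (w, cand.id)
        if best is not None:
            out.append((child.id, best[1]))
    return out


def set_morphology_closing(mask: np.ndarray, radius: int, iterations: int):
    """Independent dilation/erosion oracle via explicit pixel-offset shifts.

    Dilation: union of the mask translated by every offset of the disk;
    erosion: intersection. Works on a zero-padded copy so the image border
    never clips the grown set.
    """
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    pad = iterations * radius + 1
    work = np.pad(mask.astype(bool), pad)

    def dilate(m):
        out = np.zeros_like(m)
        for dr, dc in offsets:
            out |= np.roll(np.roll(m, dr, axis=0), dc, axis=1)
        return out

    def erode(m):
        out = np.ones_like(m)
        for dr, dc in offsets:
            out &= np.roll(np.roll(m, dr, axis=0), dc, axis=1)
        return out

    for _ in range(iterations):
        work = dilate(work)
    for _ in range(iterations):
        work = erode(work)
    return work[pad:-pad, pad:-pad]
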