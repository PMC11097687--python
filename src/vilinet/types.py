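"""Core data containers shared across the pipeline.

Pixel classes use integer codes on a rectangular grid: 0 = background
(outside the section or excluded artifact), 1 = injured parenchyma
(atelectasis / airspace edema), 2 = air, 3 = other tissue (patent septa,
airway walls, interstitium).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BACKGROUND: int = 0
INJURY: int = 1
AIR: int = 2
OTHER: int = 3

CLASS_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    INJURY: "injury",
    AIR: "air",
    OTHER: "other",
}

#: Classes scored in morphometry / confusion analysis (background excluded).
TISSUE_CLASSES: tuple[int, int, int] = (INJURY, AIR, OTHER)


class VilinetError(Exception):
    """Base class for pipeline errors."""


class InvalidParameterError(VilinetError, ValueError):
    pass


class InvalidInputError(VilinetError, ValueError):
    pass


class PlacementError(VilinetError, RuntimeError):
    """Raised when a synthetic blob cannot be placed within the attempt cap."""

    def __init__(self, blob_index: int, attempts: int):
        self.blob_index = blob_index
        self.attempts = attempts
        super().__init__(
            f"could not place blob {blob_index} after {attempts} attempts"
        )


class DegenerateClusterError(VilinetError, ValueError):
    """k-means background exclusion on an (effectively) constant image."""


class DegenerateGeometryError(VilinetError, ValueError):
    """Coincident centroids make the pairwise distance zero."""


class InsufficientTailError(VilinetError, ValueError):
    """Fewer than the minimum tail samples at/above x_min."""


@dataclass(frozen=True)
class InjuryNode:
    """One discrete injured region.

    ``magnitude`` is log10(area / m_ref) with reference size m_ref = 1 px,
    in analogy to the Richter scale.
    """

    id: int
    centroid_row: float
    centroid_col: float
    area_m: float

    @property
    def magnitude(self) -> float:
        return math.log10(self.area_m)


@dataclass
class LobeMask:
    """Boolean mask of one lung lobe, same shape as the label image."""

    grid: np.ndarray
    lobe_id: int = 0

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.grid))


@dataclass
class ConfusionSummary:
    """One-vs-rest accuracy summary of sampled-pixel scoring.

    ``counts``: rows = truth, cols = predicted, ordered (injury, air, other).
    Sensitivity/specificity are NaN for a class absent from the truth
    (respectively: absent from the complement).
    """

    counts: np.ndarray
    classes: tuple[int, ...]
    sensitivity: dict[int, float]
    specificity: dict[int, float]
    accuracy: float


@dataclass
class ModelParams:
    """Parameters of the expected-count correlation weight.

    weight = C * l**df * [t *] delta_m * m_parent**(-alpha)

    ``alpha`` and ``df`` are the lobe-specific injury-size exponent and
    box-counting fractal dimension; C and delta_m cancel in every argmin
    and percentile threshold, so their defaults are 1.
    """

    alpha: float
    df: float
    C: float = 1.0
    delta_m: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise InvalidParameterError("C must be > 0")
        if self.delta_m <= 0:
            raise InvalidParameterError("delta_m must be > 0")


@dataclass
class CorrelationNetwork:
    """Nearest-neighbor correlation network.

    One directed edge per non-root node, stored child -> parent with the
    minimized weight; smaller weight = stronger (less likely by chance)
    correlation.
    """

    nodes: list[InjuryNode]
    edges: list[tuple[int, int, float]]  # (child_id, parent_id, weight)
    root_ids: list[int] = field(default_factory=list)

    @property
    def node_ids(self) -> list[int]:
        return [n.id for n in self.nodes]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.edges], dtype=float)

    def in_degrees(self) -> dict[int, int]:
        deg = {n.id: 0 for n in self.nodes}
        for _, parent, _ in self.edges:
            deg[parent] += 1
        return deg

    def to_networkx(self, reverse: bool = False):
        import networkx as nx

        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, area=float(n.area_m), row=n.centroid_row,
                       col=n.centroid_col)
        for child, parent, w in self.edges:
            if reverse:
                g.add_edge(parent, child, weight=float(w))
            else:
                g.add_edge(child, parent, weight=float(w))
        return g


@dataclass
class CentralityScores:
    """Per-node PageRank scores (sum to 1 over the lobe)."""

    scores: dict[int, float]
    damping: float = 0.85

    def normalized(self) -> dict[int, float]:
        """Rescaled so the top score is 1 (per-lobe display convention)."""
        top = max(self.scores.values())
        return {k: v / top for k, v in self.scores.items()}


@dataclass
class PowerLawFit:
    """Maximum-likelihood power-law fit with KS plausibility.

    ``plausible`` is None until a bootstrap p-value has been attached and
    then equals p_value >= 0.1.
    """

    alpha_hat: float
    xmin_hat: float
    n_tail: int
    ks_D: float
    variant: str  # "continuous" | "discrete"
    xmin_fixed: bool
    p_value: float | None = None

    @property
    def plausible(self) -> bool | None:
        if self.p_value is None:
            return None
        return self.p_value >= 0.1


@dataclass
class FractalEstimate:
    """Box-counting fractal dimension of the injured set within a lobe."""

    df: float
    intercept: float
    box_sizes: np.ndarray
    counts: np.ndarray
    r_squared: float


@dataclass
class TemporalAssignment:
    """Random event order with exponential inter-event intervals."""

    order: np.ndarray          # node ids in event order
    times: dict[int, float]    # node id -> event time (s)
    mean_interval_s: float
    seed: int | None = None


@dataclass
class RateCurve:
    """Secondary-event rate in exponentially growing elapsed-time bins."""

    bin_edges_s: np.ndarray
    rate_per_s: np.ndarray         # ensemble mean
    ci_low: np.ndarray
    ci_high: np.ndarray
    magnitude_class: int | str = "all"
    n_events: int = 0


@dataclass
class BootstrapResult:
    observed_stat: float
    p_value: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None = None
    sided: str = "two-sided"
    flags: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Blob inventory of a synthetic lobe: (id, row, col, area) + times."""

    nodes: list[tuple[int, float, float, int]]
    times: list[float] | None = None

    def to_injury_nodes(self) -> list[InjuryNode]:
        return [InjuryNode(i, r, c, a) for i, r, c, a in self.nodes]
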