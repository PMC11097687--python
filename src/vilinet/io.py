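"""Reading and writing the pipeline's file formats.

Label images are single-channel 8-bit TIFF or PNG with integer codes
{0=background, 1=injury, 2=air, 3=other}; node tables, edge lists,
centralities, overlap and rate curves are CSV; fits and manifests are
JSON; networks also export to GraphML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    CorrelationNetwork,
    GroundTruth,
    InjuryNode,
    InvalidInputError,
    LobeMask,
    PowerLawFit,
    RateCurve,
)

VALID_CODES = frozenset({0, 1, 2, 3})


def read_label_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise InvalidInputError(f"{path}: label image must be single-channel 2-D")
    if not set(np.unique(arr)).issubset(VALID_CODES):
        raise InvalidInputError(f"{path}: codes outside {{0,1,2,3}}")
    return arr.astype(np.uint8)


def write_label_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)


def write_mask(path: str | Path, mask: LobeMask) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def read_intensity_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse RGB to luminance
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(float)


def nodes_to_frame(nodes: list[InjuryNode]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [n.id for n in nodes],
            "row": [n.centroid_row for n in nodes],
            "col": [n.centroid_col for n in nodes],
            "area": [n.area_m for n in nodes],
            "magnitude": [n.magnitude for n in nodes],
        }
    )


def write_nodes(path: str | Path, nodes: list[InjuryNode]) -> None:
    nodes_to_frame(nodes).to_csv(path, index=False)


def read_nodes(path: str | Path) -> list[InjuryNode]:
    df = pd.read_csv(path)
    return [
        InjuryNode(int(r.id), float(r.row), float(r.col), float(r.area))
        for r in df.itertuples()
    ]


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    rows = []
    for i, (node_id, r, c, a) in enumerate(truth.nodes):
        t = truth.times[i] if truth.times else ""
        rows.append({"id": node_id, "row": r, "col": c, "area": a, "time": t})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_edge_list(path: str | Path, net: CorrelationNetwork) -> None:
    pd.DataFrame(net.edges, columns=["child", "parent", "weight"]).to_csv(
        path, index=False
    )


def write_graphml(path: str | Path, net: CorrelationNetwork) -> None:
    nx.write_graphml(net.to_networkx(), Path(path))


def fit_to_dict(fit: PowerLawFit) -> dict:
    d = dataclasses.asdict(fit)
    d["plausible"] = fit.plausible
    return d


def write_fit(path: str | Path, fit: PowerLawFit) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2))


def write_rate_curves(path: str | Path, curves: list[RateCurve]) -> None:
    rows = []
    for curve in curves:
        for k in range(len(curve.rate_per_s)):
            rows.append(
                {
                    "bin_lo": curve.bin_edges_s[k],
                    "bin_hi": curve.bin_edges_s[k + 1],
                    "rate": curve.rate_per_s[k],
                    "ci_lo": curve.ci_low[k],
                    "ci_hi": curve.ci_high[k],
                    "magnitude_class": curve.magnitude_class,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(payload, indent=2, default=default))
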