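"""Run configuration with the analysis defaults, YAML/JSON round-trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import InvalidParameterError


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the published defaults.

    input_mode "synthetic" generates lobes from the synthetic module;
    "label-images" reads user-supplied label images listed in ``inputs``
    (optionally with a sample sheet CSV mapping file -> group for group
    comparisons).
    """

    input_mode: str = "synthetic"
    inputs: list[str] = field(default_factory=list)
    sample_sheet: str | None = None
    output_dir: str = "vilinet_out"
    seed: int = 0

    # segmentation post-processing
    min_px: int = 100
    disk_diameter_px: int = 5
    merge_iterations: int = 5
    merge_mode: str = "sequential"
    mask_min_px: int = 100_000
    mask_gap_px: float = 100.0

    # power-law fitting
    p_plausible: float = 0.1
    fit_n_boot: int = 200
    size_xmin: float | None = None  # None = KS scan

    # network
    damping: float = 0.85
    threshold_percentiles: list[float] = field(
        default_factory=lambda: [25.0, 50.0, 75.0, 90.0]
    )
    reverse_edges: bool = False

    # temporal simulation
    mean_interval_s: float = 2.0
    n_reps: int = 100
    bin_growth: float = 2.0
    top_frac_no_time: float = 0.005

    # resampling
    n_boot: int = 10_000

    # synthetic mode
    synth_width_px: int = 768
    synth_height_px: int = 768
    synth_n_injuries: int = 150
    synth_alpha: float = 2.5
    synth_xmin_px: float = 100.0
    synth_placement: str = "uniform"
    synth_cluster_strength: float = 0.0
    synth_min_gap_px: int = 25
    synth_n_lobes: int = 2

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "label-images"):
            raise InvalidParameterError(
                f"unknown input_mode {self.input_mode!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
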