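"""End-to-end orchestration: images -> nodes -> fits -> networks -> rates.

Per lobe: post-process the label image into injury nodes, fit the
injury-size power law and the box-counting fractal dimension, build the
time-free correlation network (plus a threshold spectrum and PageRank
hubs), run the temporal ensemble with in-degree fits, centrality overlap
and secondary-event rate curves, and write every table. Across lobes,
group differences in injured fraction are tested by pooled bootstrap with
Benjamini–Hochberg correction.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from . import network as vnet
from . import powerlaw as vpl
from . import segment as vseg
from . import temporal as vtemp
from .bootstrap import benjamini_hochberg, bootstrap_group_difference
from .config import RunConfig
from .synthetic import SyntheticLobeSpec, generate_lobe_image
from .types import InvalidInputError, LobeMask, ModelParams

log = logging.getLogger("vilinet")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig, out: Path):
    """Yield (name, image, mask-or-None, group) per lobe."""
    if config.input_mode == "synthetic":
        ss = np.random.SeedSequence(config.seed)
        groups = ["CTRL", "LAV"]
        for k, child in enumerate(ss.spawn(config.synth_n_lobes)):
            spec = SyntheticLobeSpec(
                width_px=config.synth_width_px,
                height_px=config.synth_height_px,
                n_injuries=config.synth_n_injuries,
                alpha=config.synth_alpha,
                xmin_px=config.synth_xmin_px,
                placement=config.synth_placement,
                cluster_strength=config.synth_cluster_strength,
                min_gap_px=config.synth_min_gap_px,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            image, mask, truth = generate_lobe_image(spec)
            name = f"synthetic_lobe_{k}"
            vio.write_ground_truth(out / f"{name}_truth.csv", truth)
            yield name, image, mask, groups[k % len(groups)]
    else:
        sheet = {}
        if config.sample_sheet:
            df = pd.read_csv(config.sample_sheet)
            sheet = dict(zip(df["file"].astype(str), df["group"].astype(str)))
        for path_str in config.inputs:
            path = Path(path_str)
            if not path.exists():
                raise InvalidInputError(f"missing input: {path}")
            image = vio.read_label_image(path)
            masks = vseg.build_lobe_masks(
                image, gap_px=config.mask_gap_px, min_mask_px=config.mask_min_px
            )
            group = sheet.get(path.name, sheet.get(str(path), "ungrouped"))
            if not masks:
                log.warning("%s: no lobe mask survives the size filter", path)
                yield path.stem, image, None, group
            for mask in masks:
                yield f"{path.stem}_lobe{mask.lobe_id}", image, mask, group


def _analyze_lobe(name, image, mask, config: RunConfig, out: Path, rng) -> dict:
    stage = "segmentation"
    try:
        merged, nodes = vseg.process_label_image(
            image, mask,
            min_px=config.min_px,
            disk_diameter_px=config.disk_diameter_px,
            iterations=config.merge_iterations,
        )
        vio.write_nodes(out / f"{name}_nodes.csv", nodes)
        result: dict = {"name": name, "n_nodes": len(nodes)}
        if mask is not None:
            fi, fa, fo = vseg.class_fractions(image, mask)
            result["fractions"] = {"injury": fi, "air": fa, "other": fo}
        if len(nodes) < vpl.MIN_TAIL:
            log.info("%s: only %d node(s); downstream stages skipped",
                     name, len(nodes))
            result["skipped"] = (
                f"fewer than {vpl.MIN_TAIL} injury nodes for tail fitting"
            )
            return result

        stage = "powerlaw_fit"
        areas = np.array([n.area_m for n in nodes])
        size_fit = vpl.fit_with_plausibility(
            areas, variant="continuous", xmin=config.size_xmin,
            n_boot=config.fit_n_boot, seed=rng,
        )
        vio.write_fit(out / f"{name}_size_fit.json", size_fit)
        injured = np.asarray(merged) == 1
        frac = vpl.box_counting_dimension(injured, mask)
        pd.DataFrame(
            {"box_size": frac.box_sizes, "count": frac.counts}
        ).to_csv(out / f"{name}_boxcounts.csv", index=False)
        result["size_alpha"] = size_fit.alpha_hat
        result["size_plausible"] = size_fit.plausible
        result["df"] = frac.df

        stage = "network"
        params = ModelParams(alpha=size_fit.alpha_hat, df=frac.df)
        net = vnet.build_network(nodes, params)
        vio.write_edge_list(out / f"{name}_edges.csv", net)
        vio.write_graphml(out / f"{name}_network.graphml", net)
        spectrum = {
            pct: len(vnet.threshold_network(net, pct).edges)
            for pct in config.threshold_percentiles
        }
        result["threshold_edge_counts"] = spectrum
        degrees = vnet.in_degree_distribution(net)
        deg_fit = None
        if int((degrees >= 1).sum()) >= vpl.MIN_TAIL:
            deg_fit = vpl.fit_with_plausibility(
                degrees[degrees >= 1], variant="discrete", xmin=1,
                n_boot=config.fit_n_boot, seed=rng,
            )
            vio.write_fit(out / f"{name}_indegree_fit.json", deg_fit)
            result["indegree_gamma"] = deg_fit.alpha_hat
            result["indegree_plausible"] = deg_fit.plausible
        scores = vnet.pagerank_centrality(
            net, damping=config.damping, reverse_edges=config.reverse_edges
        )
        pd.DataFrame(
            {"id": list(scores.scores), "pagerank": list(scores.scores.values())}
        ).to_csv(out / f"{name}_centrality.csv", index=False)

        stage = "temporal"
        ensemble = vtemp.ensemble_run(
            nodes, params, n_reps=config.n_reps,
            mean_interval_s=config.mean_interval_s,
            seed=int(rng.integers(2**31)),
            n_boot=config.fit_n_boot,
        )
        assignments = [a for a, _, _ in ensemble]
        nets = [n for _, n, _ in ensemble]
        fits = [f for _, _, f in ensemble if f is not None]
        if deg_fit is not None and fits:
            cmp = vtemp.compare_gamma(
                deg_fit, fits, n_boot=config.n_boot,
                seed=int(rng.integers(2**31)),
            )
            vio.write_json(out / f"{name}_gamma_compare.json", cmp)
            result["gamma_median"] = cmp["median_gamma"]
        ens_scores = [
            vnet.pagerank_centrality(n, damping=config.damping,
                                     reverse_edges=config.reverse_edges)
            for n in nets
        ]
        overlap = vtemp.centrality_overlap(
            scores, ens_scores, top_frac_no_time=config.top_frac_no_time,
            nodes=nodes, n_boot=config.n_boot,
            seed=int(rng.integers(2**31)),
        )
        pd.DataFrame(overlap).to_csv(out / f"{name}_overlap.csv", index=False)
        curves = vtemp.secondary_event_rates(
            nets, assignments, bin_growth=config.bin_growth,
            n_boot=config.n_boot, seed=int(rng.integers(2**31)),
        )
        vio.write_rate_curves(out / f"{name}_rates.csv", curves)
        return result
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed for lobe {name}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    t0 = time.time()
    lobes = []
    groups: dict[str, list[float]] = {}
    for name, image, mask, group in _load_inputs(config, out):
        t_lobe = time.time()
        result = _analyze_lobe(name, image, mask, config, out, rng)
        result["group"] = group
        if "fractions" in result:
            groups.setdefault(group, []).append(result["fractions"]["injury"])
        lobes.append(result)
        log.info("lobe %s done in %.1fs", name, time.time() - t_lobe)

    comparisons = []
    names = sorted(g for g in groups if len(groups[g]) >= 2)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = bootstrap_group_difference(
                groups[names[i]], groups[names[j]], stat="median",
                n_boot=config.n_boot, seed=int(rng.integers(2**31)),
            )
            comparisons.append(
                {"a": names[i], "b": names[j],
                 "difference": res.observed_stat, "p": res.p_value,
                 "ci": [res.ci_low, res.ci_high]}
            )
    if comparisons:
        reject, adjusted = benjamini_hochberg(
            [c["p"] for c in comparisons]
        )
        for c, r, padj in zip(comparisons, reject, adjusted):
            c["p_adjusted"] = float(padj)
            c["significant"] = bool(r)

    log.info("pipeline finished in %.1fs", time.time() - t0)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "lobes": lobes,
        "group_comparisons": comparisons,
        "outputs": {},
    }
    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    vio.write_json(out / "manifest.json", manifest)
    return manifest
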