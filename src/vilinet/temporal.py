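"""Simulated injury-event times and the time-extended correlation network.

Histological measurement is terminal, so injury timing cannot be observed
in the same animal. Instead, event times are simulated: a uniformly random
injury order with exponential inter-event intervals (Poisson process,
mean 2 s by default), repeated over an ensemble (100 replicates by
default) to form distributions. The time-extended weight

    n_ij = C * l_ij**df * t_ij * delta_m * m_i**(-alpha),  t_ij = t_j - t_i

correlates regions across space and time; candidate parents are the
strictly earlier events and each later event links to its minimizing
parent, so the earliest event is the single root. Secondary-injury
("aftershock") rates are then read off the edges as events per second in
exponentially growing elapsed-time bins, stratified by the parent's
log10-magnitude — the lung analogue of Omori's law.
"""

from __future__ import annotations

import math

import numpy as np

from .powerlaw import PowerLawFit, fit_with_plausibility
from .types import (
    CentralityScores,
    CorrelationNetwork,
    InjuryNode,
    InvalidInputError,
    InvalidParameterError,
    ModelParams,
    RateCurve,
    TemporalAssignment,
)


def assign_times(
    nodes: list[InjuryNode],
    mean_interval_s: float = 2.0,
    seed: int | np.random.Generator | None = None,
) -> TemporalAssignment:
    """Random event order with exponential inter-event intervals.

    The node order is a uniformly random permutation; event times are
    cumulative sums of i.i.d. exponential intervals with the given mean
    (first event one interval after t = 0).
    """
    if mean_interval_s <= 0:
        raise InvalidParameterError("mean_interval_s must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = np.array([n.id for n in nodes], dtype=int)
    order = rng.permutation(ids)
    times = np.cumsum(rng.exponential(mean_interval_s, size=len(ids)))
    return TemporalAssignment(
        order=order,
        times={int(i): float(t) for i, t in zip(order, times)},
        mean_interval_s=mean_interval_s,
    )


def build_time_network(
    nodes: list[InjuryNode],
    assignment: TemporalAssignment,
    params: ModelParams,
) -> CorrelationNetwork:
    """Time-extended nearest-neighbor network over timed events.

    Each non-earliest event links to the strictly earlier event minimizing
    n_ij; the earliest event is the root. Ties (probability zero under
    continuous intervals) break by event order.
    """
    if len(nodes) < 2:
        return CorrelationNetwork(
            nodes=list(nodes), edges=[], root_ids=[n.id for n in nodes]
        )
    missing = [n.id for n in nodes if n.id not in assignment.times]
    if missing:
        raise InvalidInputError(f"nodes without event times: {missing[:5]}")

    from .network import _weight_matrix

    W = _weight_matrix(nodes, params)  # spatial part, parent rows
    t = np.array([assignment.times[n.id] for n in nodes])
    ids = [n.id for n in nodes]
    dt = t[None, :] - t[:, None]  # dt[i, j] = t_j - t_i
    with np.errstate(invalid="ignore"):  # inf * 0 on the diagonal
        Wt = np.where(dt > 0, W * dt, np.inf)

    order_rank = {int(i): r for r, i in enumerate(assignment.order)}
    edges = []
    roots = []
    for j in range(len(nodes)):
        col = Wt[:, j]
        if not np.isfinite(col).any():
            roots.append(ids[j])
            continue
        wmin = col.min()
        tied = np.flatnonzero(col == wmin)
        if len(tied) > 1:
            tied = sorted(tied, key=lambda i: order_rank[ids[i]])
        i = int(tied[0])
        edges.append((ids[j], ids[i], float(Wt[i, j])))
    return CorrelationNetwork(nodes=list(nodes), edges=edges, root_ids=roots)


def replicate_seeds(master_seed: int | None, n_reps: int) -> list[np.random.Generator]:
    """Deterministic per-replicate generators derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(s) for s in ss.spawn(n_reps)]


def ensemble_run(
    nodes: list[InjuryNode],
    params: ModelParams,
    n_reps: int = 100,
    mean_interval_s: float = 2.0,
    seed: int | None = None,
    fit_in_degrees: bool = True,
    degree_xmin: float | None = 1.0,
    n_boot: int = 200,
) -> list[tuple[TemporalAssignment, CorrelationNetwork, PowerLawFit | None]]:
    """Repeat time assignment + network construction over an ensemble.

    Per replicate, returns the assignment, the time-extended network and —
    when ``fit_in_degrees`` — a discrete power-law fit (with bootstrap
    plausibility) of the positive in-degrees. Replicate randomness is
    derived deterministically from the master seed.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    from .network import in_degree_distribution

    out = []
    for rng in replicate_seeds(seed, n_reps):
        assignment = assign_times(nodes, mean_interval_s, rng)
        net = build_time_network(nodes, assignment, params)
        fit = None
        if fit_in_degrees:
            degrees = in_degree_distribution(net)
            degrees = degrees[degrees >= 1]
            try:
                fit = fit_with_plausibility(
                    degrees, variant="discrete", xmin=degree_xmin,
                    n_boot=n_boot, seed=rng,
                )
            except Exception:
                fit = None
        out.append((assignment, net, fit))
    return out


def compare_gamma(
    no_time_fit: PowerLawFit,
    ensemble_fits: list[PowerLawFit],
    n_boot: int = 10_000,
    seed: int | None = None,
):
    """Compare the timed ensemble's in-degree slope gamma to the time-free
    slope.

    Returns a dict with the ensemble median gamma, the time-free slope,
    their difference (median gamma - time-free alpha), a percentile
    bootstrap 95% CI of the difference over replicates, and a two-sided
    bootstrap p for difference = 0. A single-replicate ensemble yields a
    degenerate CI, flagged in the result.
    """
    if not ensemble_fits:
        raise InvalidInputError("ensemble is empty")
    gammas = np.array([f.alpha_hat for f in ensemble_fits])
    alpha0 = no_time_fit.alpha_hat
    observed = float(np.median(gammas) - alpha0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(gammas), size=(n_boot, len(gammas)))
    boot = np.median(gammas[idx], axis=1) - alpha0
    lo, hi = np.percentile(boot, [2.5, 97.5])
    p = 2 * min(float(np.mean(boot <= 0)), float(np.mean(boot >= 0)))
    p = min(1.0, max(p, 1.0 / n_boot))
    flags = ["degenerate-ci"] if len(gammas) < 2 else []
    return {
        "median_gamma": float(np.median(gammas)),
        "no_time_alpha": float(alpha0),
        "difference": observed,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p_value": p,
        "flags": flags,
    }


def centrality_overlap(
    no_time_scores: CentralityScores,
    ensemble_scores: list[CentralityScores],
    top_frac_no_time: float = 0.005,
    top_frac_time_grid: np.ndarray | None = None,
    nodes: list[InjuryNode] | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
):
    """Overlap of top time-free hubs with the top-f timed hubs, versus f.

    For each grid fraction f the overlap is the share of the top
    ``top_frac_no_time`` time-free nodes found within the top f timed
    nodes, averaged over the ensemble with a percentile bootstrap 95% CI.
    The chance line equals f itself. Returns a dict of arrays keyed by
    fraction / mean / ci_low / ci_high / chance.
    """
    from .network import top_fraction

    if top_frac_time_grid is None:
        top_frac_time_grid = np.concatenate(
            [np.arange(0.005, 0.105, 0.005), np.arange(0.12, 1.0001, 0.02)]
        )
    base_ids = set(no_time_scores.scores)
    for s in ensemble_scores:
        if set(s.scores) != base_ids:
            raise InvalidInputError("score sets cover different node ids")
    ref = top_fraction(no_time_scores, top_frac_no_time, nodes)
    rng = np.random.default_rng(seed)
    per_rep = np.empty((len(ensemble_scores), len(top_frac_time_grid)))
    for r, s in enumerate(ensemble_scores):
        ranked = sorted(
            s.scores, key=lambda i: (-s.scores[i], i)
        )
        for c, f in enumerate(top_frac_time_grid):
            k = math.ceil(f * len(ranked))
            per_rep[r, c] = len(ref.intersection(ranked[:k])) / len(ref)
    mean = per_rep.mean(axis=0)
    if len(ensemble_scores) > 1:
        idx = rng.integers(0, len(ensemble_scores), size=(n_boot, len(ensemble_scores)))
        boot = per_rep[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    else:
        lo = hi = mean
    return {
        "fraction": np.asarray(top_frac_time_grid, dtype=float),
        "mean": mean,
        "ci_low": lo,
        "ci_high": hi,
        "chance": np.asarray(top_frac_time_grid, dtype=float),
    }


def _exp_bin_edges(t_min: float, t_max: float, growth: float) -> np.ndarray:
    edges = [t_min]
    while edges[-1] <= t_max:
        edges.append(edges[-1] * growth)
    return np.array(edges)


def secondary_event_rates(
    ensemble: list[CorrelationNetwork],
    assignments: list[TemporalAssignment],
    bin_growth: float = 2.0,
    t_min: float | None = None,
    bin_edges: np.ndarray | None = None,
    per_primary: bool = False,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> list[RateCurve]:
    """Secondary-injury event rates versus elapsed time since the parent.

    Each edge contributes one secondary event at elapsed time
    t_child - t_parent, pooled per integer magnitude class floor(log10 m)
    of the parent and per replicate. Counts in exponentially growing time
    bins divided by the bin width give rates per second; the ensemble mean
    carries a percentile bootstrap 95% CI over replicates. An aggregate
    curve over all magnitudes is included last (magnitude_class="all").
    ``per_primary`` normalizes each class's rate by its number of distinct
    parents.
    """
    if not ensemble:
        raise InvalidInputError("empty ensemble")
    if len(ensemble) != len(assignments):
        raise InvalidInputError("ensemble and assignments differ in length")
    if bin_growth <= 1 and bin_edges is None:
        raise InvalidParameterError("bin_growth must be > 1")

    records = []  # (replicate, magnitude_class, elapsed, parent_id)
    for r, (net, asg) in enumerate(zip(ensemble, assignments)):
        area = {n.id: n.area_m for n in net.nodes}
        for child, parent, _ in net.edges:
            elapsed = asg.times[child] - asg.times[parent]
            if elapsed <= 0:
                raise InvalidInputError("edge with non-positive elapsed time")
            mag = math.floor(math.log10(area[parent]))
            records.append((r, mag, elapsed, parent))
    if not records:
        return [
            RateCurve(
                bin_edges_s=np.array([1.0, bin_growth]),
                rate_per_s=np.zeros(1), ci_low=np.zeros(1),
                ci_high=np.zeros(1), magnitude_class="all", n_events=0,
            )
        ]
    elapsed_all = np.array([e for _, _, e, _ in records])
    if bin_edges is None:
        lo = t_min if t_min is not None else float(elapsed_all.min())
        bin_edges = _exp_bin_edges(lo, float(elapsed_all.max()), bin_growth)
    bin_edges = np.asarray(bin_edges, dtype=float)
    widths = np.diff(bin_edges)
    n_reps = len(ensemble)
    rng = np.random.default_rng(seed)

    classes: list[int | str] = sorted({m for _, m, _, _ in records})
    classes.append("all")
    curves = []
    for cls in classes:
        sel = [rec for rec in records if cls == "all" or rec[1] == cls]
        per_rep = np.zeros((n_reps, len(widths)))
        n_parents = np.ones(n_reps)
        for r in range(n_reps):
            times = [rec[2] for rec in sel if rec[0] == r]
            counts, _ = np.histogram(times, bins=bin_edges)
            per_rep[r] = counts / widths
            if per_primary:
                parents = {rec[3] for rec in sel if rec[0] == r}
                n_parents[r] = max(1, len(parents))
        per_rep = per_rep / n_parents[:, None]
        mean = per_rep.mean(axis=0)
        if n_reps > 1:
            idx = rng.integers(0, n_reps, size=(n_boot, n_reps))
            boot = per_rep[idx].mean(axis=1)
            lo_ci, hi_ci = np.percentile(boot, [2.5, 97.5], axis=0)
        else:
            lo_ci = hi_ci = mean
        curves.append(
            RateCurve(
                bin_edges_s=bin_edges, rate_per_s=mean,
                ci_low=lo_ci, ci_high=hi_ci,
                magnitude_class=cls, n_events=len(sel),
            )
        )
    return curves
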