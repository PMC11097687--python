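"""Power-law fitting, KS plausibility testing, and box-counting dimension.

Maximum-likelihood fits with optional Kolmogorov–Smirnov scanning of the
lower cutoff x_min, and a semiparametric bootstrap plausibility test in
which p >= 0.1 means a power law is a plausible fit (the null hypothesis
is that the data could come from the fitted power law; high p = not
rejected).

Continuous variant (injury areas, which span orders of magnitude):
    pdf  f(x) = (alpha-1)/xmin * (x/xmin)**(-alpha),  x >= xmin
    MLE  alpha_hat = 1 + n / sum(ln(x_i / xmin))
Discrete variant (in-degrees, small integers):
    pmf  f(k) = k**(-alpha) / zeta(alpha, xmin),  k = xmin, xmin+1, ...
    alpha_hat maximizes the zeta-normalized likelihood numerically,
    started from the approximation 1 + n / sum(ln(x_i / (xmin - 0.5))).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, special

from .types import (
    FractalEstimate,
    InsufficientTailError,
    InvalidParameterError,
    LobeMask,
    PowerLawFit,
)

MIN_TAIL = 10
PLAUSIBILITY_THRESHOLD = 0.1


# ---------------------------------------------------------------- MLE + KS


def _alpha_mle_continuous(x: np.ndarray, xmin: float) -> float:
    s = np.log(x / xmin).sum()
    if s <= 0:
        raise InvalidParameterError(
            "divergent estimate: all samples equal to xmin"
        )
    return 1.0 + len(x) / s

def _alpha_start_discrete(x: np.ndarray, xmin: float) -> float:
    s = np.log(x / (xmin - 0.5)).sum()
    if s <= 0:
        raise InvalidParameterError(
            "divergent estimate: all samples equal to xmin"
        )
    return 1.0 + len(x) / s


def _alpha_mle_discrete(x: np.ndarray, xmin: float) -> float:
    n = len(x)
    log_sum = np.log(x).sum()

    def nll(alpha: float) -> float:
        return n * np.log(special.zeta(alpha, xmin)) + alpha * log_sum

    start = _alpha_start_discrete(x, xmin)
    res = optimize.minimize_scalar(
        nll, bounds=(1.0 + 1e-8, max(25.0, start * 2)), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _ks_continuous(x_sorted: np.ndarray, alpha: float, xmin: float) -> float:
    n = len(x_sorted)
    cdf = 1.0 - (x_sorted / xmin) ** (1.0 - alpha)
    lo = np.arange(n) / n
    hi = np.arange(1, n + 1) / n
    return float(np.max(np.maximum(np.abs(cdf - lo), np.abs(cdf - hi))))


def _ks_discrete(x: np.ndarray, alpha: float, xmin: float) -> float:
    values, counts = np.unique(x, return_counts=True)
    emp_cdf = np.cumsum(counts) / len(x)
    z0 = special.zeta(alpha, xmin)
    model_cdf = 1.0 - special.zeta(alpha, values + 1) / z0
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def _fit_fixed_xmin(x: np.ndarray, xmin: float, variant: str) -> tuple[float, float]:
    tail = x[x >= xmin]
    if variant == "continuous":
        alpha = _alpha_mle_continuous(tail, xmin)
        D = _ks_continuous(np.sort(tail), alpha, xmin)
    else:
        alpha = _alpha_mle_discrete(tail, xmin)
        D = _ks_discrete(tail, alpha, xmin)
    return alpha, D


def fit_powerlaw(
    samples: np.ndarray,
    variant: str = "continuous",
    xmin: float | None = None,
    max_xmin_candidates: int = 100,
) -> PowerLawFit:
    """Fit a power law by MLE, scanning x_min by KS minimization if unset.

    The scan considers the distinct sample values as candidate cutoffs
    (thinned to at most ``max_xmin_candidates``, evenly over the sorted
    distinct values), fits the tail above each and keeps the candidate
    with the smallest KS distance, following the Clauset–Shalizi–Newman
    procedure. Requires at least 10 tail samples.
    """
    if variant not in ("continuous", "discrete"):
        raise InvalidParameterError(f"unknown variant {variant!r}")
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if variant == "discrete":
        x = x[x >= 1]
        if not np.allclose(x, np.rint(x)):
            raise InvalidParameterError("discrete variant requires integers")
        x = np.rint(x)
    else:
        x = x[x > 0]

    if xmin is not None:
        n_tail = int(np.sum(x >= xmin))
        if n_tail < 2:
            raise InsufficientTailError(
                f"fewer than 2 samples at/above xmin={xmin}"
            )
        if n_tail < MIN_TAIL:
            warnings.warn(
                f"only {n_tail} tail samples: exponent estimate is unstable",
                stacklevel=2,
            )
        alpha, D = _fit_fixed_xmin(x, xmin, variant)
        return PowerLawFit(
            alpha_hat=alpha, xmin_hat=float(xmin), n_tail=int(np.sum(x >= xmin)),
            ks_D=D, variant=variant, xmin_fixed=True,
        )

    candidates = np.unique(x)
    # leave enough tail above the cutoff
    candidates = candidates[np.searchsorted(np.sort(x), candidates,
                                            side="left") <= len(x) - MIN_TAIL]
    if candidates.size == 0:
        raise InsufficientTailError(
            f"no candidate xmin leaves {MIN_TAIL} tail samples"
        )
    if candidates.size > max_xmin_candidates:
        idx = np.unique(
            np.linspace(0, candidates.size - 1, max_xmin_candidates).astype(int)
        )
        candidates = candidates[idx]

    best: tuple[float, float, float] | None = None  # (D, xmin, alpha)
    for cand in candidates:
        try:
            alpha, D = _fit_fixed_xmin(x, float(cand), variant)
        except InvalidParameterError:
            continue
        if best is None or D < best[0]:
            best = (D, float(cand), alpha)
    if best is None:
        raise InvalidParameterError(
            "divergent estimate at every candidate xmin"
        )
    D, xmin_hat, alpha = best
    return PowerLawFit(
        alpha_hat=alpha, xmin_hat=xmin_hat, n_tail=int(np.sum(x >= xmin_hat)),
        ks_D=D, variant=variant, xmin_fixed=False,
    )


# ------------------------------------------------------------- bootstrap p


def sample_discrete_powerlaw(
    n: int, alpha: float, xmin: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact zeta-law sampling by inverse CDF with binary search.

    The survival function S(k) = zeta(alpha, k) / zeta(alpha, xmin) is
    inverted per sample: the result is the smallest k >= xmin with
    S(k + 1) <= 1 - u.
    """
    if n == 0:
        return np.zeros(0)
    u = rng.random(n)
    z0 = special.zeta(alpha, xmin)
    target = (1.0 - u) * z0  # want smallest k with zeta(alpha, k+1) <= target
    lo = np.full(n, xmin, dtype=float)
    hi = np.full(n, xmin, dtype=float)
    # exponential search for an upper bound, then bisection
    need = special.zeta(alpha, hi + 1) > target
    while need.any():
        hi[need] = hi[need] * 2 + 1
        need = special.zeta(alpha, hi + 1) > target
    while np.any(hi > lo):
        mid = np.floor((lo + hi) / 2)
        ok = special.zeta(alpha, mid + 1) <= target
        hi = np.where(ok, mid, hi)
        lo = np.where(ok, lo, mid + 1)
    return lo


def _sample_tail(
    rng: np.random.Generator, n: int, alpha: float, xmin: float, variant: str
) -> np.ndarray:
    if variant == "continuous":
        u = rng.random(n)
        return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))
    return sample_discrete_powerlaw(n, alpha, int(xmin), rng)


def ks_plausibility(
    fit: PowerLawFit,
    samples: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Semiparametric bootstrap p-value for the power-law fit.

    Each replicate draws a synthetic dataset of the original size — points
    from the fitted tail model with probability n_tail/n, otherwise
    resampled from the observed below-xmin body (only relevant when x_min
    was scanned) — refits it under the same protocol (re-scanning x_min if
    it was scanned), and records the KS distance. p is the fraction of
    replicate KS distances >= the observed one; p >= 0.1 deems the power
    law plausible. Zero exceedances are reported at the resolution floor
    1/n_boot.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable p-value", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if fit.variant == "discrete":
        x = np.rint(x[x >= 1])
    else:
        x = x[x > 0]
    body = x[x < fit.xmin_hat]
    n_total = len(x)
    n_tail = fit.n_tail
    p_tail = n_tail / n_total

    # fast path: fixed xmin + continuous -> fully vectorized replicates
    if fit.xmin_fixed and fit.variant == "continuous" and len(body) == 0:
        u = rng.random((n_boot, n_total))
        sims = fit.xmin_hat * (1.0 - u) ** (-1.0 / (fit.alpha_hat - 1.0))
        sims.sort(axis=1)
        logs = np.log(sims / fit.xmin_hat).sum(axis=1)
        alphas = 1.0 + n_total / logs
        cdf = 1.0 - (sims / fit.xmin_hat) ** (1.0 - alphas[:, None])
        grid_lo = np.arange(n_total) / n_total
        grid_hi = np.arange(1, n_total + 1) / n_total
        D = np.maximum(np.abs(cdf - grid_lo), np.abs(cdf - grid_hi)).max(axis=1)
        exceed = int(np.sum(D >= fit.ks_D))
        return max(exceed / n_boot, 1.0 / n_boot)

    exceed = 0
    for _ in range(n_boot):
        take_tail = rng.random(n_total) < p_tail if len(body) else np.ones(
            n_total, dtype=bool
        )
        k = int(take_tail.sum())
        sim = np.empty(n_total)
        sim[take_tail] = _sample_tail(
            rng, k, fit.alpha_hat, fit.xmin_hat, fit.variant
        )
        if n_total - k:
            sim[~take_tail] = rng.choice(body, size=n_total - k, replace=True)
        try:
            refit = fit_powerlaw(
                sim,
                variant=fit.variant,
                xmin=fit.xmin_hat if fit.xmin_fixed else None,
            )
        except (InvalidParameterError, InsufficientTailError):
            exceed += 1  # un-fittable replicate counts against the model
            continue
        if refit.ks_D >= fit.ks_D:
            exceed += 1
    return max(exceed / n_boot, 1.0 / n_boot)


def fit_with_plausibility(
    samples: np.ndarray,
    variant: str = "continuous",
    xmin: float | None = None,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PowerLawFit:
    """fit_powerlaw followed by ks_plausibility; returns the completed fit."""
    import dataclasses

    fit = fit_powerlaw(samples, variant=variant, xmin=xmin)
    p = ks_plausibility(fit, samples, n_boot=n_boot, seed=seed)
    return dataclasses.replace(fit, p_value=p)


def histogram_slope(
    samples: np.ndarray, n_bins: int = 20
) -> tuple[float, float]:
    """Log-log histogram regression slope (comparison to the MLE exponent).

    Logarithmic bins; empty bins dropped. Returns (slope magnitude,
    intercept) where the density is ~ x**(-slope).
    """
    x = np.asarray(samples, dtype=float)
    x = x[x > 0]
    edges = np.geomspace(x.min(), x.max() * (1 + 1e-12), n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / widths / len(x)
    keep = dens > 0
    coeffs = np.polyfit(np.log(centers[keep]), np.log(dens[keep]), 1)
    return float(-coeffs[0]), float(coeffs[1])


# ------------------------------------------------------------ box counting


def box_counting_dimension(
    injury_mask: np.ndarray,
    lobe_mask: LobeMask | np.ndarray | None = None,
    base: int = 2,
    min_box_px: int = 1,
    grid_offsets: int = 1,
) -> FractalEstimate:
    """Box-counting fractal dimension of the injured set within a lobe.

    A grid of boxes, anchored at the top-left of the lobe-mask bounding
    box, is laid over the image; the box size starts at the largest power
    of ``base`` fitting the bounding box and is reduced by factors of
    ``base`` down to ``min_box_px``. d_f is the least-squares slope of
    log(occupied-box count) versus log(1/box size). ``grid_offsets`` > 1
    additionally tries that many diagonal grid shifts per size and keeps
    the smallest cover (reduces the anchoring bias on sparse sets).
    """
    injured = np.asarray(injury_mask, dtype=bool)
    if lobe_mask is not None:
        grid = lobe_mask.grid if isinstance(lobe_mask, LobeMask) else np.asarray(
            lobe_mask
        )
        injured = injured & grid
        ref = grid
    else:
        ref = injured
    if not injured.any():
        raise InvalidParameterError("no injured pixels inside the lobe mask")
    rows, cols = np.nonzero(ref)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    window = injured[r0:r1, c0:c1]
    extent = max(window.shape)

    def count_at(size: int, shift: int) -> int:
        shifted = np.pad(window, ((shift, 0), (shift, 0)))
        n_r = -(-shifted.shape[0] // size)
        n_c = -(-shifted.shape[1] // size)
        padded = np.zeros((n_r * size, n_c * size), dtype=bool)
        padded[: shifted.shape[0], : shifted.shape[1]] = shifted
        occupied = padded.reshape(n_r, size, n_c, size).any(axis=(1, 3))
        return int(occupied.sum())

    size = base ** int(np.floor(np.log(extent) / np.log(base)))
    sizes, counts = [], []
    while size >= max(1, min_box_px):
        shifts = [(k * size) // grid_offsets for k in range(grid_offsets)]
        sizes.append(size)
        counts.append(min(count_at(size, s) for s in dict.fromkeys(shifts)))
        size //= base

    sizes_arr = np.array(sizes, dtype=float)
    counts_arr = np.array(counts, dtype=float)
    if len(sizes_arr) < 2 or np.all(counts_arr == counts_arr[0]):
        warnings.warn("degenerate box-count fit (single scale or flat counts)",
                      stacklevel=2)
        if np.all(counts_arr == counts_arr[0]):
            return FractalEstimate(
                df=0.0, intercept=float(np.log(counts_arr[0])),
                box_sizes=sizes_arr, counts=counts_arr, r_squared=1.0,
            )
    logx = np.log(1.0 / sizes_arr)
    logy = np.log(counts_arr)
    slope, intercept = np.polyfit(logx, logy, 1)
    pred = slope * logx + intercept
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FractalEstimate(
        df=float(slope), intercept=float(intercept),
        box_sizes=sizes_arr, counts=counts_arr, r_squared=r2,
    )
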