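"""Resampling inference: bootstrap group tests, percentile CIs, FDR.

The group-difference test builds its null by resampling each group from
itself and re-centering the bootstrap differences at zero (null="centered",
the default), or by resampling both groups from the pooled data at the
original sizes (null="pooled"). The p-value is the proportion of null
differences at least as large as the observed one — two-sided on
|difference| by default, with a one-sided reading available.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .types import BootstrapResult, InvalidInputError, InvalidParameterError

_STATS = {"median": np.median, "mean": np.mean}


def _resolve_stat(stat: str):
    if stat not in _STATS:
        raise InvalidParameterError(f"stat must be one of {sorted(_STATS)}")
    return _STATS[stat]


def bootstrap_group_difference(
    a: np.ndarray,
    b: np.ndarray,
    stat: str = "median",
    n_boot: int = 10_000,
    seed: int | None = None,
    sided: str = "two-sided",
    null: str = "centered",
) -> BootstrapResult:
    """Bootstrap test of a difference in medians (or means).

    null="centered" resamples each group from itself and centers the
    bootstrap differences at zero, so identical constant groups give p = 1
    and perfectly separated groups hit the 1/n_boot resolution floor.
    null="pooled" resamples both groups from the pooled data at the
    original sizes instead. The p-value is the proportion of null
    differences whose magnitude reaches the observed |stat(a) - stat(b)|
    (sided="greater" uses the signed difference). The CI is the percentile
    bootstrap 95% interval of the difference (groups resampled
    separately).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each group needs at least 2 samples")
    if sided not in ("two-sided", "greater"):
        raise InvalidParameterError("sided must be 'two-sided' or 'greater'")
    if null not in ("centered", "pooled"):
        raise InvalidParameterError("null must be 'centered' or 'pooled'")
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    fn = _resolve_stat(stat)
    rng = np.random.default_rng(seed)
    observed = float(fn(a) - fn(b))

    ja = rng.integers(0, len(a), size=(n_boot, len(a)))
    jb = rng.integers(0, len(b), size=(n_boot, len(b)))
    diffs = fn(a[ja], axis=1) - fn(b[jb], axis=1)

    if null == "pooled":
        pooled = np.concatenate([a, b])
        ia = rng.integers(0, len(pooled), size=(n_boot, len(a)))
        ib = rng.integers(0, len(pooled), size=(n_boot, len(b)))
        null_diffs = fn(pooled[ia], axis=1) - fn(pooled[ib], axis=1)
    else:
        null_diffs = diffs - observed
    if sided == "two-sided":
        exceed = np.abs(null_diffs) >= abs(observed)
    else:
        exceed = null_diffs >= observed
    p = max(float(exceed.mean()), 1.0 / n_boot)

    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapResult(
        observed_stat=observed, p_value=min(1.0, p),
        ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, seed=seed, sided=sided,
    )


def bootstrap_ci(
    samples: np.ndarray,
    stat: str = "median",
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a summary statistic."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise InvalidInputError("need at least 2 samples")
    if not (0 < level < 1):
        raise InvalidParameterError("level must be in (0, 1)")
    fn = _resolve_stat(stat)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    boot = fn(x[idx], axis=1)
    tail = 100 * (1 - level) / 2
    lo, hi = np.percentile(boot, [tail, 100 - tail])
    return float(lo), float(hi)


def benjamini_hochberg(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values); adjusted values are
    monotone non-decreasing in rank and never below the raw values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted
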