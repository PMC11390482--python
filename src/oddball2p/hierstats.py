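"""Resampling statistics for nested neural data.

Cells are nested in animals, so cell-level comparisons cannot treat cells
as independent. The hierarchical bootstrap builds a null distribution by
resampling animals with replacement, then cells with replacement within
each drawn animal, then shuffling the paired condition labels, and
compares the original-sample statistic against it. Also here: a flat
randomization test, BCa bootstrap confidence intervals, Cohen's d, and
Bonferroni adjustment.

All Monte-Carlo p-values carry the +1 small-sample correction and are
therefore never exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "HierBootResult",
    "EffectSize",
    "bonferroni",
    "bootstrap_ci",
    "cohens_d",
    "hierarchical_bootstrap_test",
    "randomization_test",
]


@dataclass
class HierBootResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_boot: int
    seed: int | None
    statistic_name: str


@dataclass
class EffectSize:
    cohens_d: float
    mean_a: float
    mean_b: float
    pooled_sd: float


def _mc_pvalue(observed: float, null: np.ndarray, alternative: str) -> float:
    n = null.size
    if alternative == "two-sided":
        k = int(np.sum(np.abs(null) >= abs(observed)))
    elif alternative == "greater":
        k = int(np.sum(null >= observed))
    elif alternative == "less":
        k = int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + k) / (n + 1)


def hierarchical_bootstrap_test(
    animal_ids,
    value_a,
    value_b,
    statistic=None,
    n_boot: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> HierBootResult:
    """Two-level bootstrap null test for paired cell-level data.

    Each iteration resamples animals with replacement, resamples cells
    with replacement within each drawn animal (to that animal's original
    cell count), independently swaps the (a, b) pair with probability 0.5
    per resampled cell, and records the statistic. The p-value compares
    the statistic of the original (unresampled) data against this null.

    ``statistic`` maps (a, b) arrays to a scalar; the default is the mean
    paired difference mean(a - b), for which the resampling loop is fully
    vectorized.
    """
    animal_ids = np.asarray(animal_ids)
    a = np.asarray(value_a, dtype=float)
    b = np.asarray(value_b, dtype=float)
    if not (animal_ids.shape == a.shape == b.shape):
        raise ValueError("animal_ids, value_a, value_b must have equal length")
    animals, inverse = np.unique(animal_ids, return_inverse=True)
    n_animals = animals.size
    if n_animals < 2:
        raise ValueError(
            "hierarchical bootstrap needs >= 2 animals; "
            "use randomization_test for single-animal data"
        )
    if a.size < 2:
        raise ValueError("need at least 2 cells")

    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(inverse == i) for i in range(n_animals)]
    counts = np.array([g.size for g in groups])

    if statistic is None:
        observed = float(np.mean(a - b))
        name = "mean paired difference"
        diffs = [a[g] - b[g] for g in groups]
        if np.all(counts == counts[0]):
            # equal per-animal cell counts: vectorize across iterations
            d = np.stack(diffs)  # (n_animals, n_cells)
            nc = counts[0]
            an = rng.integers(0, n_animals, size=(n_boot, n_animals))
            ci = rng.integers(0, nc, size=(n_boot, n_animals, nc))
            drawn = d[an[..., None], ci]  # (n_boot, n_animals, nc)
            signs = np.where(rng.random(drawn.shape) < 0.5, -1.0, 1.0)
            null = (drawn * signs).mean(axis=(1, 2))
        else:
            null = np.empty(n_boot)
            for it in range(n_boot):
                an = rng.integers(0, n_animals, size=n_animals)
                parts = []
                for ai in an:
                    g = diffs[ai]
                    parts.append(g[rng.integers(0, g.size, size=g.size)])
                dd = np.concatenate(parts)
                signs = np.where(rng.random(dd.size) < 0.5, -1.0, 1.0)
                null[it] = (dd * signs).mean()
    else:
        observed = float(statistic(a, b))
        name = getattr(statistic, "__name__", "statistic")
        null = np.empty(n_boot)
        for it in range(n_boot):
            an = rng.integers(0, n_animals, size=n_animals)
            ia = []
            for ai in an:
                g = groups[ai]
                ia.append(g[rng.integers(0, g.size, size=g.size)])
            idx = np.concatenate(ia)
            aa, bb = a[idx].copy(), b[idx].copy()
            swap = rng.random(idx.size) < 0.5
            aa[swap], bb[swap] = bb[swap], aa[swap].copy()
            null[it] = statistic(aa, bb)

    p = _mc_pvalue(observed, null, alternative)
    return HierBootResult(observed, null, p, n_boot, seed, name)


def randomization_test(
    sample_a,
    sample_b,
    statistic=None,
    n_perm: int = 10000,
    seed: int | None = None,
    paired: bool = False,
    alternative: str = "two-sided",
) -> float:
    """Permutation test on condition labels; paired data uses pair swaps.

    The default statistic is the difference of means (paired: mean of
    differences). Returns the Monte-Carlo p-value with +1 correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    rng = np.random.default_rng(seed)

    if paired:
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        if statistic is None:
            observed = float(np.mean(a - b))
            d = a - b
            signs = np.where(rng.random((n_perm, d.size)) < 0.5, -1.0, 1.0)
            null = (signs * d).mean(axis=1)
        else:
            observed = float(statistic(a, b))
            null = np.empty(n_perm)
            for it in range(n_perm):
                swap = rng.random(a.size) < 0.5
                aa = np.where(swap, b, a)
                bb = np.where(swap, a, b)
                null[it] = statistic(aa, bb)
    else:
        pooled = np.concatenate([a, b])
        na = a.size
        if statistic is None:
            observed = float(a.mean() - b.mean())
            null = np.empty(n_perm)
            for it in range(n_perm):
                perm = rng.permutation(pooled)
                null[it] = perm[:na].mean() - perm[na:].mean()
        else:
            observed = float(statistic(a, b))
            null = np.empty(n_perm)
            for it in range(n_perm):
                perm = rng.permutation(pooled)
                null[it] = statistic(perm[:na], perm[na:])

    return _mc_pvalue(observed, null, alternative)


def bootstrap_ci(
    values,
    level: float = 0.95,
    n_boot: int = 10000,
    seed: int | None = None,
    statistic=np.mean,
    method: str = "BCa",
):
    """Bootstrap confidence interval for a statistic of one sample.

    Default is the bias-corrected and accelerated (BCa) interval for the
    mean; ``method="percentile"`` selects the simple percentile variant.
    A constant sample yields a zero-width interval at the constant.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(x) == 0:
        c = float(x[0])
        return c, c
    res = stats.bootstrap(
        (x,),
        statistic,
        n_resamples=n_boot,
        confidence_level=level,
        method=method,
        vectorized=False,
        rng=np.random.default_rng(seed),
    )
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def cohens_d(sample_a, sample_b) -> EffectSize:
    """Mean difference divided by the pooled standard deviation."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    na, nb = a.size, b.size
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    diff = a.mean() - b.mean()
    if pooled == 0:
        d = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        d = diff / pooled
    return EffectSize(cohens_d=float(d), mean_a=float(a.mean()), mean_b=float(b.mean()), pooled_sd=pooled)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """min(1, m * p) elementwise; m defaults to the number of p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)
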