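"""Phase-level diversity statistics.

Alpha diversity (Shannon entropy in bits, Kruskal-Wallis across lake
phases) and beta diversity (distance-matrix PERMANOVA between every
pair of phases with Benjamini-Hochberg correction). Bray-Curtis is the
default dissimilarity, but any precomputed symmetric distance matrix
(e.g. weighted UniFrac from an external tree pipeline) can be supplied.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhaseComparison",
    "shannon",
    "kruskal_wallis",
    "bray_curtis",
    "permanova_pairwise",
    "bh_adjust",
]


@dataclass(frozen=True)
class PhaseComparison:
    """Pairwise PERMANOVA result for one phase pair."""

    phase_a: str
    phase_b: str
    pseudo_f: float
    r2: float
    p_raw: float
    p_adj: float
    n_permutations: int


def shannon(counts: Sequence[float]) -> float:
    """Shannon entropy in bits: H = -sum p_i log2 p_i over nonzero p."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("counts must contain at least one positive value")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log2(p)).sum())


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based H with tie correction; p from chi-square(k-1).

    A degenerate case where every observation is identical (H undefined
    in scipy) is reported as H=0, p=1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(h), float(p)


def bray_curtis(matrix: np.ndarray, ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (rows).

    d(x, y) = sum|x-y| / sum(x+y); a pair of all-zero samples has an
    undefined ratio and is reported as distance 0 with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if np.any(m < 0):
        raise ValueError("abundances must be non-negative")
    n = m.shape[0]
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        denom = (m[i] + m[j]).sum()
        if denom == 0:
            warnings.warn(f"samples {i} and {j} are both all-zero; distance set to 0")
            d = 0.0
        else:
            d = np.abs(m[i] - m[j]).sum() / denom
        dist[i, j] = dist[j, i] = d
    if ids is None:
        ids = [str(i) for i in range(n)]
    return DistanceMatrix(dist, ids=list(ids))


def _permanova_stat(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R2 from squared distances and group labels.

    SS_total = sum_{i<j} d2_ij / n; SS_within = sum over groups of
    within-group pair sums / group size (Gower-centering algebra in its
    pairwise form); F = (SS_B/(k-1)) / (SS_W/(n-k)).
    """
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    k = len(groups)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_within <= 0:
        f = math.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, r2


def permanova_oneway(
    dist: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> tuple[float, float, float]:
    """One-way PERMANOVA: (pseudo-F, R2, permutation p).

    Monte-Carlo p includes the observed statistic:
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1). With ``exhaustive``
    the p-value enumerates every distinct label assignment instead.
    """
    labels = np.asarray(labels)
    d2 = np.asarray(dist.data) ** 2
    f_obs, r2 = _permanova_stat(d2, labels)
    if exhaustive:
        perms = set(itertools.permutations(labels))
        hits = sum(1 for p in perms if _permanova_stat(d2, np.asarray(p))[0] >= f_obs - 1e-12)
        return f_obs, r2, hits / len(perms)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stat(d2, rng.permutation(labels))
        if f_perm >= f_obs - 1e-12:
            hits += 1
    return f_obs, r2, (1 + hits) / (n_perm + 1)


def permanova_pairwise(
    dist: DistanceMatrix,
    phases: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> list[PhaseComparison]:
    """Pairwise PERMANOVA between every pair of phases, BH-adjusted.

    ``phases`` gives the phase label of each sample in ``dist`` order.
    Pairs involving a phase with fewer than 2 samples are skipped with
    a warning; BH adjustment runs across the pairs of this one call.
    """
    phases = np.asarray([str(p) for p in phases])
    if len(phases) != dist.shape[0]:
        raise ValueError("one phase label per sample required")
    ids = np.asarray(dist.ids)
    levels = sorted(set(phases))
    if len(levels) < 2:
        raise ValueError("need at least 2 phases")
    rng = np.random.default_rng(seed)
    results: list[tuple[str, str, float, float, float]] = []
    for a, b in itertools.combinations(levels, 2):
        mask = (phases == a) | (phases == b)
        if (phases == a).sum() < 2 or (phases == b).sum() < 2:
            warnings.warn(f"phase pair ({a}, {b}) skipped: a phase has <2 samples")
            continue
        sub = dist.filter(ids[mask])
        f, r2, p = permanova_oneway(
            sub, phases[mask], n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        results.append((a, b, f, r2, p))
    if not results:
        return []
    p_adj = bh_adjust([r[4] for r in results])
    return [
        PhaseComparison(a, b, f, r2, p, float(q), n_perm)
        for (a, b, f, r2, p), q in zip(results, p_adj)
    ]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
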