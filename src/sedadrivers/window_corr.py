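"""Sliding-window Pearson correlation with permutation FDR and recall.

For every family x driver pair the engine enumerates all contiguous
windows of at least ``min_window`` time points and discards windows
with more than 50% zeros on either side or a constant series. Two
pitfalls shape the inference design:

* selecting the best of hundreds of overlapping windows and then
  permutation-testing that window alone is severely optimistic
  (winner's curse) — under a global null nearly every pair passes;
* the raw max-|r| statistic has no power, because 5-point windows
  saturate |r| ~ 0.95 under null and alternative alike.

Windows are therefore compared on an evidence scale: for each length
``w`` the admissible max |r| is converted to a per-window p-value (a
two-sided t tail floored at the exhaustive-permutation minimum 2/w!
for short windows) and weighted by a per-length prior — Bonferroni
over the number of windows of that length times a geometric factor
2^(w-T) favoring sustained windows (the prior masses sum to at most
2, so this is a proper weighted multiple-test scheme). The scan
statistic is the best weighted evidence across lengths, so a
sustained long-window correlation outranks short-window chance
alignments. The family-level p-value permutes the driver
series as a whole and recomputes this statistic on every permutation
— exact under the exchangeable null by construction. These scan-level
p-values are Benjamini-Hochberg adjusted across all family x driver
tests within a driver class. A family is called only if additionally
more than ``recall_threshold`` of its member ASVs individually pass
the same |r| and adjusted-p criteria in the family's (now fixed) best
window — a within-family consistency filter against spurious
aggregate correlations. The fixed-window permutation test
(``perm_pvalue``, exhaustive when the window is short enough) remains
the primitive for those ASV-level and re-tested-window checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .community_ops import FamilyTable, zero_fraction_ok
from .community_shift import bh_adjust
from .io_formats import AlignedMatrices

__all__ = [
    "SwcConfig",
    "WindowStat",
    "FamilyDriverLink",
    "LinkCallResult",
    "enumerate_windows",
    "pearson",
    "perm_pvalue",
    "scan_pvalue",
    "swc_scan",
    "call_family_links",
    "recall_rate",
]


@dataclass(frozen=True)
class SwcConfig:
    """Thresholds of the triple filter (|r|, adjusted p, recall)."""

    min_window: int = 5
    r_threshold: float = 0.5
    n_permutations: int = 10_000
    alpha: float = 0.05
    recall_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_window < 3:
            raise ValueError("min_window must be >= 3")
        if self.n_permutations < 99:
            raise ValueError("need at least 99 permutations")
        for name in ("r_threshold", "alpha", "recall_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class WindowStat:
    """Best-window correlation between one unit and one driver."""

    driver: str
    unit: str
    start: int
    length: int
    r: float
    p_raw: float
    p_adj: float = math.nan  # filled after the batch BH step


@dataclass(frozen=True)
class FamilyDriverLink:
    """A called (or rejected) family-driver association."""

    family: str
    driver: str
    driver_class: str
    window: WindowStat
    sign: int  # +1 / -1 from the best-window r
    recall: float
    pass_r: bool
    pass_padj: bool
    pass_recall: bool

    @property
    def passed(self) -> bool:
        return self.pass_r and self.pass_padj and self.pass_recall


@dataclass(frozen=True)
class LinkCallResult:
    """Links plus the reported 90% recall quantile per driver class."""

    links: tuple[FamilyDriverLink, ...]
    recall_q90: dict[str, float]
    not_testable: tuple[tuple[str, str], ...]  # (family, driver) pairs


def enumerate_windows(T: int, min_len: int) -> list[tuple[int, int]]:
    """All (start, length) contiguous windows with length >= min_len."""
    if min_len < 1:
        raise ValueError("min_len must be positive")
    if T < min_len:
        raise ValueError(f"series length {T} shorter than minimum window {min_len}")
    return [(s, w) for w in range(min_len, T + 1) for s in range(T - w + 1)]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("constant input: correlation undefined")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def perm_pvalue(x: Sequence[float], y: Sequence[float], B: int, seed: int | None = None) -> float:
    """Two-sided permutation p for the Pearson correlation of (x, y).

    Permutes ``y``. When n! <= B the full permutation distribution is
    enumerated and p is the exact tail fraction #{|r_perm| >= |r_obs|}/n!
    (the identity permutation makes it strictly positive). Otherwise B
    Monte-Carlo permutations give p = (1 + #hits) / (B + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = abs(pearson(x, y))
    n = x.size
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    tol = 1e-12
    if math.factorial(n) <= B:
        perms = np.array(list(itertools.permutations(yc)))
        r_perm = perms @ xc / (sx * sy)
        return float((np.abs(r_perm) >= r_obs - tol).mean())
    rng = np.random.default_rng(seed)
    draws = rng.permuted(np.tile(yc, (B, 1)), axis=1)
    r_perm = draws @ xc / (sx * sy)
    hits = int((np.abs(r_perm) >= r_obs - tol).sum())
    return (1 + hits) / (B + 1)


def _window_correlations(x: np.ndarray, y: np.ndarray, min_len: int) -> tuple[np.ndarray, ...]:
    """Correlation of every admissible window via prefix sums.

    Returns (starts, lengths, r, admissible) over all enumerated
    windows; windows failing the zero-fraction filter or with a
    constant series get admissible=False.
    """
    T = x.size
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    zx = np.concatenate([[0], np.cumsum(x == 0)])
    zy = np.concatenate([[0], np.cumsum(y == 0)])
    starts, lengths, rs, ok = [], [], [], []
    for w in range(min_len, T + 1):
        s = np.arange(T - w + 1)
        e = s + w
        sx = cx[e] - cx[s]
        sy_ = cy[e] - cy[s]
        sxx = cxx[e] - cxx[s]
        syy = cyy[e] - cyy[s]
        sxy = cxy[e] - cxy[s]
        varx = sxx - sx * sx / w
        vary = syy - sy_ * sy_ / w
        cov = sxy - sx * sy_ / w
        nonconst = (varx > 1e-12 * np.maximum(sxx, 1.0)) & (vary > 1e-12 * np.maximum(syy, 1.0))
        zero_ok = ((zx[e] - zx[s]) <= w / 2) & ((zy[e] - zy[s]) <= w / 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(varx * vary)
        starts.append(s)
        lengths.append(np.full_like(s, w))
        rs.append(np.clip(r, -1.0, 1.0))
        ok.append(nonconst & zero_ok)
    return (
        np.concatenate(starts),
        np.concatenate(lengths),
        np.concatenate(rs),
        np.concatenate(ok),
    )


def _window_log_p(absr: np.ndarray, w: np.ndarray) -> np.ndarray:
    """log of the per-window two-sided p for |r| at length w.

    Student-t tail, floored at the exhaustive-permutation minimum
    2/w! for short windows (a permutation of w points can never be
    more extreme than every ordering).
    """
    absr = np.minimum(np.asarray(absr, dtype=float), 1.0 - 1e-12)
    w = np.asarray(w)
    t = absr * np.sqrt((w - 2) / (1.0 - absr**2))
    p = 2.0 * scipy.stats.t.sf(t, w - 2)
    floor = np.array([2.0 / math.factorial(int(k)) if k <= 10 else 0.0 for k in w])
    return np.log(np.maximum(np.maximum(p, floor), 1e-300))


def _scan_evidence(x: np.ndarray, y: np.ndarray, min_len: int) -> tuple[float, tuple[int, int, float] | None]:
    """(scan statistic, best window) for one pair.

    The statistic is max over lengths w of
    ``-log p(max admissible |r| at w) - log n_windows(w) + (w - T) log 2``
    (per-length Bonferroni weight with a geometric prior favoring
    sustained windows); the best window is its argmax, ties broken
    toward the longer window, then the earlier start.
    """
    starts, lengths, rs, ok = _window_correlations(x, y, min_len)
    if not ok.any():
        return -np.inf, None
    starts, lengths, rs = starts[ok], lengths[ok], rs[ok]
    T = x.size
    candidates = []  # (stat, w, start, r) — one per length
    for w in np.unique(lengths):
        m = lengths == w
        absr = np.abs(rs[m])
        j = int(np.argmax(absr))  # first occurrence = earliest start
        stat = (
            float(-_window_log_p(np.array([absr[j]]), np.array([int(w)]))[0])
            - math.log(T - w + 1)
            + (int(w) - T) * math.log(2.0)
        )
        candidates.append((stat, int(w), int(starts[m][j]), float(rs[m][j])))
    top = max(c[0] for c in candidates)
    near = [c for c in candidates if c[0] >= top - 1e-12]
    near.sort(key=lambda c: (-c[1], c[2]))  # longer window, then earlier start
    _stat, w, s, r = near[0]
    return top, (s, w, r)


def best_window(
    x: np.ndarray, y: np.ndarray, min_len: int, criterion: str = "evidence"
) -> tuple[int, int, float] | None:
    """(start, length, r) of the best admissible window, or None.

    ``criterion="evidence"`` (default) maximizes the length-adjusted
    evidence score used by the scan test; ``criterion="max_r"``
    maximizes plain |r|. Ties (to 1e-12) prefer the longer window,
    then the earlier start.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if criterion == "evidence":
        return _scan_evidence(x, y, min_len)[1]
    if criterion != "max_r":
        raise ValueError(f"unknown criterion {criterion!r}")
    starts, lengths, rs, ok = _window_correlations(x, y, min_len)
    if not ok.any():
        return None
    starts, lengths, rs = starts[ok], lengths[ok], rs[ok]
    absr = np.abs(rs)
    tol = 1e-12
    idx = np.flatnonzero(absr >= absr.max() - tol)
    # among ties: longest window, then earliest start
    order = np.lexsort((starts[idx], -lengths[idx]))
    j = idx[order[0]]
    return int(starts[j]), int(lengths[j]), float(rs[j])


def scan_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    min_len: int,
    B: int,
    seed: int | None = None,
) -> float:
    """Permutation p for the window-scan evidence statistic.

    Permutes the driver ``y`` as a whole series and recomputes the
    full scan statistic (length-adjusted best evidence over admissible
    windows) on each permutation; permutations with no admissible
    window score -inf. p = (1 + #{stat_perm >= stat_obs}) / (B + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    T = x.size
    obs, found = _scan_evidence(x, y, min_len)
    if found is None:
        raise ValueError("no admissible window in the observed data")
    rng = np.random.default_rng(seed)
    Y = rng.permuted(np.tile(y, (B, 1)), axis=1)  # B x T

    pad = np.zeros((B, 1))
    cy = np.concatenate([pad, np.cumsum(Y, axis=1)], axis=1)
    cyy = np.concatenate([pad, np.cumsum(Y * Y, axis=1)], axis=1)
    cxy_all = np.concatenate([pad, np.cumsum(Y * x[None, :], axis=1)], axis=1)
    zy = np.concatenate([pad, np.cumsum(Y == 0, axis=1)], axis=1)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    zx = np.concatenate([[0], np.cumsum(x == 0)])

    best = np.full(B, -np.inf)
    for w in range(min_len, T + 1):
        s = np.arange(T - w + 1)
        e = s + w
        sx = cx[e] - cx[s]
        sxx = cxx[e] - cxx[s]
        varx = sxx - sx * sx / w
        x_ok = (varx > 1e-12 * np.maximum(sxx, 1.0)) & ((zx[e] - zx[s]) <= w / 2)
        if not x_ok.any():
            continue
        sy = cy[:, e] - cy[:, s]
        syy = cyy[:, e] - cyy[:, s]
        sxy = cxy_all[:, e] - cxy_all[:, s]
        vary = syy - sy * sy / w
        cov = sxy - sx[None, :] * sy / w
        y_ok = (vary > 1e-12 * np.maximum(syy, 1.0)) & ((zy[:, e] - zy[:, s]) <= w / 2)
        ok = x_ok[None, :] & y_ok
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(cov) / np.sqrt(varx[None, :] * vary)
        r = np.where(ok, np.minimum(r, 1.0), -np.inf)
        rmax = r.max(axis=1)  # per-permutation max |r| at this length
        has = rmax > -np.inf
        if has.any():
            stat_w = np.full(B, -np.inf)
            stat_w[has] = (
                -_window_log_p(rmax[has], np.full(has.sum(), w))
                - math.log(T - w + 1)
                + (w - T) * math.log(2.0)
            )
            best = np.maximum(best, stat_w)
    hits = int((best >= obs - 1e-12).sum())
    return (1 + hits) / (B + 1)


def swc_scan(
    unit_series: Sequence[float],
    driver_series: Sequence[float],
    config: SwcConfig,
    driver: str = "driver",
    unit: str = "unit",
    seed: int | None = None,
) -> WindowStat | None:
    """Best-window statistic for one unit x driver pair, or None.

    The reported p-value is the scan-level permutation p (the max-|r|
    statistic over all admissible windows, see :func:`scan_pvalue`),
    which accounts for the window selection. Returns None when no
    window passes the zero-fraction and non-constancy filters (the
    pair is not testable).
    """
    x = np.asarray(unit_series, dtype=float)
    y = np.asarray(driver_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be aligned")
    if x.size < config.min_window:
        raise ValueError("series shorter than the minimum window")
    found = best_window(x, y, config.min_window)
    if found is None:
        return None
    s, w, r = found
    p = scan_pvalue(
        x, y, config.min_window, config.n_permutations,
        seed=config.seed if seed is None else seed,
    )
    return WindowStat(driver=driver, unit=unit, start=s, length=w, r=r, p_raw=p)


def recall_rate(family: str, asv_calls: Sequence[bool]) -> float:
    """Fraction of a family's ASVs individually passing the criteria."""
    if len(asv_calls) == 0:
        raise ValueError(f"family {family!r} has no ASVs")
    return float(np.mean([bool(c) for c in asv_calls]))


def _asv_recall(
    asv_rows: np.ndarray,
    y_win: np.ndarray,
    s: int,
    w: int,
    config: SwcConfig,
    rng: np.random.Generator,
) -> float:
    """Recall over member ASVs in the family's best window."""
    rs, ps = [], []
    for row in asv_rows:
        x_win = row[s : s + w]
        if x_win.std() == 0 or y_win.std() == 0 or not zero_fraction_ok(x_win, y_win):
            rs.append(0.0)
            ps.append(1.0)
            continue
        rs.append(pearson(x_win, y_win))
        ps.append(perm_pvalue(x_win, y_win, config.n_permutations, seed=int(rng.integers(2**31))))
    padj = bh_adjust(ps)
    calls = [abs(r) > config.r_threshold and q < config.alpha for r, q in zip(rs, padj)]
    return recall_rate("family", calls)


def call_family_links(
    family_table: FamilyTable,
    asv_table: pd.DataFrame,
    aligned: AlignedMatrices,
    config: SwcConfig,
) -> LinkCallResult:
    """Full link-calling pass over every family x driver pair.

    ``family_table`` holds family relative abundances over
    ``aligned.layer_ids``; ``asv_table`` the member-ASV relative
    abundances (ASV id x layer). Steps: best-window scan per pair, BH
    adjustment of the selected-window p-values within each driver
    class, then the recall-rate filter for candidates surviving the
    |r| and adjusted-p gates.
    """
    if list(family_table.layer_ids) != list(aligned.layer_ids):
        family_table = family_table.subset_layers(list(aligned.layer_ids))
    asv_table = asv_table.loc[:, list(aligned.layer_ids)]
    rng = np.random.default_rng(config.seed)
    layer_index = {l: i for i, l in enumerate(aligned.layer_ids)}

    stats: list[tuple[str, str, str, WindowStat, np.ndarray, np.ndarray, int]] = []
    not_testable: list[tuple[str, str]] = []
    for driver in aligned.driver_names():
        clazz = aligned.classes[driver]
        layers, y = aligned.driver_axis(driver)
        if len(layers) < config.min_window:
            not_testable.extend((f, driver) for f in family_table.labels)
            continue
        cols = [layer_index[l] for l in layers]
        fam_matrix = family_table.values[:, cols]
        for fi, family in enumerate(family_table.labels):
            x = fam_matrix[fi]
            found = best_window(x, y, config.min_window)
            if found is None:
                not_testable.append((family, driver))
                continue
            s, w, r = found
            p = scan_pvalue(x, y, config.min_window, config.n_permutations,
                            seed=int(rng.integers(2**31)))
            ws = WindowStat(driver=driver, unit=family, start=s, length=w, r=r, p_raw=p)
            asv_ids = [a for a in family_table.registry[family] if a in asv_table.index]
            asv_rows = asv_table.loc[asv_ids].to_numpy()[:, cols] if asv_ids else np.empty((0, len(cols)))
            stats.append((family, driver, clazz, ws, asv_rows, y, s))

    # BH within each driver class over all family x driver best-window tests
    links: list[FamilyDriverLink] = []
    for clazz in sorted({t[2] for t in stats}):
        batch = [t for t in stats if t[2] == clazz]
        padj = bh_adjust([t[3].p_raw for t in batch])
        for (family, driver, _c, ws, asv_rows, y, s), q in zip(batch, padj):
            ws = replace(ws, p_adj=float(q))
            pass_r = abs(ws.r) > config.r_threshold
            pass_padj = ws.p_adj < config.alpha
            if pass_r and pass_padj and len(asv_rows):
                rec = _asv_recall(asv_rows, y[s : s + ws.length], s, ws.length, config, rng)
            else:
                rec = math.nan
            pass_recall = (not math.isnan(rec)) and rec > config.recall_threshold
            links.append(
                FamilyDriverLink(
                    family=family,
                    driver=driver,
                    driver_class=clazz,
                    window=ws,
                    sign=1 if ws.r >= 0 else -1,
                    recall=rec,
                    pass_r=pass_r,
                    pass_padj=pass_padj,
                    pass_recall=pass_recall,
                )
            )

    recall_q90 = {}
    for clazz in sorted({l.driver_class for l in links}):
        vals = [l.recall for l in links if l.driver_class == clazz and not math.isnan(l.recall)]
        recall_q90[clazz] = float(np.quantile(vals, 0.9)) if vals else math.nan
    return LinkCallResult(links=tuple(links), recall_q90=recall_q90, not_testable=tuple(not_testable))
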