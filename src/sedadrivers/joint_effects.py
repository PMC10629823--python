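"""Combined-significance and joint biocide x climate effect detection.

A family is a combined-significance candidate when a biocide and a
climate driver are each significantly correlated with it over one
shared time window — the best evidence window of the family against
the equal-weight combined series on the layers valid for both drivers
— with mean absolute correlation above the threshold. The candidate
shows a *joint effect* when the combined series correlates with the
family strictly better than either driver alone on that window, with
a BH-adjusted scan-level permutation p below alpha. The equal-weight
combination (rather than a least-squares fit, whose multiple
correlation can never be smaller than an individual correlation) keeps
the strict-improvement criterion falsifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community_ops import FamilyTable, zero_fraction_ok, zscore_series
from .community_shift import bh_adjust
from .io_formats import AlignedMatrices
from .window_corr import (
    FamilyDriverLink,
    SwcConfig,
    best_window,
    pearson,
    perm_pvalue,
    scan_pvalue,
)

__all__ = [
    "JointCandidate",
    "JointEffectRecord",
    "combined_significance",
    "joint_test",
    "detect_joint_effects",
    "rank_chemicals",
    "joint_frequency_matrix",
]


@dataclass(frozen=True)
class JointCandidate:
    """A (family, biocide, climate) triple sharing a significant window."""

    family: str
    biocide: str
    climate: str
    layers: tuple[str, ...]  # ordered shared window layers
    r_bio: float
    r_cli: float
    p_bio: float
    p_cli: float

    @property
    def mean_abs_r(self) -> float:
        return (abs(self.r_bio) + abs(self.r_cli)) / 2.0


@dataclass(frozen=True)
class JointEffectRecord:
    """Joint-effect test result for one family and shared window."""

    family: str
    biocide: str
    climate: str
    n_points: int
    year_start: float
    year_end: float
    r_bio: float
    r_cli: float
    mean_r: float
    r_joint: float
    p_adj_joint: float
    combined_significant: bool
    is_joint: bool


def _window_layers(link: FamilyDriverLink, aligned: AlignedMatrices) -> list[str]:
    layers, _vals = aligned.driver_axis(link.driver)
    s, w = link.window.start, link.window.length
    return layers[s : s + w]


def combined_significance(
    links_bio: Sequence[FamilyDriverLink],
    links_cli: Sequence[FamilyDriverLink],
    family_table: FamilyTable,
    aligned: AlignedMatrices,
    config: SwcConfig,
) -> list[JointCandidate]:
    """Candidate triples where both drivers are significant over one
    shared window.

    Every tested family x (biocide, climate) pair in the supplied link
    tables is a potential candidate (the caller typically restricts
    the tables to the top-ranked drivers per class). The candidate
    window is NOT assembled from the two individual best windows —
    that would re-import the winner's curse of the individual scans —
    but is the best evidence window of the family against the
    equal-weight combined series J = (z(bio) + z(cli)) / 2 on the
    fixed axis of layers valid for both drivers. Both drivers are then
    confirmed on that one window: mean(|r_bio|, |r_cli|) above the r
    threshold and both fixed-window permutation p below alpha. The
    calibrated inferential gate for the cascade is the scan-level
    joint p in :func:`detect_joint_effects`.
    """
    if list(family_table.layer_ids) != list(aligned.layer_ids):
        family_table = family_table.subset_layers(list(aligned.layer_ids))
    rng = np.random.default_rng(config.seed + 1)

    cli_by_family: dict[str, list[FamilyDriverLink]] = {}
    for lc in links_cli:
        cli_by_family.setdefault(lc.family, []).append(lc)
    out: list[JointCandidate] = []
    for lb in links_bio:
        for lc in cli_by_family.get(lb.family, []):
            shared = _shared_axis(aligned, lb.driver, lc.driver)
            if len(shared) < config.min_window:
                continue
            x, yb, yc = _series_on(family_table, aligned, lb.family, lb.driver, lc.driver, shared)
            if x.std() == 0 or yb.std() == 0 or yc.std() == 0:
                continue
            joint = (zscore_series(yb) + zscore_series(yc)) / 2.0
            found = best_window(x, joint, config.min_window)
            if found is None:
                continue
            s, w, _rj = found
            xw, ybw, ycw = x[s : s + w], yb[s : s + w], yc[s : s + w]
            if ybw.std() == 0 or ycw.std() == 0 or xw.std() == 0:
                continue
            if not (zero_fraction_ok(xw, ybw) and zero_fraction_ok(xw, ycw)):
                continue
            r_b = pearson(xw, ybw)
            r_c = pearson(xw, ycw)
            if (abs(r_b) + abs(r_c)) / 2.0 <= config.r_threshold:
                continue
            p_b = perm_pvalue(xw, ybw, config.n_permutations, seed=int(rng.integers(2**31)))
            p_c = perm_pvalue(xw, ycw, config.n_permutations, seed=int(rng.integers(2**31)))
            if p_b < config.alpha and p_c < config.alpha:
                out.append(
                    JointCandidate(
                        family=lb.family,
                        biocide=lb.driver,
                        climate=lc.driver,
                        layers=tuple(shared[s : s + w]),
                        r_bio=r_b,
                        r_cli=r_c,
                        p_bio=p_b,
                        p_cli=p_c,
                    )
                )
    return out


def _shared_axis(aligned: AlignedMatrices, bio: str, cli: str) -> list[str]:
    """Ordered layers valid for both drivers (the fixed joint axis)."""
    valid_b = set(aligned.driver_axis(bio)[0])
    valid_c = set(aligned.driver_axis(cli)[0])
    return [l for l in aligned.layer_ids if l in valid_b and l in valid_c]


def _series_on(family_table, aligned, family, bio, cli, layers):
    idx = [list(aligned.layer_ids).index(l) for l in layers]
    x = family_table.row(family)[idx]
    yb = aligned.abiotic.loc[bio].to_numpy()[idx]
    yc = aligned.abiotic.loc[cli].to_numpy()[idx]
    return x, yb, yc


def joint_test(
    family_series: Sequence[float],
    bio_series: Sequence[float],
    cli_series: Sequence[float],
    config: SwcConfig,
    seed: int | None = None,
) -> tuple[float, float]:
    """(r_joint, p_raw) for the equal-weight combined driver.

    The combined series is J = (z(bio) + z(cli)) / 2 over the window;
    the permutation null shuffles the paired (bio, cli) rows jointly,
    which is equivalent to permuting J against the family series.
    """
    x = np.asarray(family_series, dtype=float)
    if x.size < config.min_window:
        raise ValueError("window shorter than the minimum window")
    joint = (zscore_series(bio_series) + zscore_series(cli_series)) / 2.0
    if joint.std() == 0:
        raise ValueError("combined driver is constant on this window")
    r_joint = pearson(x, joint)
    p = perm_pvalue(x, joint, config.n_permutations, seed=config.seed if seed is None else seed)
    return r_joint, p


def detect_joint_effects(
    candidates: Sequence[JointCandidate],
    family_table: FamilyTable,
    aligned: AlignedMatrices,
    config: SwcConfig,
) -> list[JointEffectRecord]:
    """Joint-effect records for every combined-significance candidate.

    The inferential gate is the scan-level permutation p of the family
    against the combined series J on the fixed valid-for-both axis
    (permuting J as a whole is equivalent to shuffling the paired
    (bio, cli) rows jointly), BH-adjusted across this batch of joint
    tests. is_joint additionally requires a strictly larger |r_joint|
    than either individual |r| on the candidate's window.
    """
    if list(family_table.layer_ids) != list(aligned.layer_ids):
        family_table = family_table.subset_layers(list(aligned.layer_ids))
    year_of = dict(zip(aligned.layer_ids, aligned.year_mid))
    rng = np.random.default_rng(config.seed + 2)
    rows: list[tuple[JointCandidate, float, float]] = []
    for cand in candidates:
        shared = _shared_axis(aligned, cand.biocide, cand.climate)
        x, yb, yc = _series_on(
            family_table, aligned, cand.family, cand.biocide, cand.climate, shared
        )
        joint = (zscore_series(yb) + zscore_series(yc)) / 2.0
        p = scan_pvalue(
            x, joint, config.min_window, config.n_permutations,
            seed=int(rng.integers(2**31)),
        )
        win = [shared.index(l) for l in cand.layers]
        s, w = win[0], len(win)
        r_joint = pearson(x[s : s + w], joint[s : s + w])
        rows.append((cand, r_joint, p))
    padj = bh_adjust([p for _c, _r, p in rows]) if rows else []
    out = []
    for (cand, r_joint, _p), q in zip(rows, padj):
        is_joint = bool(
            abs(r_joint) > max(abs(cand.r_bio), abs(cand.r_cli)) and q < config.alpha
        )
        years = [year_of[l] for l in cand.layers]
        out.append(
            JointEffectRecord(
                family=cand.family,
                biocide=cand.biocide,
                climate=cand.climate,
                n_points=len(cand.layers),
                year_start=float(min(years)),
                year_end=float(max(years)),
                r_bio=cand.r_bio,
                r_cli=cand.r_cli,
                mean_r=cand.mean_abs_r,
                r_joint=r_joint,
                p_adj_joint=float(q),
                combined_significant=True,
                is_joint=is_joint,
            )
        )
    return out


def rank_chemicals(
    links: Sequence[FamilyDriverLink],
    null_fraction: Mapping[str, float],
    chemical_types: Mapping[str, str],
    config: SwcConfig,
) -> dict[str, list[tuple[str, float]]]:
    """Rank individual chemicals within each biocide type.

    A chemical is discarded when its sales series has more than 50%
    absent values over the analysis range, or when its best |r| over
    the passing family links stays below the r threshold. Survivors are
    ranked by best |r| descending, ties alphabetical.
    """
    best: dict[str, float] = {}
    for link in links:
        if not link.passed:
            continue
        r = abs(link.window.r)
        best[link.driver] = max(best.get(link.driver, 0.0), r)
    out: dict[str, list[tuple[str, float]]] = {}
    for chem, r in best.items():
        if null_fraction.get(chem, 0.0) > 0.5:
            continue
        if r < config.r_threshold:
            continue
        out.setdefault(chemical_types[chem], []).append((chem, r))
    for typ in out:
        out[typ].sort(key=lambda t: (-t[1], t[0]))
    return out


def joint_frequency_matrix(
    records: Sequence[JointEffectRecord],
    biocide_types: Mapping[str, str | None],
    family_domains: Mapping[str, str] | None = None,
    domain: str | None = None,
) -> pd.DataFrame:
    """Count families with a joint effect per (biocide type, climate variable).

    With ``family_domains`` and ``domain`` given, only families of that
    domain grouping (eukaryote / prokaryote) are counted. Counting is
    over distinct families per cell.
    """
    selected = [r for r in records if r.is_joint]
    if domain is not None:
        if family_domains is None:
            raise ValueError("domain filtering requires a family_domains map")
        selected = [r for r in selected if family_domains.get(r.family) == domain]
    types = sorted({t for t in biocide_types.values() if t})
    climates = sorted({r.climate for r in records}) or []
    counts = pd.DataFrame(0, index=types, columns=climates, dtype=int)
    cells: dict[tuple[str, str], set[str]] = {}
    for r in selected:
        typ = biocide_types.get(r.biocide)
        if typ is None:
            continue
        cells.setdefault((typ, r.climate), set()).add(r.family)
    for (typ, cli), fams in cells.items():
        counts.loc[typ, cli] = len(fams)
    return counts
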