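"""Fisher-exact pathway enrichment and link bookkeeping summaries.

The enrichment stage consumes user-supplied differential term lists
(differential-abundance calling itself is upstream of this package)
and tests each pathway's 2x2 membership table with a two-sided Fisher
exact test. The summary stage reproduces the per-driver family counts,
class percentages and sign splits used to report link tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import scipy.stats

from .window_corr import FamilyDriverLink

__all__ = [
    "EnrichmentResult",
    "DriverSummaryRow",
    "DriverSummary",
    "fisher_enrichment",
    "round_half_up",
    "summarize_links",
    "run_pipeline",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher exact test of one pathway's 2x2 membership table.

    Cells: a = differential terms in the pathway, b = differential not
    in it, c = non-differential in it, d = non-differential not in it.
    odds_ratio = (a*d)/(b*c), infinity when a cross cell is zero.
    """

    pathway: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float


def fisher_enrichment(
    diff_terms: Iterable[str],
    background: Iterable[str],
    pathway_membership: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Two-sided Fisher exact enrichment of each pathway, sorted by p."""
    diff = set(diff_terms)
    bg = set(background)
    if not diff <= bg:
        raise ValueError(f"differential terms outside background: {sorted(diff - bg)[:5]}")
    if not pathway_membership:
        raise ValueError("no pathways supplied")
    results = []
    for pathway, members in pathway_membership.items():
        mem = set(members) & bg
        a = len(diff & mem)
        b = len(diff - mem)
        c = len(mem - diff)
        d = len(bg - diff - mem)
        if b * c == 0:
            odds = math.inf if a * d > 0 else math.nan
        else:
            odds = (a * d) / (b * c)
        _or, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(EnrichmentResult(pathway, a, b, c, d, odds, float(p)))
    results.sort(key=lambda r: (r.p, r.pathway))
    return results


def round_half_up(value: float, digits: int = 0) -> float:
    """Round half away from zero at the printed precision (68.75 -> 69)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DriverSummaryRow:
    driver: str
    driver_class: str
    n_families: int
    pct_of_class: float  # of distinct families correlated in the class
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class DriverSummary:
    """Bookkeeping of passing links: counts, class percentages, signs."""

    rows: tuple[DriverSummaryRow, ...]
    class_totals: dict[str, int]  # distinct families with >=1 passing link

    def row(self, driver: str) -> DriverSummaryRow:
        for r in self.rows:
            if r.driver == driver:
                return r
        raise KeyError(driver)

    def formatted(self, driver: str) -> str:
        """e.g. '22 (69%)' — the printed-table form of one driver row."""
        r = self.row(driver)
        pct = r.pct_of_class
        text = f"{pct:g}"
        return f"{r.n_families} ({text}%)"


def summarize_links(links: Sequence[FamilyDriverLink], digits: int = 0) -> DriverSummary:
    """Per-driver counts of passing families with class percentages.

    The percentage base for a driver is the number of distinct families
    with at least one passing link in that driver's class; rounding is
    half-up at ``digits`` decimals to match printed tables.
    """
    passing = [l for l in links if l.passed]
    class_families: dict[str, set[str]] = {}
    for l in passing:
        class_families.setdefault(l.driver_class, set()).add(l.family)
    totals = {c: len(f) for c, f in class_families.items()}
    per_driver: dict[str, dict] = {}
    for l in passing:
        d = per_driver.setdefault(
            l.driver, {"class": l.driver_class, "families": set(), "pos": 0, "neg": 0}
        )
        if l.family not in d["families"]:
            d["families"].add(l.family)
            if l.sign > 0:
                d["pos"] += 1
            else:
                d["neg"] += 1
    rows = []
    for driver in sorted(per_driver):
        d = per_driver[driver]
        n = len(d["families"])
        total = totals[d["class"]]
        pct = round_half_up(100.0 * n / total, digits) if total else 0.0
        rows.append(
            DriverSummaryRow(
                driver=driver,
                driver_class=d["class"],
                n_families=n,
                pct_of_class=pct,
                n_positive=d["pos"],
                n_negative=d["neg"],
            )
        )
    return DriverSummary(rows=tuple(rows), class_totals=totals)


def run_pipeline(*args, **kwargs):
    """Orchestrated end-to-end run; see :mod:`sedadrivers.pipeline`."""
    from .pipeline import run_pipeline as _run

    return _run(*args, **kwargs)
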