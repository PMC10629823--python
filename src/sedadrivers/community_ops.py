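"""Count-matrix transformations shared by every analysis stage.

Rarefaction to a common read depth, aggregation of ASVs to family-level
grouping labels, relative abundance, z-scoring, and the zero-fraction
window filter that protects the sliding-window correlations from
sparse intervals.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import FeatureTable, TaxonomyMap

__all__ = [
    "FamilyTable",
    "rarefy",
    "collapse_to_family",
    "relative_abundance",
    "zscore_series",
    "zero_fraction_ok",
]

log = logging.getLogger(__name__)


class FamilyTable:
    """Family (grouping label) x layer matrix with an ASV registry.

    ``values`` holds counts after :func:`collapse_to_family` or
    proportions after :func:`relative_abundance`; ``registry`` maps each
    grouping label to the member ASV ids it aggregates, which the
    recall-rate filter needs downstream.
    """

    def __init__(
        self,
        labels: Sequence[str],
        layer_ids: Sequence[str],
        values: np.ndarray,
        registry: Mapping[str, Sequence[str]],
    ) -> None:
        labels = list(map(str, labels))
        layer_ids = list(map(str, layer_ids))
        values = np.asarray(values, dtype=float)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate grouping labels")
        if values.shape != (len(labels), len(layer_ids)):
            raise ValueError("values shape mismatch")
        missing = set(labels) - set(registry)
        if missing:
            raise ValueError(f"registry missing labels: {sorted(missing)}")
        seen: set[str] = set()
        for label in labels:
            members = set(registry[label])
            if members & seen:
                raise ValueError("an ASV maps to more than one grouping label")
            seen |= members
        self.labels = labels
        self.layer_ids = layer_ids
        self.values = values
        self.registry = {k: list(registry[k]) for k in labels}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.layer_ids)

    def subset_layers(self, layer_ids: Sequence[str]) -> "FamilyTable":
        idx = [self.layer_ids.index(l) for l in layer_ids]
        return FamilyTable(self.labels, list(layer_ids), self.values[:, idx], self.registry)


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each layer without replacement to exactly ``depth`` reads.

    Layers whose total falls short of the depth are dropped (and
    logged), mirroring the treatment of samples that fail a rarefaction
    cutoff. Sampling is a multivariate hypergeometric draw per layer.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    kept_cols: list[int] = []
    out_cols: list[np.ndarray] = []
    totals = table.counts.sum(axis=0)
    for j, total in enumerate(totals):
        if total < depth:
            log.info("rarefy: dropping layer %s (total %d < depth %d)", table.layer_ids[j], total, depth)
            continue
        kept_cols.append(j)
        if total == depth:
            out_cols.append(table.counts[:, j].copy())
        else:
            out_cols.append(rng.multivariate_hypergeometric(table.counts[:, j], depth))
    if not kept_cols:
        raise ValueError("no layer meets the rarefaction depth")
    counts = np.column_stack(out_cols)
    return FeatureTable(table.feature_ids, [table.layer_ids[j] for j in kept_cols], counts)


def collapse_to_family(table: FeatureTable, tax: TaxonomyMap) -> FamilyTable:
    """Sum ASV counts within each grouping label (family where possible)."""
    unknown = [fid for fid in table.feature_ids if fid not in tax]
    if unknown:
        raise ValueError(f"features missing from taxonomy: {unknown}")
    labels: list[str] = []
    registry: dict[str, list[str]] = {}
    rows: dict[str, np.ndarray] = {}
    for i, fid in enumerate(table.feature_ids):
        label = tax.label(fid)
        if label not in rows:
            labels.append(label)
            registry[label] = []
            rows[label] = np.zeros(len(table.layer_ids), dtype=float)
        registry[label].append(fid)
        rows[label] = rows[label] + table.counts[i]
    values = np.vstack([rows[l] for l in labels])
    return FamilyTable(labels, table.layer_ids, values, registry)


def relative_abundance(table: FamilyTable) -> FamilyTable:
    """Convert counts to column-stochastic proportions per layer."""
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"all-zero layers: {[table.layer_ids[j] for j in zero]}")
    return FamilyTable(table.labels, table.layer_ids, table.values / sums, table.registry)


def zscore_series(x: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0 and sample standard deviation 1 (n-1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (x - x.mean()) / sd


def zero_fraction_ok(biotic_window: Sequence[float], abiotic_window: Sequence[float]) -> bool:
    """True iff neither window has MORE than 50% zero values.

    Exactly half zeros passes on both sides (the discard rule is a
    strict 'more than').
    """
    b = np.asarray(biotic_window, dtype=float)
    a = np.asarray(abiotic_window, dtype=float)
    if b.shape != a.shape or b.size < 1:
        raise ValueError("windows must be equal-length, non-empty")
    return (b == 0).mean() <= 0.5 and (a == 0).mean() <= 0.5
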