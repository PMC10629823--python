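"""Readers, writers and the layer-to-driver time alignment.

All downstream stages consume the containers defined here: a dated
:class:`SedimentCore`, integer :class:`FeatureTable` count matrices, a
:class:`TaxonomyMap` resolving amplicon sequence variants (ASVs) to a
family-level (or lowest-available-rank) grouping label, yearly
:class:`AbioticSeries` for climate variables and biocide sales, and the
:class:`AlignedMatrices` product of matching ~3-year sediment layers to
yearly driver records.

On-disk dialects are deliberately plain: dense TSV feature tables (a
leading ``#OTU ID`` header is tolerated), greengenes-style taxonomy TSV,
CSV core metadata, and a year-wide CSV of drivers with a YAML/JSON
manifest describing each variable's class and units.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PHASES",
    "RANK_PREFIXES",
    "SedimentCore",
    "FeatureTable",
    "TaxonomyAssignment",
    "TaxonomyMap",
    "AbioticSeries",
    "AlignedMatrices",
    "FormatError",
    "read_core",
    "write_core",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_abiotic_tables",
    "write_abiotic_tables",
    "align_layers_to_drivers",
    "write_results",
    "read_results",
]

#: Lake phase codes: semi-pristine, eutrophic, pesticide, recovery.
PHASES = ("SP", "E", "P", "R")

#: Greengenes-style lineage rank prefixes, highest to lowest rank.
RANK_PREFIXES = (
    ("domain", "d__"),
    ("phylum", "p__"),
    ("class", "c__"),
    ("order", "o__"),
    ("family", "f__"),
    ("genus", "g__"),
    ("species", "s__"),
)


class FormatError(ValueError):
    """A file violated the expected on-disk dialect."""


# ---------------------------------------------------------------------------
# SedimentCore


@dataclass(frozen=True)
class SedimentCore:
    """Ordered, dated sediment layers with phase labels.

    Layers are strictly ordered by ``year_mid`` ascending. Each layer is
    assigned a half-open calendar-year span ``[start, end)`` derived from
    the gaps to neighbouring midpoints, so that spans tile the core's
    full range without gaps or double counting.
    """

    layer_ids: tuple[str, ...]
    depth_top_cm: tuple[float, ...]
    depth_bottom_cm: tuple[float, ...]
    year_mid: tuple[float, ...]
    phase: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.layer_ids)
        if n == 0:
            raise FormatError("core has no layers")
        if len(set(self.layer_ids)) != n:
            raise FormatError("duplicate layer ids in core")
        for name in ("depth_top_cm", "depth_bottom_cm", "year_mid", "phase"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"core field {name!r} length mismatch")
        ym = np.asarray(self.year_mid, dtype=float)
        if n > 1 and not np.all(np.diff(ym) > 0):
            raise FormatError("layers must be strictly ordered by year_mid")
        for ph in self.phase:
            if ph not in PHASES:
                raise FormatError(f"unknown phase label {ph!r}")
        # depth intervals must not overlap (younger sediment is shallower)
        for i in range(n):
            if self.depth_bottom_cm[i] < self.depth_top_cm[i]:
                raise FormatError(f"layer {self.layer_ids[i]}: inverted depth interval")

    def __len__(self) -> int:
        return len(self.layer_ids)

    @property
    def year_spans(self) -> tuple[tuple[float, float], ...]:
        """Half-open [start, end) calendar spans tiling the core range.

        Interior boundaries sit midway between neighbouring midpoints;
        the two edge layers take their single neighbour gap on the open
        side, so a one-layer core spans 3 years by convention.
        """
        ym = np.asarray(self.year_mid, dtype=float)
        n = len(ym)
        if n == 1:
            return (((ym[0] - 1.5), (ym[0] + 1.5)),)
        bounds = np.empty(n + 1)
        bounds[1:-1] = (ym[:-1] + ym[1:]) / 2.0
        bounds[0] = ym[0] - (ym[1] - ym[0]) / 2.0
        bounds[-1] = ym[-1] + (ym[-1] - ym[-2]) / 2.0
        return tuple((bounds[i], bounds[i + 1]) for i in range(n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer_id": self.layer_ids,
                "depth_top_cm": self.depth_top_cm,
                "depth_bottom_cm": self.depth_bottom_cm,
                "year_mid": self.year_mid,
                "phase": self.phase,
            }
        )


def read_core(path: str | Path) -> SedimentCore:
    """Read layer chronology/phase metadata from CSV."""
    df = pd.read_csv(path, dtype={"layer_id": str})
    required = {"layer_id", "depth_top_cm", "depth_bottom_cm", "year_mid", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"core metadata missing columns: {sorted(missing)}")
    df = df.sort_values("year_mid", kind="stable")
    return SedimentCore(
        layer_ids=tuple(df["layer_id"]),
        depth_top_cm=tuple(float(v) for v in df["depth_top_cm"]),
        depth_bottom_cm=tuple(float(v) for v in df["depth_bottom_cm"]),
        year_mid=tuple(float(v) for v in df["year_mid"]),
        phase=tuple(str(v) for v in df["phase"]),
    )


def write_core(core: SedimentCore, path: str | Path) -> Path:
    path = Path(path)
    core.to_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# FeatureTable


class FeatureTable:
    """Non-negative integer count matrix, features x layers."""

    def __init__(
        self,
        feature_ids: Sequence[str],
        layer_ids: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        feature_ids = list(map(str, feature_ids))
        layer_ids = list(map(str, layer_ids))
        counts = np.asarray(counts)
        if len(set(feature_ids)) != len(feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(layer_ids)) != len(layer_ids):
            raise FormatError("duplicate layer ids")
        if counts.shape != (len(feature_ids), len(layer_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(feature_ids)} features x {len(layer_ids)} layers"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise FormatError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and np.any(counts < 0):
            raise FormatError("counts must be non-negative")
        self.feature_ids = feature_ids
        self.layer_ids = layer_ids
        self.counts = counts.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.layer_ids)

    def subset_layers(self, layer_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.layer_ids.index(l) for l in layer_ids]
        return FeatureTable(self.feature_ids, list(layer_ids), self.counts[:, idx])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FeatureTable)
            and self.feature_ids == other.feature_ids
            and self.layer_ids == other.layer_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a dense TSV feature table (first column = feature id).

    A leading ``#OTU ID`` header cell (BIOM dense-TSV dialect) is
    tolerated; a ``# Constructed from biom file`` comment line is
    skipped.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if lines and lines[0].startswith("# Constructed"):
        lines = lines[1:]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    layer_ids = header[1:]
    if not layer_ids:
        raise FormatError(f"{path}: no layer columns")
    feature_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}: line {lineno} has {len(cells)} cells, expected {len(header)}")
        feature_ids.append(cells[0])
        row = []
        for col, cell in zip(layer_ids, cells[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(f"{path}: non-numeric count at ({cells[0]}, {col}): {cell!r}") from None
            if not value.is_integer():
                raise FormatError(f"{path}: non-integer count at ({cells[0]}, {col}): {cell!r}")
            if value < 0:
                raise FormatError(f"{path}: negative count at ({cells[0]}, {col})")
            row.append(int(value))
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no features")
    return FeatureTable(feature_ids, layer_ids, np.asarray(rows, dtype=np.int64))


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.layer_ids) + "\n")
        for fid, row in zip(table.feature_ids, table.counts):
            fh.write(fid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# TaxonomyMap


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Grouping label for one feature with the rank actually used."""

    feature_id: str
    label: str
    rank: str
    lineage: tuple[tuple[str, str], ...]  # (rank, name) pairs, high to low


class TaxonomyMap:
    """Per-feature grouping labels: family rank when present, else the
    lowest available rank, else ``Unassigned``."""

    def __init__(self, assignments: Iterable[TaxonomyAssignment]) -> None:
        self._by_id: dict[str, TaxonomyAssignment] = {}
        for a in assignments:
            if a.feature_id in self._by_id:
                raise FormatError(f"duplicate taxonomy entry for {a.feature_id}")
            self._by_id[a.feature_id] = a

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __getitem__(self, feature_id: str) -> TaxonomyAssignment:
        return self._by_id[feature_id]

    def label(self, feature_id: str) -> str:
        return self._by_id[feature_id].label

    def items(self):
        return self._by_id.items()


def parse_lineage(lineage: str) -> tuple[tuple[str, str], ...]:
    """Parse ``d__X; p__Y; ...`` into ordered (rank, name) pairs."""
    pairs: list[tuple[str, str]] = []
    for token in lineage.split(";"):
        token = token.strip()
        if not token:
            continue
        for rank, prefix in RANK_PREFIXES:
            if token.startswith(prefix):
                name = token[len(prefix):].strip()
                if name:
                    pairs.append((rank, name))
                break
        else:
            # un-prefixed token: ignore rather than fail (classifier quirk)
            continue
    return tuple(pairs)


def assign_label(feature_id: str, lineage: str) -> TaxonomyAssignment:
    pairs = parse_lineage(lineage)
    if not pairs:
        warnings.warn(f"feature {feature_id}: empty lineage, labelled Unassigned")
        return TaxonomyAssignment(feature_id, "Unassigned", "none", ())
    by_rank = dict(pairs)
    if "family" in by_rank:
        return TaxonomyAssignment(feature_id, by_rank["family"], "family", pairs)
    rank, name = pairs[-1]
    return TaxonomyAssignment(feature_id, name, rank, pairs)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a 2-3 column TSV (feature id, lineage, optional confidence)."""
    path = Path(path)
    assignments = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            if lineno == 1 and ln.lower().startswith(("feature", "#otu", "otu")):
                continue  # header row
            cells = ln.split("\t")
            fid = cells[0]
            lineage = cells[1] if len(cells) > 1 else ""
            assignments.append(assign_label(fid, lineage))
    if not assignments:
        raise FormatError(f"{path}: no taxonomy rows")
    return TaxonomyMap(assignments)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("Feature ID\tTaxon\n")
        for fid, a in tax.items():
            prefix = {rank: p for rank, p in RANK_PREFIXES}
            lineage = "; ".join(prefix[r] + n for r, n in a.lineage)
            fh.write(f"{fid}\t{lineage}\n")
    return path


# ---------------------------------------------------------------------------
# AbioticSeries


BIOCIDE_TYPES = ("insecticide", "fungicide", "herbicide", "pesticide", "other")


@dataclass(frozen=True)
class AbioticSeries:
    """One named yearly driver series.

    ``years`` holds only the years with a recorded value: values before
    the first recorded year are absent, never zero (biocides simply do
    not exist before introduction).
    """

    name: str
    clazz: str  # "climate" | "biocide"
    years: tuple[int, ...]
    values: tuple[float, ...]
    biocide_type: str | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.clazz not in ("climate", "biocide"):
            raise FormatError(f"series {self.name}: unknown class {self.clazz!r}")
        if self.clazz == "biocide":
            if self.biocide_type not in BIOCIDE_TYPES:
                raise FormatError(
                    f"series {self.name}: biocide requires a biocide_type, got {self.biocide_type!r}"
                )
        if len(self.years) != len(self.values):
            raise FormatError(f"series {self.name}: years/values length mismatch")
        ys = np.asarray(self.years)
        if len(ys) > 1 and not np.all(np.diff(ys) > 0):
            raise FormatError(f"series {self.name}: years must be strictly increasing")

    def value_at(self, year: int) -> float | None:
        try:
            return self.values[self.years.index(year)]
        except ValueError:
            return None

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"), name=self.name)


def read_abiotic_tables(path: str | Path, manifest: str | Path) -> list[AbioticSeries]:
    """Read a year-wide driver CSV plus its category manifest.

    The manifest (YAML or JSON) maps variable name to
    ``{class, biocide_type, units}``. Variables absent from the manifest
    are inferred as climate with a warning. Blank cells are absent
    values at that year, never zeros.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise FormatError(f"{path}: missing 'year' column")
    years_all = df["year"].to_numpy()
    if np.any(np.diff(years_all) <= 0):
        raise FormatError(f"{path}: years must be strictly increasing")
    names = [c for c in df.columns if c != "year"]
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate variable names")
    with open(manifest) as fh:
        text = fh.read()
    meta = yaml.safe_load(text) or {}
    series = []
    for name in names:
        col = df[name]
        mask = col.notna()
        info = meta.get(name)
        if info is None:
            warnings.warn(f"variable {name!r} missing from manifest; inferred class 'climate'")
            info = {"class": "climate"}
        series.append(
            AbioticSeries(
                name=name,
                clazz=info.get("class", "climate"),
                biocide_type=info.get("biocide_type"),
                units=info.get("units", ""),
                years=tuple(int(y) for y in years_all[mask]),
                values=tuple(float(v) for v in col[mask]),
            )
        )
    return series


def write_abiotic_tables(
    series: Sequence[AbioticSeries], path: str | Path, manifest: str | Path
) -> tuple[Path, Path]:
    path, manifest = Path(path), Path(manifest)
    frame = pd.concat([s.as_series() for s in series], axis=1).sort_index()
    frame.insert(0, "year", frame.index)
    frame.to_csv(path, index=False)
    meta = {
        s.name: {
            "class": s.clazz,
            **({"biocide_type": s.biocide_type} if s.biocide_type else {}),
            "units": s.units,
        }
        for s in series
    }
    with open(manifest, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path, manifest


# ---------------------------------------------------------------------------
# Alignment


#: Minimum layers a driver needs for the sliding-window stage to fit.
MIN_LAYERS_PER_DRIVER = 5


@dataclass
class AlignedMatrices:
    """Layer axis shared by biotic and abiotic matrices.

    ``abiotic`` is drivers x layers with NaN where a driver has no
    recorded year inside a layer's span; ``valid`` marks, per driver,
    the layers that survive for that driver's analysis axis.
    """

    layer_ids: tuple[str, ...]
    year_mid: tuple[float, ...]
    abiotic: pd.DataFrame
    valid: pd.DataFrame
    classes: dict[str, str]
    biocide_types: dict[str, str | None]
    unanalyzable: tuple[str, ...]
    exclusions: tuple[str, ...]

    def driver_names(self, clazz: str | None = None) -> list[str]:
        names = [n for n in self.abiotic.index if n not in self.unanalyzable]
        if clazz is not None:
            names = [n for n in names if self.classes[n] == clazz]
        return names

    def driver_axis(self, name: str) -> tuple[list[str], np.ndarray]:
        """Ordered surviving layer ids and driver values for one driver."""
        mask = self.valid.loc[name].to_numpy()
        layers = [l for l, m in zip(self.layer_ids, mask) if m]
        return layers, self.abiotic.loc[name].to_numpy()[mask]


def align_layers_to_drivers(
    core: SedimentCore,
    series: Sequence[AbioticSeries],
    analysis_start_year: float = -math.inf,
    agg: str = "mean",
) -> AlignedMatrices:
    """Match yearly driver records onto sediment layers.

    The abiotic value for a layer is the unweighted mean (or sum, for
    sales quantities) of the yearly values whose calendar year falls in
    the layer's half-open span. Layers whose span begins before
    ``analysis_start_year`` are excluded outright; a layer missing any
    recorded year for a driver is excluded from that driver's axis
    rather than imputed. Drivers left with fewer than
    ``MIN_LAYERS_PER_DRIVER`` layers are flagged unanalyzable.
    """
    if agg not in ("mean", "sum"):
        raise ValueError(f"agg must be 'mean' or 'sum', got {agg!r}")
    spans = core.year_spans
    keep = [i for i, (start, _end) in enumerate(spans) if start >= analysis_start_year]
    layer_ids = tuple(core.layer_ids[i] for i in keep)
    year_mid = tuple(core.year_mid[i] for i in keep)
    exclusions = [
        f"layer {core.layer_ids[i]}: span starts before {analysis_start_year}"
        for i in range(len(core))
        if i not in keep
    ]
    names = [s.name for s in series]
    if len(set(names)) != len(names):
        raise FormatError("duplicate driver names")
    values = np.full((len(series), len(keep)), np.nan)
    valid = np.zeros((len(series), len(keep)), dtype=bool)
    for si, s in enumerate(series):
        yrs = np.asarray(s.years)
        vals = np.asarray(s.values, dtype=float)
        for li, i in enumerate(keep):
            start, end = spans[i]
            covered = np.arange(math.ceil(start), math.ceil(end))
            in_series = np.isin(covered, yrs)
            if len(covered) == 0 or not np.all(in_series):
                exclusions.append(
                    f"layer {core.layer_ids[i]}: driver {s.name} missing years in span "
                    f"[{start:g},{end:g})"
                )
                continue
            picked = vals[np.isin(yrs, covered)]
            values[si, li] = picked.sum() if agg == "sum" else picked.mean()
            valid[si, li] = True
    unanalyzable = tuple(
        s.name for si, s in enumerate(series) if valid[si].sum() < MIN_LAYERS_PER_DRIVER
    )
    return AlignedMatrices(
        layer_ids=layer_ids,
        year_mid=year_mid,
        abiotic=pd.DataFrame(values, index=names, columns=list(layer_ids)),
        valid=pd.DataFrame(valid, index=names, columns=list(layer_ids)),
        classes={s.name: s.clazz for s in series},
        biocide_types={s.name: s.biocide_type for s in series},
        unanalyzable=unanalyzable,
        exclusions=tuple(exclusions),
    )


# ---------------------------------------------------------------------------
# Generic record writers (round-trip stable)


def _flatten(record) -> dict:
    if dataclasses.is_dataclass(record):
        out = {}
        for f in dataclasses.fields(record):
            v = getattr(record, f.name)
            if dataclasses.is_dataclass(v):
                for k, sub in _flatten(v).items():
                    out[f"{f.name}.{k}"] = sub
            else:
                out[f.name] = v
        return out
    if isinstance(record, Mapping):
        return dict(record)
    raise TypeError(f"cannot serialize record of type {type(record).__name__}")


def write_results(records: Sequence, path: str | Path, format: str = "tsv", fields: Sequence[str] | None = None) -> Path:
    """Write a homogeneous record collection to TSV or JSON.

    Nested dataclass fields are flattened with dotted names so that
    ``read_results(write_results(x)) == x`` field for field. An empty
    collection yields a header-only file (TSV) or an empty list (JSON);
    for an empty TSV pass ``fields`` to supply the header.
    """
    path = Path(path)
    rows = [_flatten(r) for r in records]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1, default=_json_default)
            fh.write("\n")
        return path
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    if rows:
        fields = list(rows[0].keys())
    elif fields is None:
        fields = []
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for row in rows:
            fh.write("\t".join(_cell(row[f]) for f in fields) + "\n")
    return path


def _json_default(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    raise TypeError(f"unserializable value {v!r}")


def _cell(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if v is None:
        return ""
    if isinstance(v, float) and math.isnan(v):
        return "nan"
    return repr(v) if isinstance(v, float) else str(v)


def read_results(path: str | Path, format: str = "tsv") -> list[dict]:
    """Read back a :func:`write_results` file as a list of flat dicts."""
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    rows = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0]:
        return []
    header = lines[0].split("\t")
    for ln in lines[1:]:
        if not ln:
            continue
        cells = ln.split("\t")
        rows.append({h: _parse_cell(c) for h, c in zip(header, cells)})
    return rows


def _parse_cell(cell: str):
    if cell == "":
        return None
    if cell == "true":
        return True
    if cell == "false":
        return False
    try:
        return int(cell)
    except ValueError:
        pass
    try:
        return float(cell)
    except ValueError:
        return cell
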