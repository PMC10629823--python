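"""End-to-end orchestration: simulate/load -> diversity -> PERMANOVA ->
sparse CCA ranking -> sliding-window links -> joint effects -> summary.

Every stage writes a plain-text table under the output directory and a
run manifest records the seed, package version and a hash of the
configuration, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community_ops import collapse_to_family, rarefy, relative_abundance
from .community_shift import bray_curtis, kruskal_wallis, permanova_pairwise, shannon
from .enrich_summary import summarize_links
from .io_formats import (
    AlignedMatrices,
    align_layers_to_drivers,
    read_abiotic_tables,
    read_core,
    read_feature_table,
    read_taxonomy,
    write_abiotic_tables,
    write_core,
    write_feature_table,
    write_results,
    write_taxonomy,
)
from .joint_effects import combined_significance, detect_joint_effects, joint_frequency_matrix
from .scca_rank import SccaConfig, rank_drivers, scca_fit, variance_explained
from .synthetic_core import SimulationConfig, score_recovery, simulate_core
from .window_corr import SwcConfig, call_family_links

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for one pipeline run.

    Either ``simulate`` is set (synthetic data, seeded) or the four
    input paths are. ``analysis_start_year`` defaults to the biocide
    introduction year so the driver analysis spans only the layers for
    which biocide records exist.
    """

    seed: int = 0
    simulate: SimulationConfig | None = None
    feature_table_path: str | None = None
    taxonomy_path: str | None = None
    core_path: str | None = None
    abiotic_path: str | None = None
    manifest_path: str | None = None
    rarefaction_depth: int | None = None
    analysis_start_year: float | None = None
    n_permutations_permanova: int = 999
    scca: SccaConfig = field(default_factory=SccaConfig)
    swc: SwcConfig = field(default_factory=SwcConfig)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output."""

    core: object
    family_rel: object
    alpha: pd.DataFrame
    kruskal: tuple[float, float]
    permanova: list
    aligned: AlignedMatrices
    scca_rankings: dict
    scca_variance: dict
    links: object
    joint_records: list
    joint_matrix: pd.DataFrame
    summary: object
    recovery: object | None
    outdir: Path | None


def _stable_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage; write tables plus a manifest when ``outdir`` set."""
    if config.simulate is not None:
        core, table, tax, drivers, truth = simulate_core(config.simulate, config.seed)
        biocide_year = config.simulate.biocide_year
    else:
        for name in ("feature_table_path", "taxonomy_path", "core_path", "abiotic_path", "manifest_path"):
            if getattr(config, name) is None:
                raise ValueError(f"missing input: {name} (or set config.simulate)")
        core = read_core(config.core_path)
        table = read_feature_table(config.feature_table_path)
        tax = read_taxonomy(config.taxonomy_path)
        drivers = read_abiotic_tables(config.abiotic_path, config.manifest_path)
        truth = None
        biocide_year = min(
            (s.years[0] for s in drivers if s.clazz == "biocide"), default=core.year_mid[0]
        )

    if config.rarefaction_depth:
        table = rarefy(table, config.rarefaction_depth, seed=config.seed)

    families = collapse_to_family(table, tax)
    family_rel = relative_abundance(families)
    asv_rel = table.to_frame().astype(float)
    asv_rel = asv_rel / asv_rel.sum(axis=0)

    # --- alpha and beta diversity across phases
    phase_of = dict(zip(core.layer_ids, core.phase))
    alpha_rows = []
    for j, layer in enumerate(families.layer_ids):
        alpha_rows.append(
            {"layer_id": layer, "phase": phase_of[layer], "shannon_bits": shannon(families.values[:, j])}
        )
    alpha = pd.DataFrame(alpha_rows)
    groups = [g["shannon_bits"].to_numpy() for _, g in alpha.groupby("phase") if len(g) > 0]
    kw = kruskal_wallis(groups) if len(groups) >= 2 else (float("nan"), float("nan"))
    dist = bray_curtis(families.values.T, ids=families.layer_ids)
    permanova = permanova_pairwise(
        dist,
        [phase_of[l] for l in families.layer_ids],
        n_perm=config.n_permutations_permanova,
        seed=config.seed,
    )

    # --- driver alignment: the link scan uses each driver's full valid
    # axis (climate spans the whole core; biocide axes start at the
    # introduction year through missing-record exclusion alone), while
    # the sparse CCA uses the common biocide-era axis
    aligned = align_layers_to_drivers(core, drivers)
    fam_aligned = family_rel.subset_layers(list(aligned.layer_ids))
    start = config.analysis_start_year if config.analysis_start_year is not None else biocide_year
    aligned_era = align_layers_to_drivers(core, drivers, analysis_start_year=start)

    # --- sparse CCA ranking on the layers shared by every driver
    common = np.asarray(aligned_era.valid.loc[list(aligned_era.driver_names())].all(axis=0))
    common_layers = [l for l, m in zip(aligned_era.layer_ids, common) if m]
    scca_rankings: dict = {}
    scca_variance: dict = {}
    if len(common_layers) >= 3:
        idx = [list(aligned.layer_ids).index(l) for l in common_layers]
        Xf = fam_aligned.values[:, idx].T  # layers x families
        keep = Xf.std(axis=0) > 0
        Xz = (Xf[:, keep] - Xf[:, keep].mean(axis=0)) / Xf[:, keep].std(axis=0, ddof=1)
        fam_names = [f for f, k in zip(fam_aligned.labels, keep) if k]
        driver_names = aligned_era.driver_names()
        Zm = aligned_era.abiotic.loc[driver_names, common_layers].to_numpy().T
        Zz = (Zm - Zm.mean(axis=0)) / Zm.std(axis=0, ddof=1)
        result = scca_fit(Xz, Zz, config.scca, family_names=fam_names, driver_names=driver_names)
        scca_rankings = rank_drivers(result, classes=aligned.classes)
        for clazz in sorted(set(aligned.classes[d] for d in driver_names)):
            cols = [i for i, d in enumerate(driver_names) if aligned.classes[d] == clazz]
            sub = scca_fit(
                Xz, Zz[:, cols], config.scca,
                family_names=fam_names,
                driver_names=[driver_names[i] for i in cols],
            )
            scca_variance[clazz] = variance_explained(sub, Xz, Zz[:, cols])["biotic"]

    # --- sliding-window link calling and joint effects
    links = call_family_links(fam_aligned, asv_rel, aligned, config.swc)
    by_class = {
        clazz: [l for l in links.links if l.driver_class == clazz]
        for clazz in ("biocide", "climate")
    }
    candidates = combined_significance(
        by_class.get("biocide", []), by_class.get("climate", []), fam_aligned, aligned, config.swc
    )
    joint_records = detect_joint_effects(candidates, fam_aligned, aligned, config.swc)
    joint_matrix = joint_frequency_matrix(joint_records, aligned.biocide_types)
    summary = summarize_links(links.links)
    recovery = score_recovery(list(links.links) + list(joint_records), truth) if truth else None

    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_core(core, out / "core.csv")
        write_feature_table(table, out / "feature_table.tsv")
        write_taxonomy(tax, out / "taxonomy.tsv")
        write_abiotic_tables(drivers, out / "abiotic.csv", out / "abiotic_manifest.yaml")
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
        write_results(permanova, out / "permanova.tsv", "tsv")
        write_results(list(links.links), out / "links.tsv", "tsv")
        write_results(joint_records, out / "joint_effects.tsv", "tsv")
        joint_matrix.to_csv(out / "joint_frequency.tsv", sep="\t")
        write_results(list(summary.rows), out / "driver_summary.tsv", "tsv")
        manifest = {
            "seed": config.seed,
            "version": __version__,
            "config_hash": _stable_hash(config),
            "kruskal_wallis": {"H": kw[0], "p": kw[1]},
            "scca_rankings": scca_rankings,
            "scca_variance_explained": scca_variance,
            "recall_q90": links.recall_q90,
            "n_links_passing": sum(1 for l in links.links if l.passed),
            "n_joint_effects": sum(1 for r in joint_records if r.is_joint),
            **(
                {"recovery": dataclasses.asdict(recovery)}
                if recovery is not None
                else {}
            ),
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
            fh.write("\n")

    return PipelineResult(
        core=core,
        family_rel=family_rel,
        alpha=alpha,
        kruskal=kw,
        permanova=permanova,
        aligned=aligned,
        scca_rankings=scca_rankings,
        scca_variance=scca_variance,
        links=links,
        joint_records=joint_records,
        joint_matrix=joint_matrix,
        summary=summary,
        recovery=recovery,
        outdir=out,
    )
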