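"""Synthetic sediment-core datasets with planted ground truth.

Emulates the data shape the analysis assumes: a 34-layer core spanning
1916-2016 at ~3-year resolution with four phase regimes (semi-pristine,
eutrophic, pesticide, recovery), family-structured ASV counts drawn by
multinomial sampling, yearly climate series (linear trend + AR(1)
noise), and biocide sales series that are absent before their
introduction year and then follow a smooth rise-peak-decline pulse.

Family dynamics are latent log-abundances

    lambda_f(t) = baseline_f + phase_offset_f + sum_d beta * z_d(t) + AR(1) noise,

where beta is calibrated from the target correlation r* through the
variance identity r* = beta / sqrt(beta^2 + sigma^2) on standardized
drivers (sigma is the stationary sd of the AR(1) noise), so the
realized Pearson correlation between the family's relative abundance
and the driver lands near r*. Joint-effect families load on the
equal-weight sum of a standardized biocide and climate driver. Counts
are a multinomial split of softmax(lambda) across each family's ASVs,
conditioned on a log-normal library size per layer — preserving the
compositionality that rarefaction assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    AbioticSeries,
    FeatureTable,
    SedimentCore,
    TaxonomyAssignment,
    TaxonomyMap,
    align_layers_to_drivers,
)

__all__ = [
    "PlantedLink",
    "PlantedJoint",
    "SimulationConfig",
    "TruthTable",
    "RecoveryScore",
    "default_scenario",
    "null_scenario",
    "simulate_drivers",
    "simulate_core",
    "score_recovery",
]


@dataclass(frozen=True)
class PlantedLink:
    """A planted family-driver correlation with target strength r* and sign."""

    family: str
    driver: str
    r: float  # target |r*| in (0, 1)
    sign: int  # +1 or -1


@dataclass(frozen=True)
class PlantedJoint:
    """A planted joint biocide x climate effect on one family.

    Signed weights: the family's latent log-abundance loads on
    ``w_bio * z(biocide) + w_cli * z(climate)``. The equal-weight joint
    test can only beat both individual correlations when the two
    weights share a sign, so adverse joint effects use -1/-1.
    """

    family: str
    biocide: str
    climate: str
    w_bio: float = -1.0
    w_cli: float = -1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic core.

    Defaults mirror the emulated system: 34 layers over 1916-2016,
    phase boundaries SP < 1958, E 1958-1979, P 1980-1998, R >= 1999,
    biocides introduced in 1960 peaking in the pesticide phase. The
    AR(1) latent noise (phi, sd) sets family log-abundance persistence
    and spread; the beta calibration uses its stationary sd.
    """

    n_layers: int = 34
    year_start: int = 1916
    year_end: int = 2016
    phase_boundaries: tuple[int, int, int] = (1958, 1980, 1999)  # E, P, R starts
    n_families: int = 20
    asvs_per_family: tuple[int, int] = (2, 6)
    library_size_log_mean: float = math.log(10_000.0)
    library_size_log_sd: float = 0.3
    # layers aggregate ~3 years, so yearly persistence ~0.7 maps to
    # ~0.7^3 ~ 0.35 at layer resolution
    ar_coef: float = 0.35
    ar_sd: float = 0.4
    baseline_sd: float = 1.0
    climate_names: tuple[str, ...] = (
        "mean_minimum_temperature",
        "summer_precipitation",
        "summer_atmospheric_pressure",
        "highest_recorded_temperature",
    )
    climate_trends: tuple[float, ...] = (0.02, 0.0, 0.005, 0.015)
    climate_ar_coef: float = 0.5
    climate_sd: float = 1.0
    biocide_types: Mapping[str, str] = field(
        default_factory=lambda: {
            "insecticides": "insecticide",
            "fungicides": "fungicide",
            "herbicides": "herbicide",
            "pesticides": "pesticide",
        }
    )
    biocide_peak_years: tuple[int, ...] = (1975, 1984, 1993, 2002)
    biocide_pulse_widths: tuple[float, ...] = (5.0, 6.0, 7.0, 8.0)
    # relative to pulse amplitude; sales records swing hard year to year
    # (regulation, prices, weather), and ~3-year layer aggregation
    # averages yearly noise down by ~sqrt(3)
    biocide_noise_sd: float = 0.6
    biocide_year: int = 1960
    planted_links: tuple[PlantedLink, ...] = ()
    planted_joints: tuple[PlantedJoint, ...] = ()
    joint_target_r: float = 0.9
    phase_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    unassigned_fraction: float = 0.1  # ASVs lacking family rank (fallback rule)

    def __post_init__(self) -> None:
        if not self.phase_boundaries[0] < self.phase_boundaries[1] < self.phase_boundaries[2]:
            raise ValueError("phase boundaries must be ordered")
        if self.n_layers < 2 or self.n_families < 1:
            raise ValueError("need at least 2 layers and 1 family")
        for link in self.planted_links:
            if not 0.0 < link.r < 1.0:
                raise ValueError(f"target |r*| must lie in (0, 1): {link}")
            if link.sign not in (-1, 1):
                raise ValueError(f"sign must be +1 or -1: {link}")
        if (self.planted_links or self.planted_joints) and self.ar_sd <= 0:
            raise ValueError("planting correlations requires ar_sd > 0")

    def phase_of(self, year: float) -> str:
        e, p, r = self.phase_boundaries
        if year < e:
            return "SP"
        if year < p:
            return "E"
        if year < r:
            return "P"
        return "R"

    def family_names(self) -> list[str]:
        return [f"family_{i + 1:02d}" for i in range(self.n_families)]


@dataclass(frozen=True)
class TruthTable:
    """Planted structure against which calls are scored."""

    links: tuple[PlantedLink, ...]
    joints: tuple[PlantedJoint, ...]
    phase_shift_families: tuple[str, ...]


@dataclass(frozen=True)
class RecoveryScore:
    """Precision/recall of called links and joint effects vs the truth."""

    precision: float
    recall: float
    joint_precision: float
    joint_recall: float
    precision_defined: bool = True
    joint_precision_defined: bool = True


def default_scenario(seed: int = 0) -> SimulationConfig:
    """The reference planted scenario: 20 families, 4 links at r* = 0.8
    (two biocide-negative, two climate with mixed signs), 2 joint
    effects, and 2 phase-shift families."""
    return SimulationConfig(
        planted_links=(
            PlantedLink("family_01", "insecticides", 0.8, -1),
            PlantedLink("family_02", "fungicides", 0.8, -1),
            PlantedLink("family_03", "mean_minimum_temperature", 0.8, +1),
            PlantedLink("family_04", "summer_precipitation", 0.8, -1),
        ),
        planted_joints=(
            PlantedJoint("family_05", "insecticides", "mean_minimum_temperature"),
            PlantedJoint("family_06", "fungicides", "summer_precipitation"),
        ),
        # an E-phase box is near-orthogonal to linear climate trends and
        # to the later biocide pulses, so it drives pairwise PERMANOVA
        # without planting a spurious driver correlation
        phase_shifts={
            "family_07": {"E": 1.2},
            "family_08": {"E": -1.2},
        },
    )


def null_scenario(n_families: int = 20) -> SimulationConfig:
    """Global-null conditions: no planted links, joints or phase shifts."""
    return SimulationConfig(n_families=n_families)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with innovation sd ``sd``."""
    out = np.zeros(n)
    if sd == 0:
        return out
    stat_sd = sd / math.sqrt(1.0 - phi**2) if abs(phi) < 1 else sd
    out[0] = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t - 1]
    return out


def simulate_drivers(config: SimulationConfig, seed: int) -> list[AbioticSeries]:
    """Yearly climate and biocide series over the configured range."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    years = np.arange(config.year_start, config.year_end + 1)
    series: list[AbioticSeries] = []
    for name, trend in zip(config.climate_names, config.climate_trends):
        noise = _ar1(rng, len(years), config.climate_ar_coef, config.climate_sd)
        values = trend * (years - config.year_start) + noise
        series.append(
            AbioticSeries(
                name=name,
                clazz="climate",
                years=tuple(int(y) for y in years),
                values=tuple(float(v) for v in values),
                units="index",
            )
        )
    byears = years[years >= config.biocide_year]
    for i, (name, btype) in enumerate(config.biocide_types.items()):
        peak = config.biocide_peak_years[i % len(config.biocide_peak_years)]
        width = config.biocide_pulse_widths[i % len(config.biocide_pulse_widths)]
        amplitude = float(rng.uniform(50.0, 150.0))
        pulse = amplitude * np.exp(-((byears - peak) ** 2) / (2.0 * width**2))
        noise = rng.normal(0.0, config.biocide_noise_sd * amplitude, size=len(byears))
        values = np.maximum(pulse + noise, 0.0)
        series.append(
            AbioticSeries(
                name=name,
                clazz="biocide",
                biocide_type=btype,
                years=tuple(int(y) for y in byears),
                values=tuple(float(v) for v in values),
                units="tonnes/yr",
            )
        )
    return series


def _build_core(config: SimulationConfig) -> SedimentCore:
    year_mid = np.linspace(config.year_start, config.year_end, config.n_layers)
    n = config.n_layers
    return SedimentCore(
        layer_ids=tuple(f"L{i + 1:02d}" for i in range(n)),
        depth_top_cm=tuple(0.5 * (n - 1 - i) for i in range(n)),
        depth_bottom_cm=tuple(0.5 * (n - i) for i in range(n)),
        year_mid=tuple(float(y) for y in year_mid),
        phase=tuple(config.phase_of(y) for y in year_mid),
    )


def _beta_for(r: float, sigma: float) -> float:
    """Invert r = beta / sqrt(beta^2 + sigma^2) for beta (standardized driver)."""
    if not 0.0 < r < 1.0:
        raise ValueError(f"infeasible target correlation {r}")
    return sigma * r / math.sqrt(1.0 - r * r)


def _z_on_valid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """z-score over valid layers; zero contribution where invalid."""
    out = np.zeros_like(values, dtype=float)
    v = values[valid]
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("driver constant over its valid layers")
    out[valid] = (v - v.mean()) / sd
    return out


def simulate_core(
    config: SimulationConfig, seed: int
) -> tuple[SedimentCore, FeatureTable, TaxonomyMap, list[AbioticSeries], TruthTable]:
    """Full synthetic dataset: core, ASV counts, taxonomy, drivers, truth."""
    drivers = simulate_drivers(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 22]))
    core = _build_core(config)
    n_layers = len(core)
    aligned = align_layers_to_drivers(core, drivers)
    driver_z: dict[str, np.ndarray] = {}
    for s in drivers:
        valid = aligned.valid.loc[s.name].to_numpy()
        driver_z[s.name] = _z_on_valid(aligned.abiotic.loc[s.name].to_numpy(), valid)

    names = config.family_names()
    known = {l.family for l in config.planted_links} | {j.family for j in config.planted_joints}
    missing = (known | set(config.phase_shifts)) - set(names)
    if missing:
        raise ValueError(f"planted structure references unknown families: {sorted(missing)}")

    sigma = config.ar_sd / math.sqrt(1.0 - config.ar_coef**2) if config.ar_sd > 0 else 0.0
    phases = np.asarray(core.phase)
    lam0 = np.zeros((config.n_families, n_layers))
    for fi, fam in enumerate(names):
        lam0[fi] += rng.normal(0.0, config.baseline_sd)
        offsets = config.phase_shifts.get(fam)
        if offsets:
            lam0[fi] += np.asarray([offsets.get(ph, 0.0) for ph in phases])
        lam0[fi] += _ar1(rng, n_layers, config.ar_coef, config.ar_sd)

    # planted effect vectors: (family index, signed target r, standardized
    # driver combination, mask of layers the target correlation is over)
    planted_terms: list[tuple[int, float, np.ndarray, np.ndarray]] = []
    for link in config.planted_links:
        fi = names.index(link.family)
        valid = aligned.valid.loc[link.driver].to_numpy()
        planted_terms.append((fi, link.sign * link.r, driver_z[link.driver], valid))
    for joint in config.planted_joints:
        fi = names.index(joint.family)
        combo = joint.w_bio * driver_z[joint.biocide] + joint.w_cli * driver_z[joint.climate]
        valid = (
            aligned.valid.loc[joint.biocide].to_numpy()
            & aligned.valid.loc[joint.climate].to_numpy()
        )
        v = combo[valid]
        combo_z = np.zeros_like(combo)
        combo_z[valid] = (v - v.mean()) / v.std(ddof=1)
        planted_terms.append((fi, config.joint_target_r, combo_z, valid))

    # beta from the variance identity, then two deterministic secant
    # refinements on the realized pre-sampling relative-abundance
    # correlation (softmax attenuation would otherwise center the
    # realized r below the target)
    betas = [math.copysign(_beta_for(abs(tr), sigma), tr) for _fi, tr, _v, _m in planted_terms]

    def _lam(bs: Sequence[float]) -> np.ndarray:
        lam = lam0.copy()
        for (fi, _tr, v, _m), b in zip(planted_terms, bs):
            lam[fi] = lam0[fi] + b * v
        return lam

    def _realized(lam: np.ndarray, fi: int, v: np.ndarray, mask: np.ndarray) -> float:
        share = np.exp(lam - lam.max(axis=0, keepdims=True))
        share /= share.sum(axis=0, keepdims=True)
        s = share[fi][mask]
        if s.std() == 0:
            return 0.0
        return float(np.corrcoef(s, v[mask])[0, 1])

    # the exp link caps the attainable relative-abundance correlation
    # (larger beta adds convexity as fast as signal), so keep the
    # best-tried beta per term rather than trusting the last step
    best_betas = list(betas)
    best_err = [math.inf] * len(betas)
    for _ in range(3):
        lam_now = _lam(betas)
        new = []
        for ti, ((fi, target, v, mask), b) in enumerate(zip(planted_terms, betas)):
            got = _realized(lam_now, fi, v, mask)
            err = abs(abs(got) - abs(target))
            if err < best_err[ti]:
                best_err[ti], best_betas[ti] = err, b
            if abs(got) < 1e-3 or abs(got) >= 1.0:
                new.append(b)
                continue
            factor = math.atanh(min(abs(target), 0.999)) / math.atanh(min(abs(got), 0.999))
            new.append(b * min(max(factor, 0.5), 2.0))
        betas = new
    lam = _lam(best_betas)

    # split each family across its ASVs with fixed within-family shares
    lo, hi = config.asvs_per_family
    n_asvs = rng.integers(lo, hi + 1, size=config.n_families)
    asv_ids: list[str] = []
    asv_family: list[int] = []
    asv_share: list[float] = []
    for fi, fam in enumerate(names):
        shares = rng.dirichlet(np.full(n_asvs[fi], 5.0))
        for j, w in enumerate(shares):
            asv_ids.append(f"asv_{fam}_{j + 1}")
            asv_family.append(fi)
            asv_share.append(float(w))
    asv_family_arr = np.asarray(asv_family)
    asv_share_arr = np.asarray(asv_share)

    # per-layer multinomial draw conditioned on a log-normal library size
    counts = np.zeros((len(asv_ids), n_layers), dtype=np.int64)
    fam_prob = np.exp(lam - lam.max(axis=0, keepdims=True))
    fam_prob /= fam_prob.sum(axis=0, keepdims=True)
    lib_sizes = np.maximum(
        1,
        np.round(
            rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, size=n_layers)
        ).astype(np.int64),
    )
    for t in range(n_layers):
        p_asv = fam_prob[asv_family_arr, t] * asv_share_arr
        p_asv /= p_asv.sum()
        counts[:, t] = rng.multinomial(lib_sizes[t], p_asv)

    # taxonomy: ~unassigned_fraction of ASVs (never in truth families) stop
    # at order rank to exercise the lowest-available-rank fallback
    truth_families = known | set(config.phase_shifts)
    eligible = [i for i, fi in enumerate(asv_family) if names[fi] not in truth_families]
    n_fallback = int(round(config.unassigned_fraction * len(asv_ids)))
    fallback = set(
        rng.choice(eligible, size=min(n_fallback, len(eligible)), replace=False).tolist()
    )
    assignments = []
    for i, aid in enumerate(asv_ids):
        fam = names[asv_family[i]]
        fnum = asv_family[i] + 1
        lineage = [
            ("domain", "Eukaryota" if fnum % 2 else "Bacteria"),
            ("phylum", f"Phylum_{(fnum - 1) // 5 + 1}"),
            ("class", f"Class_{(fnum - 1) // 2 + 1}"),
            ("order", f"Order_{fnum:02d}"),
        ]
        if i not in fallback:
            lineage.append(("family", fam.replace("family_", "Family_")))
        label_rank, label = lineage[-1]
        assignments.append(TaxonomyAssignment(aid, label, label_rank, tuple(lineage)))
    tax = TaxonomyMap(assignments)

    table = FeatureTable(asv_ids, list(core.layer_ids), counts)
    truth = TruthTable(
        links=tuple(
            PlantedLink(l.family.replace("family_", "Family_"), l.driver, l.r, l.sign)
            for l in config.planted_links
        ),
        joints=tuple(
            PlantedJoint(
                j.family.replace("family_", "Family_"), j.biocide, j.climate, j.w_bio, j.w_cli
            )
            for j in config.planted_joints
        ),
        phase_shift_families=tuple(
            f.replace("family_", "Family_") for f in config.phase_shifts
        ),
    )
    return core, table, tax, drivers, truth


def score_recovery(called, truth: TruthTable) -> RecoveryScore:
    """Precision/recall of called links (and joint records) vs the truth.

    A called link matches a planted one iff family, driver and sign all
    agree; a joint record matches a planted triple on (family, biocide,
    climate). Link recall is over the planted links; link precision
    additionally credits the individual links a planted joint effect
    implies (a joint family genuinely co-varies with each of its two
    drivers, with the weight's sign). Calls involving phase-shift
    families are excluded from the precision denominators: a family
    with a planted regime shift necessarily co-varies with any driver
    structured by the same era (biocide pulses and climate trends are
    era-structured by construction), so such calls are ambiguous
    rather than false. An empty call set gives recall 0 and precision
    reported as 1.0 with the ``*_defined`` flag cleared.
    """
    shifted = set(truth.phase_shift_families)
    links = [
        l
        for l in called
        if hasattr(l, "sign") and getattr(l, "passed", False) and l.family not in shifted
    ]
    joints = [
        r for r in called if getattr(r, "is_joint", False) and r.family not in shifted
    ]
    planted = {(l.family, l.driver, l.sign) for l in truth.links}
    implied = {
        (j.family, d, int(math.copysign(1, w)))
        for j in truth.joints
        for d, w in ((j.biocide, j.w_bio), (j.climate, j.w_cli))
    }
    called_set = {(l.family, l.driver, l.sign) for l in links}
    hits = planted & called_set
    recall = len(hits) / len(planted) if planted else 1.0
    if called_set:
        precision = len((planted | implied) & called_set) / len(called_set)
        precision_defined = True
    else:
        precision, precision_defined = 1.0, False
    planted_j = {(j.family, j.biocide, j.climate) for j in truth.joints}
    called_j = {(r.family, r.biocide, r.climate) for r in joints}
    hits_j = planted_j & called_j
    joint_recall = len(hits_j) / len(planted_j) if planted_j else 1.0
    if called_j:
        joint_precision = len(hits_j) / len(called_j)
        jp_defined = True
    else:
        joint_precision, jp_defined = 1.0, False
    return RecoveryScore(
        precision=precision,
        recall=recall,
        joint_precision=joint_precision,
        joint_recall=joint_recall,
        precision_defined=precision_defined,
        joint_precision_defined=jp_defined,
    )
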