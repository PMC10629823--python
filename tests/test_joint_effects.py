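import numpy as np
import pandas as pd
import pytest

from sedadrivers.community_ops import FamilyTable, zscore_series
from sedadrivers.io_formats import AbioticSeries, SedimentCore, align_layers_to_drivers
from sedadrivers.joint_effects import (
    JointEffectRecord,
    combined_significance,
    detect_joint_effects,
    joint_frequency_matrix,
    joint_test,
    rank_chemicals,
)
from sedadrivers.window_corr import FamilyDriverLink, SwcConfig, WindowStat, pearson


CFG = SwcConfig(n_permutations=499, seed=0)


def test_joint_test_additive_family_beats_individuals():
    rng = np.random.default_rng(0)
    bio = rng.normal(size=24)
    cli = rng.normal(size=24)
    fam = zscore_series(bio) + zscore_series(cli) + 0.1 * rng.normal(size=24)
    r_joint, p = joint_test(fam, bio, cli, CFG)
    r_bio = pearson(fam, bio)
    r_cli = pearson(fam, cli)
    assert abs(r_joint) > max(abs(r_bio), abs(r_cli))
    assert abs(r_bio) == pytest.approx(1 / np.sqrt(2), abs=0.15)
    assert p < 0.05


def test_joint_test_single_driver_family_no_improvement():
    rng = np.random.default_rng(1)
    bio = rng.normal(size=20)
    cli = rng.normal(size=20)
    fam = bio.copy()  # exactly the biocide
    r_joint, _p = joint_test(fam, bio, cli, CFG)
    assert abs(pearson(fam, bio)) == pytest.approx(1.0)
    assert abs(r_joint) <= 1.0  # cannot strictly exceed the exact driver


def test_joint_test_duplicated_driver_degenerate():
    rng = np.random.default_rng(2)
    bio = rng.normal(size=20)
    fam = 0.8 * bio + 0.2 * rng.normal(size=20)
    r_joint, _p = joint_test(fam, bio, bio.copy(), CFG)
    assert r_joint == pytest.approx(pearson(fam, bio), abs=1e-12)


def test_joint_test_short_window_errors():
    with pytest.raises(ValueError):
        joint_test([1.0, 2.0], [1.0, 2.0], [2.0, 1.0], CFG)


# ---------------------------------------------------------- end-to-end joint


def _joint_world(seed=0, plant=True):
    """One biocide (recorded late) + one climate driver + 3 families."""
    rng = np.random.default_rng(seed)
    n = 30
    mids = tuple(1940.0 + 2.0 * i for i in range(n))
    core = SedimentCore(
        layer_ids=tuple(f"L{i:02d}" for i in range(n)),
        depth_top_cm=tuple(float(n - 1 - i) for i in range(n)),
        depth_bottom_cm=tuple(float(n - i) for i in range(n)),
        year_mid=mids,
        phase=("E",) * n,
    )
    bio = AbioticSeries(
        name="ddt", clazz="biocide", biocide_type="insecticide",
        years=tuple(range(1955, 2000)),
        values=tuple(np.abs(rng.normal(5, 2, size=45))),
    )
    cli = AbioticSeries(
        name="temp", clazz="climate",
        years=tuple(range(1939, 2000)),
        values=tuple(rng.normal(size=61)),
    )
    aligned = align_layers_to_drivers(core, [bio, cli])
    li = {l: i for i, l in enumerate(aligned.layer_ids)}

    def layer_signal(name):
        layers, y = aligned.driver_axis(name)
        out = np.zeros(len(aligned.layer_ids))
        v = (y - y.mean()) / y.std(ddof=1)
        for l, val in zip(layers, v):
            out[li[l]] = val
        return out

    zb, zc = layer_signal("ddt"), layer_signal("temp")
    base = 0.3 + 0.03 * rng.normal(size=len(aligned.layer_ids))
    famj = np.clip(base + (0.08 * (zb + zc) if plant else 0.0), 0.01, None)
    famb = np.clip(base + 0.08 * zb, 0.01, None)
    famn = np.clip(0.3 + 0.03 * rng.normal(size=len(aligned.layer_ids)), 0.01, None)
    vals = np.vstack([famj, famb, famn])
    fam = FamilyTable(
        ["J", "Bonly", "Null"], list(aligned.layer_ids), vals,
        {"J": ["j1"], "Bonly": ["b1"], "Null": ["n1"]},
    )

    def link(family, driver, clazz):
        layers, y = aligned.driver_axis(driver)
        idx = [li[l] for l in layers]
        x = fam.row(family)[idx]
        r = pearson(x, y)
        ws = WindowStat(driver=driver, unit=family, start=0, length=len(layers), r=r, p_raw=0.001, p_adj=0.01)
        return FamilyDriverLink(
            family=family, driver=driver, driver_class=clazz, window=ws,
            sign=1 if r >= 0 else -1, recall=1.0,
            pass_r=abs(r) > 0.5, pass_padj=True, pass_recall=True,
        )

    links_bio = [link(f, "ddt", "biocide") for f in fam.labels]
    links_cli = [link(f, "temp", "climate") for f in fam.labels]
    return fam, aligned, links_bio, links_cli


def test_combined_significance_finds_additive_family():
    fam, aligned, lb, lc = _joint_world(seed=3, plant=True)
    cands = combined_significance(lb, lc, fam, aligned, CFG)
    assert any(c.family == "J" for c in cands)
    for c in cands:
        assert c.mean_abs_r > CFG.r_threshold
        assert len(c.layers) >= CFG.min_window


def test_detect_joint_effects_calls_additive_not_single_driver():
    fam, aligned, lb, lc = _joint_world(seed=3, plant=True)
    cands = combined_significance(lb, lc, fam, aligned, CFG)
    records = detect_joint_effects(cands, fam, aligned, CFG)
    by_family = {r.family: r for r in records}
    assert by_family["J"].is_joint
    assert by_family["J"].r_joint == pytest.approx(
        max(abs(by_family["J"].r_bio), abs(by_family["J"].r_cli)), abs=0.5
    )
    if "Bonly" in by_family:
        rec = by_family["Bonly"]
        assert abs(rec.r_joint) <= abs(rec.r_bio) + 1e-9 or not rec.is_joint


def test_joint_invariants():
    fam, aligned, lb, lc = _joint_world(seed=4, plant=True)
    records = detect_joint_effects(
        combined_significance(lb, lc, fam, aligned, CFG), fam, aligned, CFG
    )
    for r in records:
        if r.is_joint:
            assert r.combined_significant
            assert abs(r.r_joint) > max(abs(r.r_bio), abs(r.r_cli))
            assert r.p_adj_joint < CFG.alpha


# ----------------------------------------------------------------- chemicals


def _chem_link(chem, r, passed=True):
    ws = WindowStat(driver=chem, unit="fam", start=0, length=10, r=r, p_raw=0.001, p_adj=0.01)
    return FamilyDriverLink(
        family="fam", driver=chem, driver_class="biocide", window=ws,
        sign=1 if r >= 0 else -1, recall=1.0,
        pass_r=passed, pass_padj=passed, pass_recall=passed,
    )


def test_rank_chemicals_discards_sparse_and_weak():
    links = [_chem_link("dicofol", -0.9), _chem_link("parathion", -0.7), _chem_link("sparse", -0.95), _chem_link("weak", -0.45)]
    types = {c: "insecticide" for c in ("dicofol", "parathion", "sparse", "weak")}
    nulls = {"dicofol": 0.1, "parathion": 0.2, "sparse": 0.6, "weak": 0.0}
    ranked = rank_chemicals(links, nulls, types, CFG)
    assert [c for c, _ in ranked["insecticide"]] == ["dicofol", "parathion"]


def test_rank_chemicals_tie_alphabetical():
    links = [_chem_link("zeta", 0.8), _chem_link("alpha", 0.8)]
    ranked = rank_chemicals(links, {}, {"zeta": "fungicide", "alpha": "fungicide"}, CFG)
    assert [c for c, _ in ranked["fungicide"]] == ["alpha", "zeta"]


# ----------------------------------------------------------- frequency matrix


def _record(family, bio, cli, is_joint=True):
    return JointEffectRecord(
        family=family, biocide=bio, climate=cli, n_points=6,
        year_start=1960, year_end=1980, r_bio=-0.6, r_cli=-0.6, mean_r=0.6,
        r_joint=-0.8, p_adj_joint=0.01, combined_significant=True, is_joint=is_joint,
    )


BTYPES = {"ddt": "insecticide", "captan": "fungicide"}


def test_frequency_matrix_empty():
    m = joint_frequency_matrix([], BTYPES)
    assert (m.to_numpy() == 0).all()


def test_frequency_matrix_counts_families():
    recs = [
        _record("f1", "ddt", "min_temp"),
        _record("f2", "ddt", "min_temp"),
        _record("f3", "ddt", "min_temp"),
        _record("f4", "captan", "precip"),
        _record("f5", "ddt", "precip", is_joint=False),
    ]
    m = joint_frequency_matrix(recs, BTYPES)
    assert m.loc["insecticide", "min_temp"] == 3
    assert m.loc["fungicide", "precip"] == 1
    assert m.loc["insecticide", "precip"] == 0


def test_frequency_matrix_marginals_consistent():
    recs = [_record(f"f{i}", "ddt", "min_temp") for i in range(3)] + [
        _record("g1", "captan", "precip")
    ]
    m = joint_frequency_matrix(recs, BTYPES)
    assert m.sum().sum() == 4
    assert m.sum(axis=1)["insecticide"] == 3


def test_frequency_matrix_domain_filter():
    recs = [_record("euk1", "ddt", "min_temp"), _record("prok1", "ddt", "min_temp")]
    domains = {"euk1": "eukaryote", "prok1": "prokaryote"}
    m = joint_frequency_matrix(recs, BTYPES, family_domains=domains, domain="eukaryote")
    assert m.loc["insecticide", "min_temp"] == 1
    with pytest.raises(ValueError):
        joint_frequency_matrix(recs, BTYPES, domain="eukaryote")
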