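import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sedadrivers.community_ops import FamilyTable
from sedadrivers.io_formats import AbioticSeries, SedimentCore, align_layers_to_drivers
from sedadrivers.window_corr import (
    SwcConfig,
    best_window,
    call_family_links,
    enumerate_windows,
    pearson,
    perm_pvalue,
    recall_rate,
    scan_pvalue,
    swc_scan,
    _scan_evidence,
    _window_log_p,
)


# ------------------------------------------------------------------- windows


@pytest.mark.parametrize("T,min_len,expected", [(6, 5, 3), (5, 5, 1), (8, 5, 10)])
def test_enumerate_window_counts(T, min_len, expected):
    wins = enumerate_windows(T, min_len)
    assert len(wins) == expected
    assert len(wins) == sum(T - w + 1 for w in range(min_len, T + 1))


def test_enumerate_windows_too_short_errors():
    with pytest.raises(ValueError):
        enumerate_windows(4, 5)


# ------------------------------------------------------------------- pearson


def test_pearson_perfect_and_inverse():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson(x, 2 * x) == pytest.approx(1.0)
    assert pearson(x, x[::-1]) == pytest.approx(-1.0)


def test_pearson_hand_computed():
    assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)


def test_pearson_constant_errors():
    with pytest.raises(ValueError, match="constant"):
        pearson([1, 1, 1], [1, 2, 3])


# --------------------------------------------------------------- permutation


def test_perm_pvalue_exhaustive_n3_monotone():
    # 6 permutations; identity and reversal attain |r| = 1
    assert perm_pvalue([1, 2, 3], [10, 20, 30], B=999) == pytest.approx(2 / 6)


def test_perm_pvalue_exhaustive_equals_brute_force():
    rng = np.random.default_rng(0)
    x = rng.normal(size=5)
    y = rng.normal(size=5)
    p = perm_pvalue(x, y, B=999)
    r_obs = abs(pearson(x, y))
    hits = sum(
        abs(pearson(x, np.array(perm))) >= r_obs - 1e-12
        for perm in itertools.permutations(y)
    )
    assert p == pytest.approx(hits / math.factorial(5))


def test_perm_pvalue_monte_carlo_floor():
    rng = np.random.default_rng(1)
    x = np.arange(12.0)
    y = x + rng.normal(0, 0.01, 12)
    p = perm_pvalue(x, y, B=199, seed=0)
    assert p >= 1 / 200


def test_perm_pvalue_null_calibration():
    rng = np.random.default_rng(2)
    n_reps, B, alpha = 400, 199, 0.05
    rejections = 0
    for i in range(n_reps):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rejections += perm_pvalue(x, y, B=B, seed=i) <= alpha
    rate = rejections / n_reps
    assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_reps)


# ------------------------------------------------------------------ best window


def _brute_force_max_r(x, y, min_len):
    best = None
    for s, w in enumerate_windows(len(x), min_len):
        xs, ys = x[s : s + w], y[s : s + w]
        if xs.std() == 0 or ys.std() == 0:
            continue
        if (xs == 0).mean() > 0.5 or (ys == 0).mean() > 0.5:
            continue
        r = pearson(xs, ys)
        key = (abs(r), w, -s)
        if best is None or key > best[0]:
            best = (key, (s, w, r))
    return None if best is None else best[1]


def _brute_force_evidence(x, y, min_len):
    best = None
    T = len(x)
    for s, w in enumerate_windows(T, min_len):
        xs, ys = x[s : s + w], y[s : s + w]
        if xs.std() == 0 or ys.std() == 0:
            continue
        if (xs == 0).mean() > 0.5 or (ys == 0).mean() > 0.5:
            continue
        r = pearson(xs, ys)
        stat = (
            -_window_log_p(np.array([abs(r)]), np.array([w]))[0]
            - math.log(T - w + 1)
            + (w - T) * math.log(2.0)
        )
        key = (stat, w, -s)
        if best is None or key > best[0]:
            best = (key, (s, w, r))
    return None if best is None else (best[0][0], best[1])


@pytest.mark.parametrize("seed", range(6))
def test_best_window_matches_brute_force_oracles(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=8)
    y = rng.normal(size=8)
    got = best_window(x, y, 5, criterion="max_r")
    want = _brute_force_max_r(x, y, 5)
    assert got[:2] == want[:2] and got[2] == pytest.approx(want[2], abs=1e-12)
    stat, win = _brute_force_evidence(x, y, 5)
    got_stat, got_win = _scan_evidence(x, y, 5)
    assert got_stat == pytest.approx(stat)
    assert got_win[:2] == win[:2] and got_win[2] == pytest.approx(win[2], abs=1e-12)


def test_scan_pvalue_floor_and_signal():
    rng = np.random.default_rng(3)
    x = np.linspace(0, 1, 20) + rng.normal(0, 0.05, 20)
    y = np.linspace(0, 2, 20) + rng.normal(0, 0.05, 20)
    p = scan_pvalue(x, y, 5, B=199, seed=0)
    assert p == pytest.approx(1 / 200)
    # independent noise: p not extreme
    p_null = scan_pvalue(rng.normal(size=20), rng.normal(size=20), 5, B=199, seed=1)
    assert p_null > 0.01


# ---------------------------------------------------------------------- scan


def test_swc_scan_recovers_planted_signal():
    rng = np.random.default_rng(4)
    y = rng.normal(size=30)
    x = 0.9 * y + 0.2 * rng.normal(size=30)
    stat = swc_scan(x, y, SwcConfig(n_permutations=199, seed=0))
    assert stat is not None
    assert abs(stat.r) > 0.5
    assert stat.p_raw <= 0.01


def test_swc_scan_all_zero_driver_not_testable():
    rng = np.random.default_rng(5)
    x = rng.normal(size=10)
    assert swc_scan(x, np.zeros(10), SwcConfig(n_permutations=199, seed=0)) is None


def test_swc_scan_invariant_to_joint_time_reversal():
    rng = np.random.default_rng(6)
    x = rng.normal(size=14)
    y = rng.normal(size=14) + 0.5 * x
    cfg = SwcConfig(n_permutations=199, seed=0)
    a = swc_scan(x, y, cfg)
    b = swc_scan(x[::-1].copy(), y[::-1].copy(), cfg)
    assert abs(a.r) == pytest.approx(abs(b.r))
    assert a.length == b.length
    assert b.start == len(x) - a.start - a.length  # mirrored position


def test_config_validation():
    with pytest.raises(ValueError):
        SwcConfig(min_window=2)
    with pytest.raises(ValueError):
        SwcConfig(n_permutations=10)
    with pytest.raises(ValueError):
        SwcConfig(r_threshold=1.5)


# -------------------------------------------------------------- link calling


def _toy_setup(seed=0, n_layers=24, plant=True):
    """Small aligned world: one driver, two families with 2 ASVs each."""
    rng = np.random.default_rng(seed)
    mids = tuple(1950.0 + 2.0 * i for i in range(n_layers))
    core = SedimentCore(
        layer_ids=tuple(f"L{i:02d}" for i in range(n_layers)),
        depth_top_cm=tuple(float(n_layers - 1 - i) for i in range(n_layers)),
        depth_bottom_cm=tuple(float(n_layers - i) for i in range(n_layers)),
        year_mid=mids,
        phase=("E",) * n_layers,
    )
    years = range(1949, 1999)
    driver = AbioticSeries(
        name="temp", clazz="climate",
        years=tuple(years), values=tuple(rng.normal(size=len(list(years)))),
    )
    aligned = align_layers_to_drivers(core, [driver])
    layers, y = aligned.driver_axis("temp")
    signal = np.zeros(n_layers)
    li = {l: i for i, l in enumerate(aligned.layer_ids)}
    for l, v in zip(layers, y):
        signal[li[l]] = v
    base = 0.25 + 0.05 * rng.normal(size=n_layers)
    fam_a = np.clip(base + (0.12 * signal if plant else 0.0), 0.01, None)
    fam_b = np.clip(0.5 - fam_a + 0.05 * rng.normal(size=n_layers), 0.01, None)
    values = np.vstack([fam_a, fam_b])
    values = values / values.sum(axis=0) * 1.0
    fam = FamilyTable(
        ["A", "B"], list(aligned.layer_ids), values,
        {"A": ["a1", "a2"], "B": ["b1", "b2"]},
    )
    asv = pd.DataFrame(
        np.vstack([fam_a / 2, fam_a / 2, fam_b / 2, fam_b / 2]),
        index=["a1", "a2", "b1", "b2"],
        columns=list(aligned.layer_ids),
    )
    return fam, asv, aligned


def test_call_family_links_deterministic():
    fam, asv, aligned = _toy_setup()
    cfg = SwcConfig(n_permutations=199, seed=42)
    r1 = call_family_links(fam, asv, aligned, cfg)
    r2 = call_family_links(fam, asv, aligned, cfg)
    assert r1.links == r2.links
    assert r1.recall_q90 == r2.recall_q90


def test_mirrored_asvs_give_full_recall():
    fam, asv, aligned = _toy_setup(plant=True)
    cfg = SwcConfig(n_permutations=499, seed=1)
    res = call_family_links(fam, asv, aligned, cfg)
    link_a = next(l for l in res.links if l.family == "A")
    if link_a.pass_r and link_a.pass_padj:
        # ASVs exactly mirror the family signal
        assert link_a.recall == 1.0


def test_links_carry_sign_and_flags():
    fam, asv, aligned = _toy_setup(plant=True)
    res = call_family_links(fam, asv, aligned, SwcConfig(n_permutations=199, seed=2))
    for l in res.links:
        assert l.sign in (-1, 1)
        assert l.passed == (l.pass_r and l.pass_padj and l.pass_recall)
        assert -1 <= l.window.r <= 1


# -------------------------------------------------------------------- recall


def test_recall_rate_arithmetic():
    assert recall_rate("f", [True, True, True, False]) == 0.75
    assert recall_rate("f", [False] * 5) == 0.0


def test_recall_rate_empty_family_errors():
    with pytest.raises(ValueError):
        recall_rate("f", [])
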