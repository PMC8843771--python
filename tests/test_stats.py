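from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from benthosom.stats import (benjamini_hochberg, compact_letters,
                             dunn_pairwise, kruskal_wallis, posthoc_letters,
                             spearman_screen)


# ------------------------------------------------------ Kruskal–Wallis

def test_kw_all_identical_values():
    res = kruskal_wallis([5.0] * 9, [1, 1, 1, 2, 2, 2, 3, 3, 3])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kw_matches_hand_rank_computation():
    values = np.array([3.1, 2.8, 4.0, 5.5, 5.1, 6.0, 1.0, 1.2, 0.8])
    groups = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
    res = kruskal_wallis(values, groups)
    ranks = sps.rankdata(values)
    n = len(values)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[groups == g].sum() ** 2 / (groups == g).sum()
        for g in (1, 2, 3)) - 3 * (n + 1)
    # no ties here, so no correction term
    assert res.statistic == pytest.approx(h, abs=1e-10)
    assert res.p_value == pytest.approx(sps.chi2.sf(h, 2), abs=1e-12)


def test_kw_invariant_to_monotone_transform():
    rng = np.random.default_rng(0)
    values = rng.normal(size=12)
    groups = np.repeat([1, 2, 3], 4)
    a = kruskal_wallis(values, groups).statistic
    b = kruskal_wallis(np.exp(values), groups).statistic
    assert a == pytest.approx(b, abs=1e-12)


def test_kw_chi2_p_bracketed_by_exhaustive_permutation():
    values = np.array([1.0, 2.0, 6.0, 7.0, 3.5, 9.0])
    groups = np.array([1, 1, 2, 2, 3, 3])
    obs = kruskal_wallis(values, groups).statistic
    hits = total = 0
    for perm in set(permutations(groups)):
        h = kruskal_wallis(values, np.array(perm)).statistic
        hits += h >= obs - 1e-12
        total += 1
    exact = hits / total
    approx = kruskal_wallis(values, groups).p_value
    # at n = 6 the chi-square reference is coarse; it should still land in
    # the same neighbourhood as the exact permutation tail
    assert abs(approx - exact) < 0.2


# ------------------------------------------------------------- Dunn

def test_separated_groups_get_distinct_letters():
    values = np.array([1.0, 1.1, 0.9, 1.2, 9.0, 9.1, 8.9, 9.2] * 2)
    groups = np.array(["lo"] * 4 + ["hi"] * 4 + ["lo"] * 4 + ["hi"] * 4)
    letters = posthoc_letters(values, groups, warn_omnibus=False)
    assert set(letters["lo"]) & set(letters["hi"]) == set()


def test_identical_groups_share_a_letter():
    rng = np.random.default_rng(1)
    values = rng.normal(size=15)
    groups = np.repeat(["a", "b", "c"], 5)
    letters = posthoc_letters(values, groups, warn_omnibus=False)
    assert len({v for v in letters.values()}) == 1


def test_outlier_group_gets_unique_letter_and_z_matches_oracle():
    values = np.array([1.0, 1.2, 1.1, 0.9, 1.3, 1.05, 1.15, 0.95,
                       20.0, 21.0, 19.5, 20.5])
    groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    pw = dunn_pairwise(values, groups)
    # brute-force Dunn z for the (a, c) pair: no ties in these data
    ranks = sps.rankdata(values)
    n = len(values)
    se = np.sqrt(n * (n + 1) / 12.0 * (1 / 4 + 1 / 4))
    z_ac = (ranks[groups == "a"].mean() - ranks[groups == "c"].mean()) / se
    row = pw[(pw.group_a == "a") & (pw.group_b == "c")].iloc[0]
    assert row["z"] == pytest.approx(z_ac, abs=1e-10)
    letters = posthoc_letters(values, groups, warn_omnibus=False)
    assert set(letters["c"]) & (set(letters["a"]) | set(letters["b"])) == set()
    assert set(letters["a"]) & set(letters["b"])


def test_compact_letters_share_iff_not_significant():
    pw = pd.DataFrame([
        {"group_a": 1, "group_b": 2, "p_adj": 0.80},
        {"group_a": 1, "group_b": 3, "p_adj": 0.01},
        {"group_a": 2, "group_b": 3, "p_adj": 0.90},
    ])
    letters = compact_letters(pw, [1, 2, 3])
    assert set(letters[1]) & set(letters[2])
    assert not set(letters[1]) & set(letters[3])
    assert set(letters[2]) & set(letters[3])


# --------------------------------------------------------------- BH

def test_bh_step_up_by_hand():
    out = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_bh_edge_cases():
    assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)
    assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        benjamini_hochberg([1.5])


def test_bh_monotone_and_order_preserving():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=20)
    once = benjamini_hochberg(p)
    order = np.argsort(p)
    assert (np.diff(once[order]) >= -1e-12).all()
    assert (once >= p - 1e-12).all()


def test_bh_null_discovery_rate_controlled():
    rng = np.random.default_rng(3)
    reps, m = 300, 20
    false_any = 0
    for _ in range(reps):
        p = rng.uniform(size=m)
        false_any += (benjamini_hochberg(p) < 0.05).any()
    rate = false_any / reps
    assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


# ---------------------------------------------------------- Spearman

def _screen(a, b):
    idx = pd.DataFrame({"ind": a}, index=range(len(a)))
    env = pd.DataFrame({"var": b}, index=range(len(b)))
    return spearman_screen(idx, env).iloc[0]


def test_spearman_monotone_pairs():
    assert _screen([1, 2, 3, 4, 5], [2, 4, 8, 16, 32])["rho"] == pytest.approx(1.0)
    assert _screen([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])["rho"] == pytest.approx(-1.0)


def test_spearman_worked_example():
    # d² sums to 8: rho = 1 - 6*8 / (5*24) = 0.6
    row = _screen([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
    assert row["rho"] == pytest.approx(0.6, abs=1e-12)
    t = 0.6 * np.sqrt(3 / (1 - 0.36))
    assert row["p"] == pytest.approx(2 * sps.t.sf(t, 3), abs=1e-10)


def test_spearman_zero_variance_flagged_undefined():
    row = _screen([1.0, 1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4, 5])
    assert row["undefined"]
    assert np.isnan(row["rho"])


def test_spearman_grid_shape_and_within_index_adjustment():
    rng = np.random.default_rng(4)
    idx = pd.DataFrame(rng.normal(size=(30, 5)),
                       columns=["richness", "abundance", "biomass",
                                "shannon", "pielou"])
    env = pd.DataFrame(rng.normal(size=(30, 13)),
                       columns=[f"v{i}" for i in range(13)])
    out = spearman_screen(idx, env)
    assert len(out) == 65
    for ind in out["index"].unique():
        sub = out[out["index"] == ind]
        assert np.allclose(sub["p_adj"],
                           benjamini_hochberg(sub["p"].to_numpy()), atol=1e-12)
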