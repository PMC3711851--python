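"""Tiling ChIP preprocessing, per-promoter tests, FDR and bound calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import wilcoxon

from heatshock import (
    SimChipParams,
    call_bound,
    gen_chip,
    promoter_score,
    quantile_normalize,
    subtract_background,
)
from heatshock import test_enhancement as enhancement_p
from heatshock import test_nonuniformity as nonuniformity_p
from heatshock.chip import ChipSignalSet, PromoterMap


# ---------------------------------------------------------------------------
# quantile normalization


def test_quantile_normalize_mean_of_order_statistics():
    m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    out = quantile_normalize(m)
    assert np.allclose(out["a"], [2.5, 3.5, 4.5])
    assert np.allclose(out["b"], [2.5, 3.5, 4.5])


def test_quantile_normalize_identical_columns_fixed_point():
    m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
    out = quantile_normalize(m)
    assert np.allclose(out, m)


def test_quantile_normalize_ties_get_mean_of_targets():
    """Hand-computed 3-probe case: reference is [1.5, 2.5, 4.5]; the tied
    pair in column a spans ranks 1-2 and receives their mean, 2.0."""
    m = pd.DataFrame({"a": [1.0, 1.0, 3.0], "b": [2.0, 4.0, 6.0]})
    out = quantile_normalize(m)
    assert np.allclose(out["a"], [2.0, 2.0, 4.5])
    assert np.allclose(out["b"], [1.5, 2.5, 4.5])


def test_quantile_normalize_columns_share_multiset():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.lognormal(3, 0.4, size=(200, 4)))
    out = quantile_normalize(m)
    ref = np.sort(out.iloc[:, 0].to_numpy())
    for j in range(1, 4):
        assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)


def test_quantile_normalize_needs_two_arrays():
    with pytest.raises(ValueError):
        quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


# ---------------------------------------------------------------------------
# background subtraction


def test_background_constant_vector_zeroes():
    assert np.allclose(subtract_background(np.full(10, 7.0)), 0.0)


def test_background_integer_ramp():
    vals = np.arange(1.0, 101.0)
    out = subtract_background(vals, 5)
    assert np.allclose(out, np.maximum(vals - np.percentile(vals, 5), 0.0))
    assert (out == 0).mean() >= 0.05


def test_background_pct_zero_noop_at_min_zero():
    vals = np.array([0.0, 1.0, 5.0])
    assert np.allclose(subtract_background(vals, 0), vals)


def test_background_empty_rejected():
    with pytest.raises(ValueError):
        subtract_background(np.array([]))


# ---------------------------------------------------------------------------
# promoter score


def _toy_signals(diffs):
    probes = pd.Index([f"p{i}" for i in range(len(diffs))], name="probe_id")
    ab0 = pd.DataFrame({"AB0_r1": np.full(len(diffs), 10.0)}, index=probes)
    ab1 = pd.DataFrame({"AB1_r1": 10.0 + np.asarray(diffs, float)}, index=probes)
    table = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.arange(len(diffs)) * 35,
            "end": np.arange(len(diffs)) * 35 + 25,
            "probe_id": probes,
            "promoter_id": "prom",
            "strand": "+",
        }
    )
    return ChipSignalSet(ab1=ab1, ab0=ab0), PromoterMap(table=table)


def test_promoter_score_is_mean_of_differences():
    signals, pmap = _toy_signals([10.0, 20.0, 30.0])
    score, diffs = promoter_score(pmap, signals, "prom")
    assert score == 20.0
    assert np.allclose(diffs, [10, 20, 30])


def test_promoter_score_zero_when_channels_equal():
    signals, pmap = _toy_signals([0.0, 0.0, 0.0])
    assert promoter_score(pmap, signals, "prom")[0] == 0.0


def test_unknown_promoter_lookup_error():
    signals, pmap = _toy_signals([1.0, 2.0, 3.0])
    with pytest.raises(KeyError, match="nope"):
        promoter_score(pmap, signals, "nope")


def test_score_matches_kernel_expectation():
    """Planted amplitude 100, peak sd 2, 15 probes: the mean score over
    200 promoters is within 25% of amplitude x (kernel mass / n_probes)."""
    params = SimChipParams(
        n_promoters=200, probes_per_promoter=(15, 15), peak_sd=2.0,
        amplitude=(100.0, 100.0), frac_bound=1.0, seed=5,
    )
    signals, pmap, truth = gen_chip(params)
    scores = [promoter_score(pmap, signals, p)[0] for p in pmap.promoters]
    kernel_mass = np.sqrt(2 * np.pi) * 2.0  # interior peak, light truncation
    expected = 100.0 * kernel_mass / 15.0
    assert abs(np.mean(scores) - expected) <= 0.25 * expected


# ---------------------------------------------------------------------------
# enhancement test


def test_enhancement_all_positive_exact():
    assert enhancement_p(np.full(10, 2.0)) == pytest.approx(2.0**-10)


def test_enhancement_single_positive_probe():
    assert enhancement_p([3.0]) == pytest.approx(0.5)


def test_enhancement_antisymmetric_near_half():
    p = enhancement_p([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
    assert 0.3 <= p <= 0.7


def test_enhancement_all_zero_returns_one():
    assert enhancement_p([0.0, 0.0, 0.0]) == 1.0


def test_enhancement_matches_scipy_exact():
    """No-tie random differences: the DP null equals scipy's exact
    signed-rank tail."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        d = rng.normal(0.5, 1.0, size=rng.integers(5, 20))
        expected = wilcoxon(d, alternative="greater", method="exact").pvalue
        assert enhancement_p(d) == pytest.approx(expected, rel=1e-10)


def test_enhancement_normal_approximation_beyond_25():
    rng = np.random.default_rng(2)
    d = rng.normal(0.3, 1.0, 40)
    expected = wilcoxon(
        d, alternative="greater", method="approx", correction=True
    ).pvalue
    assert enhancement_p(d) == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------------------
# nonuniformity test


def test_nonuniformity_constant_profile_p_one():
    assert nonuniformity_p(np.full(20, 4.0), window=5, b=199, seed=0) == 1.0


def test_nonuniformity_detects_sharp_peak():
    """Five +50 probes among twenty zeros: the observed window ties or
    beats every permutation, so p sits at the permutation floor except
    for the rare shuffles that reassemble the peak (adjacency probability
    21/C(25,5) ~ 4e-4 per permutation)."""
    diffs = np.zeros(25)
    diffs[10:15] = 50.0
    ps = [nonuniformity_p(diffs, window=5, b=999, seed=seed) for seed in range(20)]
    assert sum(p == pytest.approx(1 / 1000) for p in ps) >= 8
    assert max(ps) <= 5 / 1000


def test_nonuniformity_p_bounds():
    rng = np.random.default_rng(3)
    for b in (19, 99):
        for _ in range(5):
            d = rng.normal(size=12)
            p = nonuniformity_p(d, window=5, b=b, seed=1)
            assert 1 / (b + 1) <= p <= 1.0


def test_nonuniformity_short_region_p_one():
    assert nonuniformity_p([1.0, 2.0], window=5, b=99, seed=0) == 1.0


def test_nonuniformity_needs_positive_b():
    with pytest.raises(ValueError):
        nonuniformity_p(np.ones(10), b=0)


# ---------------------------------------------------------------------------
# BH and bound calls


def _bh_bruteforce(p):
    """Step-up definition, implemented literally."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = running
    return q


def test_bh_hand_example():
    df = pd.DataFrame({"score": [20.0] * 4, "p_comb": [0.01, 0.02, 0.03, 0.04]})
    out = call_bound(df)
    assert np.allclose(out["q"], 0.04)
    assert out["bound"].all()


def test_bh_matches_bruteforce_on_random_vectors():
    rng = np.random.default_rng(4)
    from statsmodels.stats.multitest import multipletests

    for _ in range(1000):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(multipletests(p, method="fdr_bh")[1], _bh_bruteforce(p))


def test_score_threshold_gates_bound():
    df = pd.DataFrame(
        {"score": [14.9, 15.0], "p_comb": [0.0001, 0.0001]}
    )
    out = call_bound(df, score_min=15.0, q_max=0.05)
    assert not bool(out.loc[0, "bound"])
    assert bool(out.loc[1, "bound"])


def test_all_p_one_no_bound():
    df = pd.DataFrame({"score": [100.0] * 5, "p_comb": [1.0] * 5})
    assert not call_bound(df)["bound"].any()


# ---------------------------------------------------------------------------
# generator + caller integration


def test_null_generator_scores_centred_at_zero():
    params = SimChipParams(n_promoters=60, frac_bound=0.0, seed=9)
    signals, pmap, _ = gen_chip(params)
    scores = np.array([promoter_score(pmap, signals, p)[0] for p in pmap.promoters])
    assert abs(scores.mean()) < 0.5
    assert (np.abs(scores) < 5).all()


def test_generator_determinism():
    params = SimChipParams(n_promoters=20, seed=3)
    a = gen_chip(params)
    b = gen_chip(params)
    assert a[0].ab1.equals(b[0].ab1)
    assert a[0].ab0.equals(b[0].ab0)
    assert a[1].table.equals(b[1].table)
    assert a[2].promoters.equals(b[2].promoters)
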