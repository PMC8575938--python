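import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from headful import (
    CoverageTrack,
    GenomeLayout,
    JunctionCounts,
    cotransduction_frequency,
    ddct,
    detect_lt_region,
    estimate_processivity,
    fisher_timepoints,
    integration_percentage,
    relative_coverage,
    segment_staircase,
    transduction_units,
)
from headful.estimators import StaircaseFit, piecewise_constant_dp


# ---------------------------------------------------------------------------
# integration percentage
# ---------------------------------------------------------------------------

class TestIntegrationPercentage:
    @pytest.mark.parametrize("attl,attb,expected", [
        (50, 50, 50.0),
        (0, 120, 0.0),
        (120, 0, 100.0),
        (3, 1, 75.0),
    ])
    def test_values(self, attl, attb, expected):
        assert integration_percentage(JunctionCounts(0, attl, attb)) == expected

    def test_zero_total_is_an_error_not_zero(self):
        with pytest.raises(ValueError):
            integration_percentage(JunctionCounts(0, 0, 0))


# ---------------------------------------------------------------------------
# Fisher exact test vs. full hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by brute-force enumeration of all tables with the
    observed margins, summing those no more probable than the observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_p(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = table_p(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_p(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_identical_rows_give_p_one(self):
        p = fisher_timepoints(JunctionCounts(0, 10, 5), JunctionCounts(30, 10, 5))
        assert p == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        # [[10,0],[0,10]]: only the two extreme tables are as improbable
        p = fisher_timepoints(JunctionCounts(0, 10, 0), JunctionCounts(30, 0, 10))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_enumeration_for_all_small_margin_tables(self):
        """Oracle equivalence over every 2x2 table with row sums <= 12."""
        for a, b, c, d in itertools.product(range(13), repeat=4):
            if a + b > 12 or c + d > 12:
                continue
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p_pkg = fisher_timepoints(JunctionCounts(0, a, b), JunctionCounts(1, c, d))
            p_ref = fisher_enumeration(a, b, c, d)
            assert p_pkg == pytest.approx(p_ref, rel=1e-7), (a, b, c, d)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_timepoints(JunctionCounts(0, 0, 0), JunctionCounts(1, 5, 5))
        with pytest.raises(ValueError):
            fisher_timepoints(JunctionCounts(0, 5, 0), JunctionCounts(1, 5, 0))


# ---------------------------------------------------------------------------
# relative coverage
# ---------------------------------------------------------------------------

class TestRelativeCoverage:
    def test_uniform_depth_is_one_everywhere(self):
        depth = np.full(50, 7.3)
        mask = np.zeros(50, bool)
        mask[10:20] = True
        assert np.allclose(relative_coverage(depth, mask), 1.0)

    def test_phage_amplification_scales(self):
        depth = np.ones(100)
        mask = np.zeros(100, bool)
        mask[:10] = True
        depth[:10] = 10.0
        rel = relative_coverage(depth, mask)
        assert np.allclose(rel[:10], 10.0)
        assert np.allclose(rel[10:], 1.0)

    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_unmasked_mean_is_exactly_one(self, vals):
        depth = np.asarray(vals)
        if depth.sum() == 0:
            return
        rel = relative_coverage(depth, np.zeros(len(depth), bool))
        assert np.mean(rel) == pytest.approx(1.0, rel=1e-9)

    def test_all_masked_is_error(self):
        with pytest.raises(ValueError):
            relative_coverage(np.ones(5), np.ones(5, bool))

    def test_zero_mean_is_error(self):
        with pytest.raises(ValueError):
            relative_coverage(np.zeros(5), np.zeros(5, bool))


# ---------------------------------------------------------------------------
# staircase DP: oracle equivalence and recovery on constructed input
# ---------------------------------------------------------------------------

def dp_exhaustive(y, penalty, min_len=1, max_cps=3):
    """Brute-force optimum over all changepoint subsets (up to max_cps)."""
    n = len(y)

    def sse(seg):
        return float(((seg - seg.mean()) ** 2).sum())

    best = (sse(y) + penalty, [])
    for k in range(1, max_cps + 1):
        for cps in itertools.combinations(range(min_len, n - min_len + 1), k):
            bounds = [0, *cps, n]
            if any(b - a < min_len for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            cost = sum(sse(y[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))
            cost += penalty * (k + 1)
            if cost < best[0] - 1e-12:
                best = (cost, list(cps))
    return best


class TestStaircaseDP:
    @pytest.mark.parametrize("seed", range(6))
    def test_dp_matches_exhaustive_search(self, seed):
        """The DP optimum equals exhaustive enumeration on short profiles."""
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 45)
        y = rng.normal(0, 1, n)
        # plant up to two true steps
        for cp, h in [(n // 3, 2.0), (2 * n // 3, -1.5)]:
            y[cp:] += h
        penalty = float(rng.uniform(1.0, 8.0))
        cps = piecewise_constant_dp(y, penalty, min_len=2)
        cost_ref, cps_ref = dp_exhaustive(y, penalty, min_len=2, max_cps=3)
        if len(cps) <= 3:
            assert cps == cps_ref
        # costs agree regardless of tie-breaking
        bounds = [0, *cps, len(y)]
        cost = sum(float(((y[a:b] - y[a:b].mean()) ** 2).sum())
                   for a, b in zip(bounds[:-1], bounds[1:])) + penalty * (len(cps) + 1)
        assert cost <= cost_ref + 1e-9

    def test_noise_free_staircase_recovered_exactly(self, p22):
        """Five 44 kb steps with heights 0.8^n: changepoints land exactly on
        the step boundaries."""
        L = p22.chromosome_length
        w = 100
        n_win = -(-L // w)
        vals = np.zeros(n_win)
        H = 44_000
        fd = np.asarray(p22.forward_distance(np.arange(0, L, w) + 50), dtype=float)
        for n in range(5):
            band = (fd >= n * H) & (fd < (n + 1) * H)
            vals[band] = 0.8 ** n
        from headful.induction_sim import phage_mask
        cov = CoverageTrack(vals, w, L, phage_mask(p22, w))
        fit = segment_staircase(cov, p22, span=6 * H)
        assert fit.n_steps == 5
        offs = np.asarray(p22.forward_distance(fit.changepoints), dtype=float)
        assert np.allclose(sorted(offs), [H, 2 * H, 3 * H, 4 * H, 5 * H], atol=w)
        assert estimate_processivity(fit) == pytest.approx(0.8, abs=1e-6)

    def test_min_step_guard(self, p22):
        from headful.induction_sim import phage_mask
        cov = CoverageTrack(np.ones(100), 100, p22.chromosome_length,
                            phage_mask(p22, 100))
        with pytest.raises(ValueError):
            segment_staircase(cov, p22, min_step=p22.headful_capacity)


class TestProcessivity:
    def test_exact_ratios(self):
        fit = StaircaseFit(np.array([1, 2]), np.array([1, 1]),
                           np.array([100.0, 80.0, 64.0]), 0.8, 3, 1.0, 100)
        assert estimate_processivity(fit) == pytest.approx(0.8)

    def test_flat_staircase(self):
        fit = StaircaseFit(np.array([1, 2]), np.array([1, 1]),
                           np.array([5.0, 5.0]), 1.0, 2, 1.0, 100)
        assert estimate_processivity(fit) == 1.0

    def test_single_step_undefined(self):
        fit = StaircaseFit(np.array([1]), np.array([1]),
                           np.array([5.0]), float("nan"), 1, 1.0, 100)
        with pytest.raises(ValueError):
            estimate_processivity(fit)


# ---------------------------------------------------------------------------
# LT-region detection on constructed coverage
# ---------------------------------------------------------------------------

class TestDetectLtRegion:
    def _track(self, p22, vals, w=100):
        from headful.induction_sim import phage_mask
        return CoverageTrack(vals, w, p22.chromosome_length, phage_mask(p22, w))

    def test_constructed_staircase_span(self, p22):
        L, w = p22.chromosome_length, 100
        vals = np.full(-(-L // w), 0.01)
        fd = np.asarray(p22.forward_distance(np.arange(0, L, w) + 50), dtype=float)
        span_true = 13 * 44_000 - p22.pac_to_attR
        vals[fd < span_true] = 5.0
        region = detect_lt_region(self._track(p22, vals), p22, threshold=5)
        assert region.span == pytest.approx(span_true, rel=0.02)
        assert region.lt_read_fraction > 0.95

    def test_flat_background_gives_empty_region(self, p22):
        rng = np.random.default_rng(0)
        L, w = p22.chromosome_length, 100
        vals = rng.poisson(1.0, -(-L // w)).astype(float)
        region = detect_lt_region(self._track(p22, vals), p22, threshold=5)
        assert region.span <= 50_000
        assert region.lt_read_fraction < 0.05


# ---------------------------------------------------------------------------
# plate-count statistics
# ---------------------------------------------------------------------------

class TestTransductionUnits:
    def test_basic_normalization(self):
        r = transduction_units(1e3, 1e9)
        assert r.tru_per_1e9_pfu == pytest.approx(1e3)
        assert r.log10_tru == pytest.approx(3.0)

    def test_titer_rescaling(self):
        r = transduction_units(2e4, 1e8)
        assert r.tru_per_1e9_pfu == pytest.approx(2e5)

    def test_below_detection(self):
        r = transduction_units(0.0, 1e9)
        assert r.tru_per_1e9_pfu == 0.0
        assert r.below_detection
        assert math.isnan(r.log10_tru)

    def test_zero_pfu_rejected(self):
        with pytest.raises(ValueError):
            transduction_units(10.0, 0.0)


class TestCotransduction:
    @pytest.mark.parametrize("k,n,expected", [(100, 100, 100.0), (0, 100, 0.0),
                                              (37, 100, 37.0)])
    def test_percent(self, k, n, expected):
        assert cotransduction_frequency(k, n).percent == expected

    def test_exact_ci_matches_clopper_pearson(self):
        r = cotransduction_frequency(37, 100)
        ref = stats.binomtest(37, 100).proportion_ci(0.95, method="exact")
        assert r.ci_low == pytest.approx(100 * ref.low)
        assert r.ci_high == pytest.approx(100 * ref.high)

    def test_zero_tested_rejected(self):
        with pytest.raises(ValueError):
            cotransduction_frequency(0, 0)

    def test_closer_markers_cotransduce_more(self, p22, make_pool_fn):
        """Same-fragment probability falls with marker separation."""
        from headful import PackagingConfig, simulate_packaging
        from headful.packaging_sim import marker_transfer_freq
        pool = make_pool_fn(p22, n_integrated=5000)
        frags = simulate_packaging(pool, p22,
                                   PackagingConfig(gt_init_prob=0.0), seed=1)
        base = (p22.attR_pos + 2_000) % p22.chromosome_length
        lt = frags[frags.origin == "LT"]

        def cofreq(sep):
            m2 = (base + sep) % p22.chromosome_length
            carry1 = marker_transfer_freq(lt, p22, base, pfu_equivalents=1.0)
            both = 0.0
            L = p22.chromosome_length
            off1 = (base - 2000 - lt.start.to_numpy()) % L
            off2 = (m2 - 2000 - lt.start.to_numpy()) % L
            in1 = (off1 + 4001) <= lt.length.to_numpy()
            in2 = (off2 + 4001) <= lt.length.to_numpy()
            return (in1 & in2).sum() / max(in1.sum(), 1)

        assert cofreq(10_000) > cofreq(40_000)


class TestDdct:
    @pytest.mark.parametrize("ct_t,ct_r,expected", [
        (20.0, 20.0, 1.0), (21.0, 20.0, 0.5), (18.0, 20.0, 4.0)])
    def test_values(self, ct_t, ct_r, expected):
        assert ddct(ct_t, ct_r) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct(float("nan"), 20.0)
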