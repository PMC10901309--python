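import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mtmkin.errors import (
    DegenerateSampleError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from mtmkin.geometry import VideoFeatureSummary
from mtmkin.scoring import MtmScore
from mtmkin.stats import (
    fisher_ci,
    independent_t,
    ks_normality,
    mann_whitney,
    run_group_comparisons,
    run_table2,
    spearman,
)


def mid_ranks(values):
    """Brute-force average ranks: mean of the 1-based positions of ties."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def make_summary(video_id, **kwargs):
    defaults = dict(
        mean_dlm15=0.0, mean_dlm16=0.0, mean_dlm27=0.0, mean_dlm28=0.0,
        mean_area_whole=0.0, mean_area_upper=0.0, mean_area_lower=0.0,
        n_valid_frames=100, n_frames=100,
    )
    defaults.update(kwargs)
    return VideoFeatureSummary(video_id=video_id, **defaults)


def make_score(video_id, lower=0.0, upper=0.0, duration_s=120.0):
    total = lower + upper
    return MtmScore(
        video_id=video_id,
        per_item_seconds={},
        total_seconds=total,
        occurrence_percentage=total / duration_s * 100,
        rate_total=total / duration_s * 60,
        rate_lower=lower / duration_s * 60,
        rate_upper=upper / duration_s * 60,
    )


class TestFisherCI:
    def test_symmetric_about_zero(self):
        lo, hi = fisher_ci(0.0, 50)
        assert lo == pytest.approx(-hi)

    def test_brackets_r_and_shrinks_with_n(self):
        r = 0.4
        widths = []
        for n in (10, 50, 200, 1000):
            lo, hi = fisher_ci(r, n)
            assert lo < r < hi
            assert -1 < lo and hi < 1
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            fisher_ci(0.3, 3)

    def test_matches_closed_form(self):
        r, n = 0.315, 94
        lo, hi = fisher_ci(r, n)
        half = 1.959963984540054 / math.sqrt(n - 3)
        assert lo == pytest.approx(math.tanh(math.atanh(r) - half), abs=1e-12)
        assert hi == pytest.approx(math.tanh(math.atanh(r) + half), abs=1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_ties_match_mid_rank_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [3.0, 1.0, 4.0, 4.0, 2.0, 6.0]
        r, _ = spearman(x, y)
        rx, ry = mid_ranks(x), mid_ranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]  # Pearson on average ranks
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.permutations(range(8)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, perm):
        x = np.arange(8.0)
        y = np.array(perm, dtype=float)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(np.exp(x / 3.0), y**3 + 2 * y)
        assert r2 == pytest.approx(r1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)


class TestMannWhitney:
    def test_identical_multisets(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, _ = mann_whitney(a, list(a), method="asymptotic")
        assert u == pytest.approx(len(a) * len(a) / 2.0)

    def test_complete_separation(self):
        u, _ = mann_whitney([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert u == 9.0  # U of the first sample = n_a * n_b

    def test_p_matches_exact_permutation_enumeration(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(0.8, size=5)
        u_obs, p = mann_whitney(a, b, method="exact")

        def u_stat(group_a, group_b):
            return sum(
                (x > y) + 0.5 * (x == y) for x in group_a for y in group_b
            )

        pooled = np.concatenate([a, b])
        n = len(a)
        count = total = 0
        mean_u = len(a) * len(b) / 2.0
        for idx in itertools.combinations(range(len(pooled)), n):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(idx)] = True
            u = u_stat(pooled[mask], pooled[~mask])
            count += abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        worst = 0.0
        for _ in range(200):
            a = rng.normal(size=8)
            b = rng.normal(rng.uniform(-1.5, 1.5), size=8)
            _, p_exact = mann_whitney(a, b, method="exact")
            _, p_asym = mann_whitney(a, b, method="asymptotic")
            worst = max(worst, abs(p_exact - p_asym))
        assert worst < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0])


class TestIndependentT:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0]
        t, p = independent_t(a, list(a))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_pooled_formula(self):
        a = np.array([3.1, 2.8, 3.6, 3.0])
        b = np.array([2.1, 2.6, 1.9, 2.4, 2.2])
        t, _ = independent_t(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(expected, abs=1e-12)

    def test_welch_variant_differs_under_unequal_variance(self, rng):
        a = rng.normal(0, 0.2, size=10)
        b = rng.normal(0.5, 3.0, size=25)
        t_student, _ = independent_t(a, b, equal_var=True)
        t_welch, _ = independent_t(a, b, equal_var=False)
        assert t_student != pytest.approx(t_welch)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            independent_t([2.0, 2.0], [2.0, 2.0])


class TestKSNormality:
    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            ks_normality([0.0, 0.0, 0.0])

    def test_statistic_matches_ecdf_enumeration(self, rng):
        x = np.sort(rng.normal(size=8))
        stat, _ = ks_normality(x, method="ks")
        mu, sd = x.mean(), x.std(ddof=1)
        n = len(x)
        oracle = max(
            max((i + 1) / n - sps.norm.cdf(x[i], mu, sd),
                sps.norm.cdf(x[i], mu, sd) - i / n)
            for i in range(n)
        )
        assert stat == pytest.approx(oracle, abs=1e-12)

    def test_lilliefors_statistic_agrees_with_plugin_ks(self, rng):
        x = rng.normal(size=40)
        stat_l, _ = ks_normality(x, method="lilliefors")
        stat_k, _ = ks_normality(x, method="ks")
        assert stat_l == pytest.approx(stat_k, abs=1e-10)

    def test_statistic_shrinks_for_large_normal_sample(self, rng):
        stat_small, _ = ks_normality(rng.normal(size=30))
        stat_large, _ = ks_normality(rng.normal(size=3000))
        assert stat_large < stat_small


class TestRunTable2:
    def test_monotone_coupling_gives_perfect_negative_r(self):
        features, scores = [], []
        for i in range(10):
            features.append(
                make_summary(
                    f"v{i}",
                    mean_dlm15=0.2 + 0.01 * ((i * 7) % 10),
                    mean_dlm16=1.0 - 0.05 * i,
                    mean_dlm27=0.1 * ((i * 3) % 10),
                    mean_dlm28=-0.1 * ((i * 9) % 10),
                )
            )
            scores.append(make_score(f"v{i}", lower=float(i % 3),
                                     upper=10.0 + 5 * i))
        table = run_table2(features, scores)
        cell = table[("mean_dlm16", "rate_total")]
        assert cell.r == pytest.approx(-1.0)
        assert cell.n == 10

    def test_cells_internally_consistent_with_fisher_ci(self, rng):
        features = [
            make_summary(f"v{i}", mean_dlm15=rng.normal(),
                         mean_dlm16=rng.normal(), mean_dlm27=rng.normal(),
                         mean_dlm28=rng.normal())
            for i in range(20)
        ]
        scores = [
            make_score(f"v{i}", lower=rng.uniform(0, 60),
                       upper=rng.uniform(0, 60))
            for i in range(20)
        ]
        table = run_table2(features, scores)
        assert len(table) == 16
        for cell in table.values():
            lo, hi = fisher_ci(cell.r, cell.n)
            assert cell.ci_low == pytest.approx(lo)
            assert cell.ci_high == pytest.approx(hi)
            assert cell.ci_low <= cell.r <= cell.ci_high

    def test_decoupled_cohort_has_small_correlations(self, rng):
        """Permuting scores against features destroys the association."""
        n = 100
        features = [
            make_summary(f"v{i}", mean_dlm15=float(np.sin(i)),
                         mean_dlm16=rng.normal(), mean_dlm27=rng.normal(),
                         mean_dlm28=rng.normal())
            for i in range(n)
        ]
        perm = rng.permutation(n)
        scores = [
            make_score(f"v{i}", lower=float(perm[i]), upper=rng.uniform(0, 60))
            for i in range(n)
        ]
        table = run_table2(features, scores)
        rs = [abs(c.r) for c in table.values()]
        assert np.median(rs) < 0.25

    def test_too_few_videos_rejected(self):
        features = [make_summary(f"v{i}") for i in range(3)]
        scores = [make_score(f"v{i}", lower=float(i + 1)) for i in range(3)]
        with pytest.raises(InsufficientDataError):
            run_table2(features, scores)


class TestRunGroupComparisons:
    def _cohort(self, rng, shift):
        """30 shows / 30 no-shows; the shows group's lower area shifted down."""
        features, scores = [], []
        for i in range(60):
            shows = i < 30
            lower_area = rng.normal(1.0 - (shift if shows else 0.0), 0.1)
            features.append(
                make_summary(
                    f"v{i}",
                    mean_area_whole=rng.normal(2.0, 0.2),
                    mean_area_upper=rng.normal(0.5, 0.05),
                    mean_area_lower=lower_area,
                )
            )
            scores.append(make_score(f"v{i}", lower=30.0 if shows else 0.0))
        return features, scores

    def test_shifted_lower_area_detected(self, rng):
        features, scores = self._cohort(rng, shift=0.2)  # 2 SD shift
        comps = run_group_comparisons(features, scores)
        cell = next(
            c for c in comps if c.category == "Lower" and c.measure == "lower"
        )
        assert cell.test == "mann_whitney"
        assert cell.p < 0.05
        assert cell.location_show < cell.location_noshow
        assert cell.n_show == cell.n_noshow == 30

    def test_test_assignment_follows_measure(self, rng):
        features, scores = self._cohort(rng, shift=0.0)
        comps = run_group_comparisons(features, scores)
        by_measure = {c.measure: c.test for c in comps if c.category == "Lower"}
        assert by_measure == {
            "whole": "t_test", "upper": "mann_whitney", "lower": "mann_whitney"
        }

    def test_empty_group_skipped_with_warning(self, rng):
        features = [make_summary(f"v{i}", mean_area_whole=rng.normal())
                    for i in range(6)]
        scores = [make_score(f"v{i}", lower=10.0) for i in range(6)]  # all show
        with pytest.warns(UserWarning):
            comps = run_group_comparisons(features, scores)
        assert not [c for c in comps if c.category in ("Lower", "Total")]
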