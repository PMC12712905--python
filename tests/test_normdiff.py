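import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from transchrom.core_io import CountMatrix, GenomicInterval, Interaction
from transchrom.normdiff import (
    FilterSpec,
    bh_adjust,
    call_differential,
    cpm,
    estimate_common_dispersion,
    filter_interactions,
    nb_exact_test,
    tmm_factors,
)

from conftest import make_counts


# ---------------------------------------------------------------------------
# TMM


class TestTmm:
    def test_identical_samples_unit_factors(self):
        x = np.tile(np.arange(1, 101)[:, None], (1, 3))
        nf = tmm_factors(make_counts(x))
        np.testing.assert_allclose(nf.factors, 1.0, atol=1e-9)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(0)
        a = rng.integers(10, 1000, 500)
        x = np.column_stack([a, 2 * a])
        cm = make_counts(x)
        nf = tmm_factors(cm)
        np.testing.assert_allclose(nf.factors, 1.0, atol=1e-9)
        norm = cpm(cm, nf)
        np.testing.assert_allclose(norm.iloc[:, 0], norm.iloc[:, 1], rtol=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(rng.lognormal(4, 1, 300)[:, None] * rng.lognormal(0, 0.3, 4)[None, :])
        nf = tmm_factors(make_counts(x))
        assert abs(np.mean(np.log(nf.factors))) < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(100, (400, 3))
        f1 = tmm_factors(make_counts(x)).factors
        f2 = tmm_factors(make_counts(3 * x)).factors
        np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_all_zero_sample_rejected(self):
        x = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(make_counts(x))

    def test_planted_composition_recovery(self):
        # 90% null features, 10% 4-fold up in sample B; the estimate must land
        # within 2% of the brute-force trimmed weighted mean computed
        # independently on the noise-free expected counts
        rng = np.random.default_rng(42)
        n, frac_de = 2000, 0.10
        lam = rng.lognormal(7, 0.5, n)
        de = np.zeros(n, dtype=bool)
        de[: int(n * frac_de)] = True
        mu_a = lam
        mu_b = lam * np.where(de, 4.0, 1.0)
        phi = 0.001  # low noise so the noise-free analytic oracle applies
        r = 1 / phi
        xa = rng.negative_binomial(r, r / (r + mu_a))
        xb = rng.negative_binomial(r, r / (r + mu_b))
        cm = make_counts(np.column_stack([xa, xb]))
        nf = tmm_factors(cm)
        estimated_ratio = nf.factors[1] / nf.factors[0]

        # independent brute-force oracle on expected counts
        na, nb = mu_a.sum(), mu_b.sum()
        m = np.log2((mu_b / nb) / (mu_a / na))
        a = 0.5 * np.log2((mu_b / nb) * (mu_a / na))
        w = (nb - mu_b) / (nb * mu_b) + (na - mu_a) / (na * mu_a)
        nn = len(m)
        lo_m, hi_m = np.floor(nn * 0.3) + 1, nn - np.floor(nn * 0.3)
        lo_a, hi_a = np.floor(nn * 0.05) + 1, nn - np.floor(nn * 0.05)
        rm = stats.rankdata(m, method="ordinal")  # ordinal: tied null block trims deterministically
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        oracle_log2 = np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep])
        # factors are rescaled to geometric mean 1: the B/A ratio is invariant
        oracle_ratio = 2.0 ** oracle_log2
        assert abs(estimated_ratio / oracle_ratio - 1) < 0.02


# ---------------------------------------------------------------------------
# filtering


def _toy_interactions():
    spans = [4000, 6000, 6000, 6000, 6000, 6000]
    ixns = []
    for i, s in enumerate(spans):
        a = GenomicInterval("chr1", 1000, 1100)
        b = GenomicInterval("chr1", 1000 + s, 1100 + s)
        ixns.append(Interaction(a, b, id=f"row{i + 1}"))
    counts = make_counts(
        np.array([[5, 5], [5, 5], [4, 4], [4, 3], [3, 3], [0, 9]]),
        features=[f"row{i + 1}" for i in range(6)],
    )
    return ixns, counts


class TestFilter:
    def test_hand_evaluated_toy_table(self):
        # row1 fails span; rows 2,3 pass both; row4 >=4 in one sample only;
        # row5 all 3s; row6 >=4 in one sample only -> retained rows 2 and 3
        ixns, counts = _toy_interactions()
        retained, report = filter_interactions(ixns, counts, FilterSpec())
        assert [i.id for i in retained] == ["row2", "row3"]
        assert report.n_retained == 2
        assert report.n_failed_span == 1
        assert report.n_failed_counts == 3

    def test_min_count_zero_keeps_all_long(self):
        ixns, counts = _toy_interactions()
        retained, _ = filter_interactions(ixns, counts, FilterSpec(min_count=0))
        assert [i.id for i in retained] == [f"row{i}" for i in range(2, 7)]

    def test_empty_input(self):
        counts = make_counts(np.empty((0, 2), dtype=int), features=[])
        retained, report = filter_interactions([], counts, FilterSpec())
        assert retained == [] and report.n_input == 0

    def test_missing_count_row(self):
        ixns, counts = _toy_interactions()
        with pytest.raises(KeyError, match="missing count rows"):
            filter_interactions(ixns, CountMatrix(counts.df.drop(index="row3")), FilterSpec())


# ---------------------------------------------------------------------------
# dispersion


class TestDispersion:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(200, (2000, 6))
        phi = estimate_common_dispersion(make_counts(x), ["A"] * 3 + ["B"] * 3)
        assert phi < 0.02

    def test_nb_recovery(self):
        rng = np.random.default_rng(4)
        phi_true, mu = 0.2, 200.0
        r = 1 / phi_true
        x = rng.negative_binomial(r, r / (r + mu), (2000, 6))
        phi = estimate_common_dispersion(make_counts(x), ["A"] * 3 + ["B"] * 3)
        assert 0.15 <= phi <= 0.25

    def test_constant_counts_clip_to_zero(self):
        x = np.full((50, 4), 7)
        phi = estimate_common_dispersion(make_counts(x), ["A", "A", "B", "B"])
        assert phi == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_common_dispersion(make_counts(np.array([[1], [2]])), ["A"])


# ---------------------------------------------------------------------------
# exact test


def _binomial_oracle_p(s_a: int, total: int, pr: float) -> float:
    """Brute-force doubled-tail binomial p by direct pmf summation."""
    pmf = np.array([stats.binom.pmf(k, total, pr) for k in range(total + 1)])
    lo = pmf[: s_a + 1].sum()
    hi = pmf[s_a:].sum()
    return min(1.0, 2 * min(lo, hi))


class TestExactTest:
    def test_phi_zero_equals_binomial_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(40, (50, 6))
        # equal library sizes: pad a balancing feature so column sums match
        pad = x.sum(axis=0).max() - x.sum(axis=0)
        x = np.vstack([x, pad])
        cm = make_counts(x)
        res = nb_exact_test(cm, ["A"] * 3 + ["B"] * 3, phi=0.0)
        for i in range(50):
            sa = int(x[i, :3].sum())
            tot = int(x[i].sum())
            assert res["pvalue"].iloc[i] == pytest.approx(
                _binomial_oracle_p(sa, tot, 0.5), abs=1e-12
            )

    def test_symmetric_counts_zero_lfc(self):
        x = np.array([[10, 20, 30, 10, 20, 30]])
        res = nb_exact_test(make_counts(x), ["A"] * 3 + ["B"] * 3, phi=0.1)
        assert res["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_group_swap_exchangeability(self):
        rng = np.random.default_rng(6)
        x = rng.poisson(100, (30, 6))
        cm = make_counts(x)
        g = ["A"] * 3 + ["B"] * 3
        res_ab = nb_exact_test(cm, g, 0.1, group_order=("A", "B"))
        res_ba = nb_exact_test(cm, g, 0.1, group_order=("B", "A"))
        np.testing.assert_allclose(res_ab["pvalue"], res_ba["pvalue"], atol=1e-12)
        np.testing.assert_allclose(res_ab["log2fc"], -res_ba["log2fc"], atol=1e-12)

    def test_three_groups_rejected(self):
        x = np.ones((5, 6), dtype=int)
        with pytest.raises(ValueError, match="pairwise"):
            nb_exact_test(make_counts(x), ["A", "A", "B", "B", "C", "C"], 0.1)


# ---------------------------------------------------------------------------
# BH


def _bh_brute_force(p):
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        rank_i = np.sum(p <= p[i])  # ties share the max rank
        # step-up: min over all p_j >= p_i of p_j * m / rank_j
        cand = []
        for j in range(m):
            if p[j] >= p[i]:
                cand.append(p[j] * m / np.sum(p <= p[j]))
        q[i] = min(1.0, min(cand))
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), _bh_brute_force(pvals), atol=1e-12)

    def test_permutation_stability(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        perm = rng.permutation(100)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], atol=1e-15)


# ---------------------------------------------------------------------------
# calling


class TestCallDifferential:
    def test_empty_when_nothing_significant(self):
        res = pd.DataFrame({"log2fc": [0.5], "pvalue": [0.9], "qvalue": [0.9]}, index=["f"])
        assert len(call_differential(res, 0.2)) == 0

    def test_threshold_one_returns_all(self):
        res = pd.DataFrame(
            {"log2fc": [0.5, -1.0], "pvalue": [0.9, 0.4], "qvalue": [0.9, 0.8]},
            index=["f1", "f2"],
        )
        out = call_differential(res, 1.0)
        assert len(out) == 2
        assert list(out["direction"]) == ["higher_in_a", "higher_in_b"]

    def test_planted_power(self):
        # 100 planted 4-fold DIs among 1,000 features, phi = 0.05, 3 vs 3:
        # >= 90 recovered at FDR 0.2
        rng = np.random.default_rng(8)
        n, n_de = 1000, 100
        lam = rng.lognormal(5, 0.5, n)
        mu = np.tile(lam[:, None], (1, 6)).astype(float)
        mu[:n_de, 3:] *= 4.0
        r = 1 / 0.05
        x = rng.negative_binomial(r, r / (r + mu))
        cm = make_counts(x)
        groups = ["A"] * 3 + ["B"] * 3
        phi = estimate_common_dispersion(cm, groups)
        res = nb_exact_test(cm, groups, phi, tmm_factors(cm))
        res["qvalue"] = bh_adjust(res["pvalue"].to_numpy())
        called = call_differential(res, 0.2)
        planted = {f"f{i}" for i in range(n_de)}
        recovered = planted & set(called.index)
        assert len(recovered) >= 90

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(9)
        n, n_de = 600, 60
        lam = rng.lognormal(5, 0.5, n)
        recov = []
        for fold in (1.5, 3.0, 6.0):
            mu = np.tile(lam[:, None], (1, 6)).astype(float)
            mu[:n_de, 3:] *= fold
            r = 1 / 0.05
            x = rng.negative_binomial(r, r / (r + mu))
            cm = make_counts(x)
            groups = ["A"] * 3 + ["B"] * 3
            res = nb_exact_test(cm, groups, 0.05, tmm_factors(cm))
            res["qvalue"] = bh_adjust(res["pvalue"].to_numpy())
            called = set(call_differential(res, 0.2).index)
            recov.append(len(called & {f"f{i}" for i in range(n_de)}))
        assert recov[0] <= recov[1] <= recov[2]
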