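import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transchrom.core_io import GenomicInterval, Interaction, overlaps
from transchrom.qtl import (
    QtlTarget,
    allele_concordance,
    classify_anchor_overlap,
    correlate_strength_effect,
    factor_binding_enrichment,
    pair_di_targets,
    permutation_enrichment,
)


def _iv(chrom, start, end, name=""):
    return GenomicInterval(chrom, start, end, name)


def _random_instance(rng, n_dis=20, n_targets=30):
    dis = []
    for i in range(n_dis):
        s1 = int(rng.integers(0, 5000))
        s2 = int(rng.integers(0, 5000))
        dis.append(
            Interaction(_iv("chr1", s1, s1 + 100), _iv("chr1", s2, s2 + 100), id=f"di{i}")
        )
    targets = [
        _iv("chr1", int(s), int(s) + int(rng.integers(10, 200)))
        for s in rng.integers(0, 5000, n_targets)
    ]
    return dis, targets


class TestClassify:
    def test_both_anchors(self):
        di = Interaction(_iv("chr1", 100, 200), _iv("chr1", 10_000, 10_100), "d")
        targets = [_iv("chr1", 150, 160), _iv("chr1", 10_050, 10_060)]
        out = classify_anchor_overlap([di], targets)
        assert out["category"].iloc[0] == "both_anchors"

    def test_no_targets(self):
        di = Interaction(_iv("chr1", 100, 200), _iv("chr1", 10_000, 10_100), "d")
        out = classify_anchor_overlap([di], [])
        assert out["category"].iloc[0] == "none"
        assert out.attrs["proportions"] == {"none": 1.0, "one_anchor": 0.0, "both_anchors": 0.0}

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            dis, targets = _random_instance(rng)
            out = classify_anchor_overlap(dis, targets)
            for di, cat in zip(dis, out["category"]):
                hit1 = any(overlaps(di.anchor1, t) for t in targets)
                hit2 = any(overlaps(di.anchor2, t) for t in targets)
                expected = (
                    "both_anchors" if hit1 and hit2
                    else "one_anchor" if hit1 or hit2
                    else "none"
                )
                assert cat == expected


class TestPermutationEnrichment:
    def test_targets_equal_universe_gives_p_one(self):
        rng = np.random.default_rng(14)
        dis, targets = _random_instance(rng, 10, 15)
        res = permutation_enrichment(dis, targets, targets, n_perm=50, seed=0)
        assert res["one_anchor"].pvalue == 1.0
        assert res["both_anchors"].pvalue == 1.0

    def test_planted_anchoring_hits_floor(self):
        # DIs anchored exactly on targets; universe mostly far away
        targets = [_iv("chr1", 1000 * i, 1000 * i + 100, f"t{i}") for i in range(10)]
        decoys = [_iv("chr2", 1000 * i, 1000 * i + 100, f"u{i}") for i in range(200)]
        dis = [
            Interaction(t, _iv("chr1", 900_000 + 1000 * i, 900_000 + 1000 * i + 100), f"di{i}")
            for i, t in enumerate(targets)
        ]
        res = permutation_enrichment(dis, targets, targets + decoys, n_perm=200, seed=1)
        assert res["one_anchor"].pvalue == pytest.approx(1 / 201)

    def test_zero_perm_degenerate(self):
        rng = np.random.default_rng(15)
        dis, targets = _random_instance(rng, 5, 5)
        res = permutation_enrichment(dis, targets, targets, n_perm=0, seed=0)
        assert res["one_anchor"].pvalue == 1.0
        assert res["one_anchor"].degenerate

    def test_more_targets_than_universe_rejected(self):
        rng = np.random.default_rng(16)
        dis, targets = _random_instance(rng, 5, 5)
        with pytest.raises(ValueError, match="universe"):
            permutation_enrichment(dis, targets, targets[:3], n_perm=10, seed=0)

    def test_pvalues_valid_under_null(self):
        # null generator: targets drawn from the universe exactly as the
        # permutation null does -> P(p <= alpha) <= alpha + 1/(1+n_perm)
        rng = np.random.default_rng(17)
        dis, _ = _random_instance(rng, 15, 0)
        universe = [
            _iv("chr1", int(s), int(s) + 50, f"p{i}")
            for i, s in enumerate(rng.integers(0, 5000, 60))
        ]
        alpha, n_perm, hits = 0.2, 39, 0
        n_rep = 40
        for rep in range(n_rep):
            idx = rng.choice(60, size=12, replace=False)
            targets = [universe[i] for i in idx]
            res = permutation_enrichment(dis, targets, universe, n_perm=n_perm, seed=rep)
            if res["one_anchor"].pvalue <= alpha:
                hits += 1
        # binomial slack: 3 sigma above alpha + 1/(1+n_perm)
        bound = alpha + 1 / (1 + n_perm)
        assert hits / n_rep <= bound + 3 * math.sqrt(bound * (1 - bound) / n_rep)


class TestCorrelation:
    def test_perfect_positive(self):
        x = np.arange(1.0, 11.0)
        res = correlate_strength_effect(x, 2 * x)
        assert res["r"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(1.0, 11.0)
        assert correlate_strength_effect(x, -x)["r"] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_strength_effect([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_pairing_multiplicity(self):
        # one DI overlapping two targets contributes two rows
        di = Interaction(_iv("chr1", 100, 300), _iv("chr1", 10_000, 10_100), "d1")
        targets = [
            QtlTarget("t1", _iv("chr1", 150, 170, "t1"), "cis", "B6", 6.0, 1.0),
            QtlTarget("t2", _iv("chr1", 200, 220, "t2"), "trans", "D2", 7.0, -1.0),
        ]
        pairs = pair_di_targets([di], {"d1": 0.5}, targets)
        assert len(pairs) == 2


class TestConcordance:
    def test_hand_computed_chi2(self):
        # perfectly concordant 2x2 with 10 per diagonal cell: E = 5 each,
        # chi2 = sum (O-E)^2/E = 4 * (5^2/5) = 20, df = 1
        d = ["higher_in_a"] * 10 + ["higher_in_b"] * 10
        a = ["B6"] * 10 + ["D2"] * 10
        res = allele_concordance(d, a)
        assert res["chi2"] == pytest.approx(20.0)
        assert res["df"] == 1
        assert res["concordant_fraction"] == 1.0

    def test_zero_row_degenerate_flagged(self):
        d = ["higher_in_a"] * 10
        a = ["B6"] * 5 + ["D2"] * 5
        res = allele_concordance(d, a)
        assert res["degenerate"]
        assert res["pvalue"] == 1.0

    def test_null_calibration(self):
        # independent uniform labels: rejection rate at alpha = 0.05 within
        # [0.03, 0.07] across seeded simulations
        rng = np.random.default_rng(18)
        n, n_sims, rejections = 2000, 600, 0
        for _ in range(n_sims):
            cells = rng.multinomial(n, [0.25] * 4)
            d = np.repeat(["higher_in_a", "higher_in_a", "higher_in_b", "higher_in_b"], cells)
            a = np.repeat(["B6", "D2", "B6", "D2"], cells)
            if allele_concordance(list(d), list(a))["pvalue"] <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07


def _fisher_enumeration_p(table):
    """Brute-force two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    probs = []
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )
        probs.append((x, p))
    p_obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= p_obs + 1e-12)


class TestFactorEnrichment:
    def _universe(self):
        return [_iv("chr1", 1000 * i, 1000 * i + 100, f"a{i}") for i in range(20)]

    def test_fisher_matches_enumeration(self):
        # construct a universe realizing the table [[8,2],[1,9]]
        universe = self._universe()
        trans_ids = [f"a{i}" for i in range(10)]
        # sites overlap anchors 0-7 (trans) and anchor 10 (non-trans)
        sites = [_iv("chr1", 1000 * i, 1000 * i + 10) for i in list(range(8)) + [10]]
        res = factor_binding_enrichment({"TF1": sites}, trans_ids, universe)
        row = res.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (8, 2, 1, 9)
        assert row.sample_odds_ratio == pytest.approx(36.0)
        assert row.pvalue == pytest.approx(_fisher_enumeration_p([[8, 2], [1, 9]]), abs=1e-9)

    def test_zero_sites(self):
        universe = self._universe()
        res = factor_binding_enrichment({"TF0": []}, [f"a{i}" for i in range(10)], universe)
        assert res["pvalue"].iloc[0] == 1.0
        assert res["sample_odds_ratio"].iloc[0] > 0  # Haldane-adjusted, finite

    def test_trans_set_equals_universe(self):
        universe = self._universe()
        sites = [_iv("chr1", 0, 50)]
        res = factor_binding_enrichment({"TF1": sites}, [iv.name for iv in universe], universe)
        assert res["pvalue"].iloc[0] == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            factor_binding_enrichment({"TF1": []}, [], [])

    def test_fisher_matches_enumeration_random_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 30, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            assert p_scipy == pytest.approx(_fisher_enumeration_p([[a, b], [c, d]]), abs=1e-9)


class TestQtlTargetValidation:
    def test_allele_effect_consistency(self):
        with pytest.raises(ValueError, match="high_allele"):
            QtlTarget("t", _iv("chr1", 0, 10), "cis", "D2", 5.0, +1.0)

    def test_negative_lod(self):
        with pytest.raises(ValueError, match="LOD"):
            QtlTarget("t", _iv("chr1", 0, 10), "cis", "B6", -1.0, +1.0)
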