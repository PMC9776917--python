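import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cxragree import (
    bootstrap_ci,
    collapse,
    interpret_kappa,
    intra_rater,
    observed_agreement_counts,
    observed_agreement_multi,
    pabak,
    randolph_kappa,
    randolph_kappa_counts,
    round_half_up,
    specific_agreement_multi,
    specific_agreement_pair,
)
from cxragree.store import AnnotationRecord

from conftest import pairwise_observed_agreement, random_binary_columns


class TestObservedAgreement:
    def test_single_discordant_case(self):
        # 100 cases, 6 raters, one case with a single positive rater:
        # P-bar-o = (99 + 20/30)/100
        col = np.zeros((100, 6), dtype=np.uint8)
        col[0, 0] = 1
        assert observed_agreement_multi(col) == pytest.approx((99 + 20 / 30) / 100)

    def test_perfect_agreement(self):
        col = np.ones((40, 6), dtype=np.uint8)
        assert observed_agreement_multi(col) == 1.0

    def test_two_raters_is_simple_proportion(self):
        col = np.zeros((100, 2), dtype=np.uint8)
        col[:12, 0] = 1  # disagree on 12 cases
        assert observed_agreement_multi(col) == pytest.approx(0.88)

    def test_closed_form_equals_pairwise_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            col = random_binary_columns(
                rng, int(rng.integers(1, 51)), int(rng.integers(2, 7))
            )
            assert observed_agreement_multi(col) == pytest.approx(
                pairwise_observed_agreement(col), abs=1e-12
            )

    def test_rejects_single_rater_and_empty(self):
        with pytest.raises(ValueError):
            observed_agreement_multi(np.zeros((10, 1)))
        with pytest.raises(ValueError):
            observed_agreement_multi(np.zeros((0, 3)))

    def test_general_q_counts_form(self):
        # 3 categories, 4 raters: check against pairwise enumeration on
        # explicit categorical assignments
        rng = np.random.default_rng(5)
        assign = rng.integers(0, 3, size=(20, 4))
        counts = np.stack([(assign == k).sum(axis=1) for k in range(3)], axis=1)
        po = observed_agreement_counts(counts)
        import itertools

        expected = np.mean(
            [
                np.mean([row[a] == row[b] for a, b in itertools.combinations(range(4), 2)])
                for row in assign
            ]
        )
        assert po == pytest.approx(expected)
        res = randolph_kappa_counts(counts)
        assert res.n_categories == 3
        assert res.value == pytest.approx((po - 1 / 3) / (1 - 1 / 3))


class TestRandolphKappa:
    def test_identical_raters(self):
        col = np.tile(np.array([[1], [0], [1]], dtype=np.uint8), (1, 5))
        res = randolph_kappa(col)
        assert res.value == 1.0
        assert res.interpretation == "almost perfect"

    def test_kappa_one_iff_perfect_observed_agreement(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            col = random_binary_columns(rng, 30, 4)
            po = observed_agreement_multi(col)
            k = randolph_kappa(col).value
            assert (k == 1.0) == (po == 1.0)

    def test_invariant_to_case_and_rater_order(self):
        rng = np.random.default_rng(9)
        col = random_binary_columns(rng, 40, 5)
        k = randolph_kappa(col).value
        assert randolph_kappa(col[rng.permutation(40)]).value == pytest.approx(k)
        assert randolph_kappa(col[:, rng.permutation(5)]).value == pytest.approx(k)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_two_rater_kappa_equals_pabak(self, seed):
        rng = np.random.default_rng(seed)
        col = random_binary_columns(rng, int(rng.integers(1, 60)), 2)
        k = randolph_kappa(col).value
        p = pabak(col[:, 0], col[:, 1]).value
        assert k == pytest.approx(p, abs=1e-12)


class TestPabak:
    def test_all_negative_pair_is_one(self):
        z = np.zeros(100, dtype=np.uint8)
        assert pabak(z, z).value == 1.0

    def test_linear_in_proportion_observed(self):
        a = np.zeros(100, dtype=np.uint8)
        b = np.zeros(100, dtype=np.uint8)
        b[:12] = 1  # Po = 0.88
        assert pabak(a, b).value == pytest.approx(0.76)

    def test_random_columns_near_zero(self):
        rng = np.random.default_rng(0)
        a = (rng.random(5000) < 0.5).astype(np.uint8)
        b = (rng.random(5000) < 0.5).astype(np.uint8)
        assert abs(pabak(a, b).value) < 0.06

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pabak(np.zeros(5), np.zeros(6))

    def test_pabak_one_iff_identical(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = (rng.random(30) < 0.4).astype(np.uint8)
            b = a.copy()
            if rng.random() < 0.5:
                b[rng.integers(30)] ^= 1
            assert (pabak(a, b).value == 1.0) == bool((a == b).all())


class TestSpecificAgreement:
    def test_two_by_two_formula(self):
        a = np.r_[np.ones(5), np.ones(2), np.zeros(3), np.zeros(90)].astype(np.uint8)
        b = np.r_[np.ones(5), np.zeros(2), np.ones(3), np.zeros(90)].astype(np.uint8)
        ppa, pna = specific_agreement_pair(a, b)
        assert ppa == pytest.approx(10 / 15)
        assert pna == pytest.approx(180 / 185)

    def test_no_positives_ppa_undefined(self):
        z = np.zeros(50, dtype=np.uint8)
        ppa, pna = specific_agreement_pair(z, z)
        assert np.isnan(ppa)
        assert pna == 1.0

    def test_identical_with_positives(self):
        a = np.r_[np.ones(4), np.zeros(6)].astype(np.uint8)
        assert specific_agreement_pair(a, a) == (1.0, 1.0)

    def test_single_positive_among_raters_gives_zero_ppa(self):
        col = np.zeros((60, 6), dtype=np.uint8)
        col[3, 2] = 1
        ppa, pna = specific_agreement_multi(col)
        assert ppa == 0.0
        assert pna < 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_multi_rater_form_specializes_to_pair(self, seed):
        rng = np.random.default_rng(seed)
        col = random_binary_columns(rng, int(rng.integers(1, 50)), 2)
        multi = specific_agreement_multi(col)
        pair = specific_agreement_pair(col[:, 0], col[:, 1])
        for m, p in zip(multi, pair):
            assert (np.isnan(m) and np.isnan(p)) or m == pytest.approx(p, abs=1e-12)


class TestBootstrap:
    def test_degenerate_data_degenerate_interval(self):
        col = np.ones((30, 4), dtype=np.uint8)
        ci = bootstrap_ci(col, lambda c: randolph_kappa(c).value, n_boot=50, seed=1)
        assert ci == (1.0, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        col = random_binary_columns(rng, 60, 6)
        stat = lambda c: randolph_kappa(c).value
        assert bootstrap_ci(col, stat, n_boot=200, seed=77) == bootstrap_ci(
            col, stat, n_boot=200, seed=77
        )

    def test_undefined_statistic_raises(self):
        col = np.zeros((20, 2), dtype=np.uint8)
        with pytest.raises(ValueError, match="undefined"):
            bootstrap_ci(
                col,
                lambda c: specific_agreement_multi(c)[0],
                n_boot=10,
                seed=0,
            )

    def test_coverage_near_nominal(self):
        # iid raters with per-case agreement known in closed form:
        # kappa is an affine function of mean per-case concordance
        rng = np.random.default_rng(123)
        p, n, N = 0.8, 4, 150
        po_true = p * p + (1 - p) * (1 - p)  # E[pairwise concordance], iid raters
        target = 2 * po_true - 1  # the q=2 free-marginal kappa of that process
        stat = lambda c: randolph_kappa(c).value
        hits, sims = 0, 120
        for _ in range(sims):
            col = (rng.random((N, n)) < p).astype(np.uint8)
            lo, hi = bootstrap_ci(col, stat, n_boot=300, seed=rng)
            hits += lo - 1e-9 <= target <= hi + 1e-9
        assert 0.85 <= hits / sims <= 1.0


class TestInterpretation:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.40, "fair"),
            (1.00, "almost perfect"),
            (-0.2, "poor"),
            (0.10, "slight"),
            (0.55, "moderate"),
            (0.75, "substantial"),
            (0.81, "almost perfect"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_kappa(value) == band

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.2)


class TestIntraRater:
    def _matrix(self, scheme, flips=0):
        cases = [f"c{i}" for i in range(100)]
        records = []
        for i, c in enumerate(cases):
            records.append(AnnotationRecord(c, "r1", 1, "frontal", "Pneumothorax"))
            if i >= flips:  # first `flips` cases differ between rounds
                records.append(AnnotationRecord(c, "r1", 2, "frontal", "Pneumothorax"))
        return collapse(records, scheme, cases=cases, raters=["r1"], rounds=[1, 2])

    def test_identical_rounds(self, scheme):
        m = self._matrix(scheme, flips=0)
        res = intra_rater(m, "r1", "Pneumothorax")
        assert res["pabak"].value == 1.0
        assert res["ppa"] == 1.0

    def test_thirty_seven_discordant_cases(self, scheme):
        m = self._matrix(scheme, flips=37)
        res = intra_rater(m, "r1", "Pneumothorax")
        assert res["pabak"].value == pytest.approx(2 * 0.63 - 1)
        assert round_half_up(res["pabak"].value) == 0.26

    def test_missing_round_rejected(self, scheme):
        m = collapse(
            [AnnotationRecord("c1", "r1", 1, "frontal", "Normal")],
            scheme,
            cases=["c1"],
            raters=["r1"],
            rounds=[1],
        )
        with pytest.raises(KeyError, match="round 2"):
            intra_rater(m, "r1", "Normal")


@pytest.mark.parametrize(
    "value,expected",
    [(0.985, 0.99), (0.125, 0.13), (0.265, 0.27), (0.994999, 0.99), (0.995, 1.0)],
)
def test_round_half_up(value, expected):
    assert round_half_up(value) == expected
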