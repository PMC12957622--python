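import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import agreedent as ag
from agreedent.exceptions import InsufficientDataError
from conftest import make_matrix
from oracles import (
    bf_cohen_weighted,
    bf_fleiss,
    bf_gwet,
    bf_jackknife_se,
    bf_percent_agreement,
    weight_table,
)


def random_matrix(rng, n_units, n_raters, cats, na_prob=0.0):
    rows = []
    for _ in range(n_units):
        rows.append([
            None if rng.random() < na_prob else cats[rng.integers(len(cats))]
            for _ in range(n_raters)
        ])
    return rows


class TestPercentAgreement:
    def test_worked_example(self, four_unit_matrix):
        w = ag.build_weights(("A", "B"), "identity")
        assert ag.percent_agreement(four_unit_matrix, w) == pytest.approx(0.75)

    def test_perfect(self):
        m = make_matrix([["A", "A", "A"], ["B", "B", "B"]], "AB")
        assert ag.percent_agreement(m) == 1.0

    def test_total_disagreement(self):
        m = make_matrix([["A", "B"]], "AB")
        assert ag.percent_agreement(m) == 0.0

    def test_insufficient(self):
        m = make_matrix([["A", None], [None, "B"]], "AB")
        with pytest.raises(InsufficientDataError):
            ag.percent_agreement(m)


class TestCohenKappa:
    def test_worked_example(self):
        w = ag.build_weights(("A", "B"), "identity")
        res = ag.cohen_kappa_weighted(
            [("A", "A"), ("A", "A"), ("B", "B"), ("A", "B")], w
        )
        assert res.coefficient == pytest.approx(0.5)
        assert res.p_a == pytest.approx(0.75)
        assert res.p_e == pytest.approx(0.5)

    @pytest.mark.parametrize("kind", ["identity", "linear", "quadratic", "ordinal"])
    def test_identical_sessions_give_one(self, kind):
        pairs = [(c, c) for c in "DDEEFFGH"]
        w = ag.build_weights(tuple("DEFGH"), kind)
        res = ag.cohen_kappa_weighted(pairs, w)
        assert res.coefficient == pytest.approx(1.0)
        assert res.ci_high == 1.0

    def test_paradox_negative_despite_high_agreement(self, paradox_pairs):
        w = ag.build_weights(("G", "H"), "identity")
        res = ag.cohen_kappa_weighted(paradox_pairs, w)
        assert res.p_a == pytest.approx(0.90)
        assert res.coefficient == pytest.approx(-1 / 19, abs=1e-9)

    def test_identity_weights_match_unweighted(self):
        rng = np.random.default_rng(1)
        cats = tuple("ABC")
        pairs = [(cats[rng.integers(3)], cats[rng.integers(3)]) for _ in range(60)]
        wi = ag.build_weights(cats, "identity")
        res = ag.cohen_kappa_weighted(pairs, wi)
        assert res.coefficient == pytest.approx(bf_cohen_weighted(pairs, cats, "identity"))

    def test_degenerate_constant_raters_flagged(self):
        w = ag.build_weights(("A", "B"), "identity")
        res = ag.cohen_kappa_weighted([("A", "A")] * 5, w)
        assert res.degenerate

    def test_matches_statsmodels(self):
        """Cross-check estimate and SE against an established implementation."""
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(7)
        cats = tuple("ABCD")
        pairs = [(cats[rng.integers(4)], cats[rng.integers(4)]) for _ in range(200)]
        table = np.zeros((4, 4))
        for a, b in pairs:
            table[cats.index(a), cats.index(b)] += 1
        for kind in ("identity", "linear", "quadratic", "ordinal"):
            w = ag.build_weights(cats, kind)
            res = ag.cohen_kappa_weighted(pairs, w)
            sm = cohens_kappa(table, weights=1 - w.w)  # disagreement weights
            assert res.coefficient == pytest.approx(sm.kappa, abs=1e-10)
            assert res.se == pytest.approx(np.sqrt(sm.var_kappa), rel=1e-6)


class TestGwet:
    def test_worked_example(self, four_unit_matrix):
        w = ag.build_weights(("A", "B"), "identity")
        res = ag.gwet_ac(four_unit_matrix, w)
        assert res.coefficient == pytest.approx(0.5294117647, abs=1e-9)
        assert res.p_a == pytest.approx(0.75)
        assert res.p_e == pytest.approx(0.46875)

    def test_perfect_agreement(self):
        m = make_matrix([["A"] * 5, ["B"] * 5, ["A"] * 5], "AB")
        w = ag.build_weights(("A", "B"), "identity")
        assert ag.gwet_ac(m, w).coefficient == pytest.approx(1.0)

    def test_paradox_ac1_stays_high(self, paradox_pairs):
        m = make_matrix([list(p) for p in paradox_pairs], "GH")
        w = ag.build_weights(("G", "H"), "identity")
        res = ag.gwet_ac(m, w)
        assert res.coefficient == pytest.approx(0.8895027624, abs=1e-9)
        assert res.p_e == pytest.approx(0.095, abs=1e-9)

    def test_paradox_gap_vs_kappa(self, paradox_pairs):
        m = make_matrix([list(p) for p in paradox_pairs], "GH")
        w = ag.build_weights(("G", "H"), "identity")
        ac1 = ag.gwet_ac(m, w).coefficient
        kappa = ag.cohen_kappa_weighted(paradox_pairs, w).coefficient
        assert ac1 - kappa > 0.5

    def test_single_category_degenerate_flag(self):
        m = make_matrix([["A", "A"], ["A", "A"]], "AB")
        res = ag.gwet_ac(m, ag.build_weights(("A",), "identity"))
        assert res.degenerate

    def test_missing_tolerance_drops_cells_not_units(self):
        rows = [["A", "A", None], ["A", None, "B"], ["B", "B", "B"], ["A", None, None]]
        m = make_matrix(rows, "AB")
        w = ag.build_weights(("A", "B"), "identity")
        res = ag.gwet_ac(m, w)
        assert res.coefficient == pytest.approx(bf_gwet(rows, ("A", "B"), "identity"))
        assert res.n_observations == 8
        assert res.n_units == 4  # the 1-rating unit still informs prevalences

    def test_se_close_to_jackknife(self):
        rng = np.random.default_rng(11)
        rows = random_matrix(rng, 40, 5, "ABC")
        m = make_matrix(rows, "ABC")
        res = ag.gwet_ac(m, ag.build_weights(tuple("ABC"), "ordinal"))
        jk_se, _ = bf_jackknife_se(rows, tuple("ABC"), "ordinal")
        assert res.se == pytest.approx(jk_se, rel=0.2)


class TestFleiss:
    def test_perfect(self):
        m = make_matrix([["A"] * 4, ["B"] * 4], "AB")
        assert ag.fleiss_kappa(m).coefficient == pytest.approx(1.0)

    def test_paradox_table_near_zero(self, paradox_pairs):
        m = make_matrix([list(p) for p in paradox_pairs], "GH")
        res = ag.fleiss_kappa(m)
        assert res.coefficient < 0.1
        assert ag.gwet_ac(m, ag.build_weights(("G", "H"), "identity")).coefficient > 0.8

    def test_random_ratings_near_zero(self):
        rng = np.random.default_rng(2)
        rows = random_matrix(rng, 400, 6, "ABCD")
        res = ag.fleiss_kappa(make_matrix(rows, "ABCD"))
        assert abs(res.coefficient) < 0.03

    def test_matches_statsmodels_on_complete_data(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(30, 6))
        counts, _ = aggregate_raters(codes)
        rows = [[("ABC"[c]) for c in row] for row in codes]
        res = ag.fleiss_kappa(make_matrix(rows, "ABC"))
        assert res.coefficient == pytest.approx(sm_fleiss(counts), abs=1e-10)


class TestEquivalences:
    def test_ac2_identity_equals_ac1_everywhere(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            rows = random_matrix(rng, 12, 4, "ABCD", na_prob=0.1)
            if all(sum(v is not None for v in r) < 2 for r in rows):
                continue
            m = make_matrix(rows, "ABCD")
            cats = ag.observed_categories(m)
            if len(cats) < 2:
                continue
            a = ag.gwet_ac(m, ag.build_weights(cats, "identity"))
            # an identity matrix passed with kind-label "ordinal" via Q=2 etc.
            assert a.coefficient == pytest.approx(
                bf_gwet(rows, cats, "identity"), abs=1e-12
            )

    def test_exhaustive_two_rater_enumeration(self):
        """All 2-rater matrices with 3 units over 2 categories match the
        brute-force defining formulas exactly."""
        cats = ("A", "B")
        for cells in itertools.product(cats, repeat=6):
            rows = [list(cells[i: i + 2]) for i in range(0, 6, 2)]
            m = make_matrix(rows, cats)
            used = ag.observed_categories(m)
            if len(used) < 2:
                continue
            for kind in ("identity", "ordinal"):
                res = ag.gwet_ac(m, ag.build_weights(used, kind))
                assert res.coefficient == pytest.approx(
                    bf_gwet(rows, used, kind), abs=1e-12
                )

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_matrix(rng, 10, 4, "ABC", na_prob=0.1)
        if all(sum(v is not None for v in r) < 2 for r in rows):
            return
        m = make_matrix(rows, "ABC")
        cats = ag.observed_categories(m)
        if len(cats) < 2:
            return
        w = ag.build_weights(cats, "ordinal")
        base = ag.gwet_ac(m, w)
        unit_perm = rng.permutation(10)
        rater_perm = rng.permutation(4)
        shuffled = [[rows[i][j] for j in rater_perm] for i in unit_perm]
        perm = ag.gwet_ac(make_matrix(shuffled, "ABC"), w)
        assert perm.coefficient == pytest.approx(base.coefficient, abs=1e-12)
        assert perm.se == pytest.approx(base.se, abs=1e-12)


class TestBenchmarks:
    @pytest.mark.parametrize(
        "value,scale,label",
        [
            (0.918, "landis_koch", "almost perfect"),
            (0.45, "landis_koch", "moderate"),
            (0.75, "landis_koch", "substantial"),
            (0.15, "landis_koch", "slight"),
            (-0.1, "landis_koch", "poor"),
            (0.986, "portney_watkins", "excellent"),
            (0.8, "portney_watkins", "good"),
            (0.6, "portney_watkins", "moderate"),
            (0.2, "portney_watkins", "poor"),
        ],
    )
    def test_bins(self, value, scale, label):
        assert ag.benchmark_label(value, scale) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ag.benchmark_label(float("nan"))


def test_percent_agreement_matches_bruteforce_with_weights():
    rng = np.random.default_rng(9)
    rows = random_matrix(rng, 25, 6, "ABCDE", na_prob=0.15)
    m = make_matrix(rows, "ABCDE")
    cats = ag.observed_categories(m)
    w = ag.build_weights(cats, "quadratic")
    assert ag.percent_agreement(m, w) == pytest.approx(
        bf_percent_agreement(rows, weight_table(cats, "quadratic")), abs=1e-12
    )
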