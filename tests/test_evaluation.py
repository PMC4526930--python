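"""Ordinal agreement statistics: published-matrix values, oracles, properties."""

import numpy as np
import pytest

from triagekit import (
    ConfusionMatrix,
    ScorePair,
    agreement_report,
    build_confusion,
    interpret_kappa,
    kappa_bootstrap_ci,
    match_fraction,
    subgroup_matrix,
    table5_fixture,
    weighted_kappa,
)
from triagekit.errors import SchemaError, UndefinedKappaError


def oracle_kappa(counts, scheme, k=5):
    """Literal double-loop po/pe computation, independent of the package path."""
    n = sum(sum(row) for row in counts)
    rows = [sum(counts[i][j] for j in range(k)) for i in range(k)]
    cols = [sum(counts[i][j] for i in range(k)) for j in range(k)]

    def w(i, j):
        if scheme == "linear":
            return 1 - abs(i - j) / (k - 1)
        if scheme == "quadratic":
            return 1 - (i - j) ** 2 / (k - 1) ** 2
        return 1.0 if i == j else 0.0

    po = sum(w(i, j) * counts[i][j] for i in range(k) for j in range(k)) / n
    pe = sum(w(i, j) * rows[i] * cols[j] for i in range(k) for j in range(k)) / n**2
    return (po - pe) / (1 - pe)


def random_matrix(rng, max_count=20):
    m = rng.integers(0, max_count, size=(5, 5))
    if m.sum() == 0:
        m[0, 0] = 1
    return m.tolist()


class TestBuildConfusion:
    def test_counts_cells(self):
        pairs = [ScorePair(case_id="a", rater_a=1, rater_b=1),
                 ScorePair(case_id="b", rater_a=2, rater_b=1)]
        m = build_confusion(pairs)
        assert m.counts[0][0] == 1 and m.counts[1][0] == 1 and m.n == 2

    def test_empty_input_rejected(self):
        with pytest.raises(SchemaError):
            build_confusion([])

    def test_fixture_pairs_round_trip(self):
        fixture = table5_fixture()
        rebuilt = build_confusion(fixture.to_pairs())
        assert rebuilt.counts == fixture.counts
        assert rebuilt.n == 73


class TestWeightedKappa:
    def test_published_matrix_linear_scheme_reproduces_printed_value(self):
        res = weighted_kappa(table5_fixture(), "linear")
        assert round(res.kappa, 3) == 0.933
        # hand arithmetic: sum|i-j|*n_ij = 6, sum r_i c_j |i-j| = 6520
        assert res.po_weighted == pytest.approx(1 - 6 / (4 * 73))
        assert res.pe_weighted == pytest.approx(1 - 6520 / (4 * 73**2))
        assert res.band == "almost perfect"

    def test_published_matrix_quadratic_scheme_differs(self):
        # the quadratic formula does NOT give the printed statistic
        res = weighted_kappa(table5_fixture(), "quadratic")
        assert round(res.kappa, 3) == 0.947
        assert res.po_weighted == pytest.approx(72.375 / 73)
        assert res.pe_weighted == pytest.approx(4469 / 5329)

    @pytest.mark.parametrize("scheme", ["linear", "quadratic", "unweighted"])
    def test_perfect_diagonal_gives_one(self, scheme):
        m = ConfusionMatrix(counts=np.diag([3, 4, 5, 2, 1]).tolist())
        assert weighted_kappa(m, scheme).kappa == pytest.approx(1.0)

    @pytest.mark.parametrize("scheme", ["linear", "quadratic", "unweighted"])
    def test_independent_margins_give_zero(self, scheme):
        row = np.array([1, 2, 3, 2, 1])
        col = np.array([2, 1, 1, 3, 2])
        m = ConfusionMatrix(counts=np.outer(row, col).tolist())
        assert weighted_kappa(m, scheme).kappa == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_category_is_undefined(self):
        m = ConfusionMatrix(counts=[[7, 0, 0, 0, 0]] + [[0] * 5] * 4)
        with pytest.raises(UndefinedKappaError):
            weighted_kappa(m, "linear")

    def test_oracle_equivalence_on_random_matrices(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            counts = random_matrix(rng)
            m = ConfusionMatrix(counts=counts)
            for scheme in ("linear", "quadratic", "unweighted"):
                try:
                    got = weighted_kappa(m, scheme).kappa
                except UndefinedKappaError:
                    continue
                want = oracle_kappa(counts, scheme)
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12)
            checked += 1

    def test_agrees_with_independent_library_implementation(self):
        # cross-check against scikit-learn's Cohen kappa on expanded pairs
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(13)
        for _ in range(20):
            pairs = [
                ScorePair(case_id=str(i), rater_a=int(a), rater_b=int(b))
                for i, (a, b) in enumerate(
                    zip(rng.integers(1, 6, 60), rng.integers(1, 6, 60))
                )
            ]
            m = build_confusion(pairs)
            a = [p.rater_a for p in pairs]
            b = [p.rater_b for p in pairs]
            labels = [1, 2, 3, 4, 5]
            for scheme, w in [("linear", "linear"), ("quadratic", "quadratic")]:
                ours = weighted_kappa(m, scheme).kappa
                theirs = cohen_kappa_score(a, b, weights=w, labels=labels)
                assert ours == pytest.approx(theirs, rel=1e-10)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = random_matrix(rng)
            m = ConfusionMatrix(counts=counts)
            mt = ConfusionMatrix(counts=np.array(counts).T.tolist())
            for scheme in ("linear", "quadratic"):
                assert weighted_kappa(m, scheme).kappa == pytest.approx(
                    weighted_kappa(mt, scheme).kappa, rel=1e-12
                )

    def test_all_schemes_agree_when_offdiagonal_empty(self):
        m = ConfusionMatrix(counts=np.diag([1, 0, 2, 3, 1]).tolist())
        ks = [weighted_kappa(m, s).kappa for s in ("linear", "quadratic", "unweighted")]
        assert ks == pytest.approx([1.0, 1.0, 1.0])

    def test_moving_disagreement_further_off_diagonal_lowers_linear_po(self):
        near = [[5, 1, 0, 0, 0]] + [[0, 3, 0, 0, 0]] + [[0] * 5] * 3
        far = [[5, 0, 1, 0, 0]] + [[0, 3, 0, 0, 0]] + [[0] * 5] * 3
        po_near = weighted_kappa(ConfusionMatrix(counts=near), "linear").po_weighted
        po_far = weighted_kappa(ConfusionMatrix(counts=far), "linear").po_weighted
        assert po_far < po_near


class TestMatchFraction:
    def test_published_matrix(self):
        assert match_fraction(table5_fixture()) == pytest.approx(69 / 73)

    def test_diagonal_and_antidiagonal_extremes(self):
        diag = ConfusionMatrix(counts=np.diag([1, 2, 3, 4, 5]).tolist())
        # odd k: keep the centre cell empty so nothing lands on the diagonal
        anti = ConfusionMatrix(counts=np.fliplr(np.diag([1, 2, 0, 4, 5])).tolist())
        assert match_fraction(diag) == 1.0
        assert match_fraction(anti) == 0.0


class TestSubgroup:
    def test_high_acuity_subgroup_of_published_matrix(self):
        pairs = table5_fixture().to_pairs()
        sub = subgroup_matrix(pairs, {1, 2})
        assert sub.n == 41
        assert sub.counts[0][0] == 13 and sub.counts[0][1] == 1
        assert sub.counts[1][1] == 26 and sub.counts[3][1] == 1
        assert sub.trace == 39

    def test_all_levels_is_identity(self):
        pairs = table5_fixture().to_pairs()
        assert subgroup_matrix(pairs, {1, 2, 3, 4, 5}).counts == table5_fixture().counts

    def test_level_five_column(self):
        sub = subgroup_matrix(table5_fixture().to_pairs(), {5})
        assert sub.n == 7
        assert sub.counts[2][4] == 1 and sub.counts[4][4] == 6

    def test_subgroup_kappa_keeps_five_level_geometry(self):
        sub = subgroup_matrix(table5_fixture().to_pairs(), {1, 2})
        assert round(weighted_kappa(sub, "linear").kappa, 3) == 0.851


class TestBootstrapCI:
    def test_interval_contains_point_estimate_and_is_deterministic(self):
        pairs = table5_fixture().to_pairs()
        lo, hi = kappa_bootstrap_ci(pairs, "linear", B=2000, seed=5)
        point = weighted_kappa(table5_fixture(), "linear").kappa
        assert lo < point < hi
        assert (lo, hi) == kappa_bootstrap_ci(pairs, "linear", B=2000, seed=5)

    def test_monte_carlo_stability_between_resample_counts(self):
        pairs = table5_fixture().to_pairs()
        a = kappa_bootstrap_ci(pairs, "linear", B=2000, seed=9)
        b = kappa_bootstrap_ci(pairs, "linear", B=4000, seed=9)
        assert abs(a[0] - b[0]) < 0.02 and abs(a[1] - b[1]) < 0.02

    def test_degenerate_identical_pairs_is_undefined(self):
        pairs = [ScorePair(case_id=str(i), rater_a=2, rater_b=2) for i in range(10)]
        with pytest.raises(UndefinedKappaError):
            kappa_bootstrap_ci(pairs, "linear", B=200, seed=1)


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (0.93, "almost perfect"),
            (0.45, "moderate"),
            (-0.1, "no agreement"),
            (0.20, "slight"),
            (0.40, "fair"),
            (0.60, "moderate"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (0.0, "slight"),
            (1.0, "almost perfect"),
        ],
    )
    def test_band_cut_points(self, kappa, band):
        assert interpret_kappa(kappa) == band


class TestAgreementReport:
    def test_report_carries_both_schemes_and_subgroup(self):
        report = agreement_report(table5_fixture())
        assert report["overall"]["n"] == 73
        assert report["overall"]["matched"] == 69
        assert round(report["overall"]["kappa"]["linear"]["kappa"], 3) == 0.933
        assert round(report["overall"]["kappa"]["quadratic"]["kappa"], 3) == 0.947
        assert report["subgroup"]["n"] == 41
        assert report["subgroup"]["matched"] == 39
        assert round(report["subgroup"]["kappa"]["linear"]["kappa"], 3) == 0.851
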