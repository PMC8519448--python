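import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    bh_reference,
    exhaustive_survival,
    random_background,
    random_count_pwm,
    revcomp,
)
from hapmotif.motif_io import Background, PWM, pwm_to_probabilities
from hapmotif.scoring import (
    DegenerateMotifError,
    NonFiniteScoreError,
    PSSM,
    benjamini_hochberg,
    build_pssm,
    build_pvalue_table,
    reverse_complement_pssm,
    scale_pssm,
    score_kmer,
    unscale_score,
)


def _pssm_from_logodds(logodds):
    return PSSM("M", "M", np.asarray(logodds, dtype=float), Background.uniform())


def _random_spssm(rng, k):
    pwm = random_count_pwm(rng, k)
    probs = pwm_to_probabilities(pwm)
    return scale_pssm(build_pssm(probs))


class TestBuildPssm:
    def test_uniform_gives_zero_logodds(self):
        pwm = PWM("M", "M", np.full((4, 3), 0.25), is_probability=True)
        pssm = build_pssm(pwm)
        np.testing.assert_allclose(pssm.logodds, 0.0)

    def test_direct_formula_high(self):
        m = np.full((4, 1), 0.01)
        m[0, 0] = 0.97
        pssm = build_pssm(PWM("M", "M", m, is_probability=True))
        assert pssm.logodds[0, 0] == pytest.approx(np.log2(3.88), abs=1e-6)

    def test_direct_formula_low(self):
        m = np.full((4, 1), (1 - 0.0025) / 3)
        m[2, 0] = 0.0025
        pssm = build_pssm(PWM("M", "M", m, is_probability=True))
        assert pssm.logodds[2, 0] == pytest.approx(np.log2(0.01), abs=1e-6)

    def test_zero_cell_errors(self):
        m = np.array([[0.5], [0.5], [0.0], [0.0]])
        with pytest.raises(NonFiniteScoreError, match="pseudocount"):
            build_pssm(PWM("M", "M", m, is_probability=True))

    def test_counts_rejected(self):
        with pytest.raises(ValueError):
            build_pssm(PWM("M", "M", np.ones((4, 2))))


class TestScalePssm:
    def test_single_column_full_range(self):
        sp = scale_pssm(_pssm_from_logodds([[2.0], [0.0], [0.0], [0.0]]))
        np.testing.assert_array_equal(sp.int_matrix[:, 0], [1000, 0, 0, 0])
        assert sp.scale == pytest.approx(500.0)
        assert sp.offsets[0] == 0.0
        assert sp.max_total == 1000

    def test_two_columns_split_by_range(self):
        # column ranges 1.0 and 3.0 -> scale 250; maxima map to 250 and 750
        sp = scale_pssm(
            _pssm_from_logodds([[1.0, 3.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        )
        assert sp.scale == pytest.approx(250.0)
        assert sp.int_matrix[0, 0] == 250
        assert sp.int_matrix[0, 1] == 750
        assert sp.max_total == 1000

    def test_uniform_motif_degenerate(self):
        with pytest.raises(DegenerateMotifError):
            scale_pssm(_pssm_from_logodds(np.zeros((4, 3))))

    def test_negative_offsets_absorbed(self):
        sp = scale_pssm(
            _pssm_from_logodds([[1.0, -0.5], [-2.0, 1.5], [0.0, 0.0], [0.0, 0.0]])
        )
        assert sp.int_matrix.min() >= 0
        assert sp.max_total <= 1000

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 12))
    def test_all_scores_within_range(self, seed, k):
        rng = np.random.default_rng(seed)
        sp = _random_spssm(rng, k)
        assert np.all(sp.int_matrix >= 0)
        assert 0 < sp.max_total <= 1000
        # max/min attainable totals are the columnwise extrema sums
        assert int(sp.int_matrix.min(axis=0).sum()) == 0


class TestScoreKmer:
    def test_consensus_scores_max_total(self, rng):
        sp = _random_spssm(rng, 6)
        consensus = "".join("ACGT"[i] for i in np.argmax(sp.int_matrix, axis=0))
        assert score_kmer(sp, consensus) == sp.max_total

    def test_anticonsensus_scores_zero(self, rng):
        sp = _random_spssm(rng, 6)
        worst = "".join("ACGT"[i] for i in np.argmin(sp.int_matrix, axis=0))
        assert score_kmer(sp, worst) == 0

    def test_n_contributes_column_minimum(self, rng):
        sp = _random_spssm(rng, 2)
        assert score_kmer(sp, "AN") == int(sp.int_matrix[0, 0]) + int(
            sp.int_matrix[:, 1].min()
        )

    def test_case_insensitive(self, rng):
        sp = _random_spssm(rng, 3)
        assert score_kmer(sp, "acg") == score_kmer(sp, "ACG")

    def test_wrong_length(self, rng):
        sp = _random_spssm(rng, 3)
        with pytest.raises(ValueError, match="length"):
            score_kmer(sp, "ACGT")

    def test_bad_character(self, rng):
        sp = _random_spssm(rng, 3)
        with pytest.raises(ValueError, match="non-nucleotide"):
            score_kmer(sp, "AXG")


class TestUnscale:
    def test_zero_gives_offset_sum(self, rng):
        sp = _random_spssm(rng, 5)
        assert unscale_score(sp, 0) == pytest.approx(float(sp.offsets.sum()))

    def test_out_of_range_rejected(self, rng):
        sp = _random_spssm(rng, 3)
        with pytest.raises(ValueError):
            unscale_score(sp, 1001)

    @pytest.mark.parametrize("k", [2, 5, 8])
    def test_roundtrip_against_direct_logodds(self, k):
        rng = np.random.default_rng(k)
        pwm = random_count_pwm(rng, k)
        probs = pwm_to_probabilities(pwm)
        pssm = build_pssm(probs)
        sp = scale_pssm(pssm)
        tol = k / (2 * sp.scale) + 1e-9
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=k))
            direct = float(
                sum(pssm.logodds["ACGT".index(c), i] for i, c in enumerate(seq))
            )
            assert abs(unscale_score(sp, score_kmer(sp, seq)) - direct) <= tol

    def test_max_total_within_rounding_of_true_maximum(self):
        rng = np.random.default_rng(7)
        pwm = random_count_pwm(rng, 6)
        pssm = build_pssm(pwm_to_probabilities(pwm))
        sp = scale_pssm(pssm)
        true_max = float(pssm.logodds.max(axis=0).sum())
        tol = sp.width / (2 * sp.scale) + 1e-9
        assert abs(unscale_score(sp, sp.max_total) - true_max) <= tol


class TestPValueTable:
    def test_single_draw(self):
        sp = scale_pssm(_pssm_from_logodds([[2.0], [0.0], [0.0], [0.0]]))
        table = build_pvalue_table(sp)
        assert table.survival[1000] == pytest.approx(0.25)
        assert table.survival[0] == pytest.approx(1.0)

    def test_two_independent_columns(self):
        sp = scale_pssm(
            _pssm_from_logodds([[1.0, 1.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        )
        table = build_pvalue_table(sp)
        assert table.pvalue(sp.max_total) == pytest.approx(1 / 16)

    def test_three_column_exhaustive_oracle(self, rng):
        sp = _random_spssm(rng, 3)
        bg = random_background(rng)
        table = build_pvalue_table(sp, bg)
        oracle = exhaustive_survival(sp.int_matrix, bg.as_array())
        np.testing.assert_allclose(
            table.survival[: sp.max_total + 1],
            oracle,
            atol=1e-12,
        )

    def test_pmf_sums_to_one(self, rng):
        sp = _random_spssm(rng, 7)
        table = build_pvalue_table(sp)
        assert table.pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(table.survival) <= 1e-15)


class TestBenjaminiHochberg:
    def test_singleton_identity(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_hand_evaluated_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_all_equal(self):
        q = benjamini_hochberg([0.2] * 5)
        np.testing.assert_allclose(q, 0.2)

    def test_input_order_preserved(self):
        p = [0.5, 0.01, 0.02]
        q = benjamini_hochberg(p)
        assert q[1] <= q[2] <= q[0]

    def test_domain_error(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([])

    @settings(max_examples=60, deadline=None)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60)
    )
    def test_properties_and_statsmodels_agreement(self, p):
        q = benjamini_hochberg(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        np.testing.assert_allclose(q, bh_reference(p), atol=1e-12)


class TestReverseComplement:
    def test_double_application_identity(self, rng):
        sp = _random_spssm(rng, 5)
        back = reverse_complement_pssm(reverse_complement_pssm(sp))
        np.testing.assert_array_equal(back.int_matrix, sp.int_matrix)
        np.testing.assert_array_equal(back.offsets, sp.offsets)

    def test_scores_reverse_complement(self, rng):
        sp = _random_spssm(rng, 6)
        rc = reverse_complement_pssm(sp)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=6))
            assert score_kmer(rc, seq) == score_kmer(sp, revcomp(seq))

    def test_palindromic_matrix_fixed_point(self):
        # column i is the complement of column k+1-i
        m = np.array(
            [[5, 0, 1, 2], [1, 3, 4, 0], [0, 4, 3, 1], [2, 1, 0, 5]], dtype=float
        )
        sp = scale_pssm(_pssm_from_logodds(m))
        rc = reverse_complement_pssm(sp)
        np.testing.assert_array_equal(rc.int_matrix, sp.int_matrix)
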