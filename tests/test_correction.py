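"""Core correction: kernel, forward contamination, sweeps, refinement."""

import math

import numpy as np
import pytest
from scipy.linalg import solve_triangular

from nacorr.correction import (
    LabelOrder,
    NACorrector,
    add_na,
    correct,
    iterate_upto,
    solve_pass,
)
from nacorr.isotopes import DEFAULT_ISOTOPES, IsotopeSpec
from nacorr.synthetic import SIMULATED_CARBON9, SIMULATED_NITROGEN6

from conftest import UDP_GLCNAC_CORRECTED, UDP_GLCNAC_NC


def dense_kernel_matrix(corrector: NACorrector) -> np.ndarray:
    """Independent brute-force kernel matrix over flattened C-order indices.

    Componentwise dominance implies lexicographic order, so the matrix is
    lower triangular; correction is then one generic triangular solve.
    """
    shape = tuple(m + 1 for m in corrector.maxima)
    cells = list(np.ndindex(*shape))
    size = len(cells)
    M = np.zeros((size, size))
    for xi, x in enumerate(cells):
        for ii, i in enumerate(cells):
            if all(a <= b for a, b in zip(i, x)):
                M[xi, ii] = corrector.kernel(x, i)
    return M


class TestIterateUpto:
    def test_penultimate_excludes_bound(self):
        assert set(iterate_upto((1, 1))) == {(0, 0), (0, 1), (1, 0)}

    def test_ultimate_includes_bound(self):
        assert set(iterate_upto((1, 1), inclusive=True)) == {
            (0, 0), (0, 1), (1, 0), (1, 1),
        }

    def test_one_dimensional_degenerates_to_range(self):
        assert [i[0] for i in iterate_upto((5,))] == list(range(5))

    def test_dominance_only_by_later_tuples(self):
        seen = list(iterate_upto((2, 3), inclusive=True))
        for pos, x in enumerate(seen):
            for i in seen[pos + 1:]:
                assert not all(a <= b for a, b in zip(i, x)) or i == x


class TestKernel:
    def test_one_heavy_gain_matches_oracle(self, c13):
        # 17-carbon molecule, 5 labels: 12 unlabeled carbons, one heavy
        corr = NACorrector((17,), LabelOrder((c13,)))
        p = c13.p
        expected = math.comb(12, 1) * p * (1 - p) ** 11
        assert corr.kernel((6,), (5,)) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(0.11772, abs=5e-6)

    def test_diagonal_equals_survival_product(self, c13, n15):
        corr = NACorrector((9, 6), LabelOrder((c13, n15)))
        for x in [(0, 0), (3, 2), (9, 6)]:
            expected = corr.stables[0][x[0]] * corr.stables[1][x[1]]
            assert corr.kernel(x, x) == pytest.approx(expected, rel=1e-15)

    def test_kernel_factorizes_across_dimensions(self, c13, n15):
        corr2 = NACorrector((9, 6), LabelOrder((c13, n15)))
        corr_c = NACorrector((9,), LabelOrder((c13,)))
        corr_n = NACorrector((6,), LabelOrder((n15,)))
        assert corr2.kernel((4, 3), (2, 1)) == pytest.approx(
            corr_c.kernel((4,), (2,)) * corr_n.kernel((3,), (1,)), rel=1e-15
        )

    def test_rejects_non_dominated_index(self, c13):
        corr = NACorrector((9,), LabelOrder((c13,)))
        with pytest.raises(ValueError):
            corr.kernel((3,), (4,))


class TestAddNA:
    def test_carbon9_contamination_matches_printed_row(self, c13):
        out = add_na(SIMULATED_CARBON9, LabelOrder((c13,)))
        expected_4dp = [0.4523, 0.0456, 0.0020, 0.1403, 0.1040, 0.0056]
        assert np.allclose(out[:6], expected_4dp, atol=5e-5)
        assert out[6] == pytest.approx(1.2e-4, abs=5e-6)
        assert out[7] == pytest.approx(1.4e-6, abs=5e-8)
        assert out[8] == pytest.approx(7.6e-9, abs=5e-10)
        assert out[9] == pytest.approx(0.25, abs=5e-5)

    def test_nitrogen6_contamination_matches_printed_row(self, n15):
        out = add_na(SIMULATED_NITROGEN6, LabelOrder((n15,)))
        assert np.allclose(
            out[:5], [0.4890, 0.0109, 0.0001, 0.0989, 0.0011], atol=5e-5
        )
        assert out[5] == pytest.approx(4e-6, abs=5e-7)
        assert out[6] == pytest.approx(0.4, abs=5e-5)

    @pytest.mark.parametrize("seed,shape", [(0, (14,)), (1, (5, 4)), (2, (4, 3, 3))])
    def test_total_intensity_conserved(self, seed, shape):
        rng = np.random.default_rng(seed)
        clean = rng.random(shape) * 100
        isos = _order_for(len(shape))
        out = add_na(clean, isos)
        assert out.sum() == pytest.approx(clean.sum(), rel=1e-12)
        assert np.all(out >= 0)

    def test_zero_abundance_is_identity(self):
        iso = IsotopeSpec("13C", "C", 0.0)
        clean = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(add_na(clean, LabelOrder((iso,))), clean)


def _order_for(ndim):
    isos = [DEFAULT_ISOTOPES["13C"], DEFAULT_ISOTOPES["15N"], DEFAULT_ISOTOPES["2H"]]
    return LabelOrder(tuple(isos[:ndim]))


class TestSolvePass:
    def test_single_sweep_reproduces_printed_corrections(
        self, c13, udp_glcnac_vector
    ):
        out = solve_pass(udp_glcnac_vector, LabelOrder((c13,)))
        for count, expected in UDP_GLCNAC_CORRECTED.items():
            assert out[count] == pytest.approx(expected, abs=0.02)

    def test_oversubtracted_peak_clamps_to_zero(self, c13, udp_glcnac_vector):
        out = solve_pass(udp_glcnac_vector, LabelOrder((c13,)))
        assert out[9] == 0.0
        signed = solve_pass(udp_glcnac_vector, LabelOrder((c13,)), clamp=False)
        assert signed[9] < 0.0  # the clamp is what zeroes it

    @pytest.mark.parametrize("seed,shape", [(3, (12,)), (4, (4, 5))])
    def test_exact_inverse_of_add_na_when_nothing_clamps(self, seed, shape):
        rng = np.random.default_rng(seed)
        clean = rng.random(shape) + 0.1  # strictly positive: no clamping
        order = _order_for(len(shape))
        recovered = solve_pass(add_na(clean, order), order)
        assert np.allclose(recovered, clean, rtol=1e-10)


class TestCorrect:
    def test_printed_single_label_dataset(self, c13, udp_glcnac_vector):
        res = correct(udp_glcnac_vector, LabelOrder((c13,)))
        for count, expected in UDP_GLCNAC_CORRECTED.items():
            assert res.corrected[count] == pytest.approx(expected, abs=0.02)
        assert res.corrected[9] == 0.0
        assert np.all(res.corrected >= 0)
        assert np.allclose(
            res.reconstructed,
            add_na(res.corrected, LabelOrder((c13,))),
            rtol=1e-12,
        )

    def test_outer_product_multi_isotope_roundtrip(self, c13, n15):
        tainted_c = add_na(SIMULATED_CARBON9, LabelOrder((c13,)))
        tainted_n = add_na(SIMULATED_NITROGEN6, LabelOrder((n15,)))
        res = correct(np.outer(tainted_c, tainted_n), LabelOrder((c13, n15)))
        clean = np.outer(SIMULATED_CARBON9, SIMULATED_NITROGEN6)
        assert np.max(np.abs(res.corrected - clean)) <= 1e-16

    @pytest.mark.parametrize(
        "seed,shape",
        [(10, (12,)), (11, (17,)), (12, (4, 5)), (13, (9, 6)), (14, (4, 3, 3))],
    )
    def test_matches_generic_triangular_solve(self, seed, shape):
        # independent oracle: brute-force dense kernel matrix + scipy
        # triangular solve; valid when nothing clamps (positive clean)
        rng = np.random.default_rng(seed)
        clean = rng.random(shape) + 0.05
        order = _order_for(len(shape))
        corrector = NACorrector(tuple(s - 1 for s in shape), order)
        data = corrector.add_na(clean)
        M = dense_kernel_matrix(corrector)
        oracle = solve_triangular(M, data.ravel(), lower=True).reshape(shape)
        res = corrector.correct(data)
        assert np.allclose(res.corrected, oracle, rtol=1e-9)

    @pytest.mark.parametrize(
        "seed,shape", [(20, (10,)), (21, (6, 4)), (22, (3, 3, 4))]
    )
    def test_recovers_seeded_sparse_clean_arrays(self, seed, shape):
        rng = np.random.default_rng(seed)
        clean = rng.random(shape) * (rng.random(shape) < 0.4)
        clean.flat[0] = 0.3  # ensure mass at the origin
        order = _order_for(len(shape))
        res = correct(add_na(clean, order), order)
        rel_err = np.abs(res.corrected - clean).sum() / clean.sum()
        assert rel_err <= 1e-8
        assert res.residual <= 1e-10 * clean.sum()

    def test_dimension_order_consistency(self, c13, n15):
        rng = np.random.default_rng(30)
        data = rng.random((10, 7))
        res_cn = correct(data, LabelOrder((c13, n15)))
        res_nc = correct(data.T, LabelOrder((n15, c13)))
        assert np.allclose(res_cn.corrected, res_nc.corrected.T, rtol=1e-12, atol=0)

    def test_one_dimensional_fast_path_matches_general_path(self, c13):
        # the 1-D sweep uses flat indexing; replay the general tuple-based
        # sweep by hand and require identical floating-point results
        rng = np.random.default_rng(31)
        data = rng.random(15) * 50
        corrector = NACorrector((14,), LabelOrder((c13,)))
        fast = corrector.solve_pass(data)
        general = np.zeros_like(data)
        for x in iterate_upto((14,), inclusive=True):
            acc = data[x]
            for i in iterate_upto(x):
                acc -= general[i] * corrector.kernel(x, i)
            general[x] = max(acc / corrector.stables[0][x[0]], 0.0)
        assert np.array_equal(fast, general)
        fast_fwd = corrector.add_na(data)
        general_fwd = np.zeros_like(data)
        for x in iterate_upto((14,), inclusive=True):
            acc = 0.0
            for i in iterate_upto(x, inclusive=True):
                acc += data[i] * corrector.kernel(x, i)
            general_fwd[x] = acc
        assert np.array_equal(fast_fwd, general_fwd)

    def test_zero_abundance_isotopes_return_data_in_one_cycle(self):
        isos = LabelOrder((IsotopeSpec("13C", "C", 0.0), IsotopeSpec("15N", "N", 0.0)))
        data = np.arange(12, dtype=float).reshape(4, 3)
        res = correct(data, isos)
        assert np.array_equal(res.corrected, data)
        assert res.iterations == 1
        assert res.residual == 0.0

    def test_error_strictly_decreases_to_returned_iterate(self, c13, n15):
        # the returned residual is the minimum over visited iterates:
        # re-running with fewer allowed cycles can never do better
        rng = np.random.default_rng(33)
        clean = rng.random((10, 7)) * (rng.random((10, 7)) < 0.3)
        clean[0, 0] = 0.5
        order = LabelOrder((c13, n15))
        data = add_na(clean, order)
        res_full = correct(data, order)
        res_one = correct(data, order, max_iterations=1)
        assert res_full.residual <= res_one.residual

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -1.0])
    def test_rejects_nonfinite_or_negative_input(self, c13, bad):
        data = np.ones(5)
        data[2] = bad
        with pytest.raises(ValueError):
            correct(data, LabelOrder((c13,)))

    def test_shape_order_mismatch_rejected(self, c13, n15):
        with pytest.raises(ValueError):
            NACorrector((9,), LabelOrder((c13, n15)))
        with pytest.raises(ValueError):
            LabelOrder((c13, IsotopeSpec("14C", "C", 0.01)))
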