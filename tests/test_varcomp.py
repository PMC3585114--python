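"""Variance decomposition against closed forms and the regression oracle."""

import numpy as np
import pytest

from epistasim.dynamics import HaplotypeState
from epistasim.gpmaps import GPMap
from epistasim.varcomp import (
    genotype_distribution,
    joint_additive_variance,
    marginal_additive_variance,
    marginal_genotype_values,
    noia_decomposition,
    regression_oracle,
    variance_components,
)

HWE_HALF = np.array([0.25, 0.5, 0.25])

RECESSIVE_A = GPMap([[1, 1, 1], [1, 1, 1], [0, 0, 0]], label="locus-A recessive")


class TestGenotypeDistribution:
    def test_le_gives_hwe_products(self, le_state):
        dist = genotype_distribution(le_state)
        expected = np.outer(HWE_HALF, HWE_HALF)
        np.testing.assert_allclose(dist.freqs, expected, atol=1e-15)
        assert dist.freqs[1, 1] == pytest.approx(0.25)

    def test_complete_coupling(self):
        s = HaplotypeState(np.array([0.5, 0.0, 0.0, 0.5]))
        dist = genotype_distribution(s)
        assert dist.freqs[0, 0] == pytest.approx(0.25)
        assert dist.freqs[1, 1] == pytest.approx(0.5)
        assert dist.freqs[2, 2] == pytest.approx(0.25)
        assert dist.freqs.sum() == pytest.approx(1.0)

    def test_marginals_are_single_locus_hwe(self, coupled_state):
        dist = genotype_distribution(coupled_state)
        p = coupled_state.pA
        np.testing.assert_allclose(
            dist.marginal_A, [p * p, 2 * p * (1 - p), (1 - p) ** 2], atol=1e-15
        )


class TestMarginalValues:
    def test_axa_at_le_flat(self, axa_map, le_state):
        vA, vB = marginal_genotype_values(axa_map, le_state)
        np.testing.assert_allclose(vA, 0.5)
        np.testing.assert_allclose(vB, 0.5)

    def test_additive_row_means(self, additive_map, le_state):
        vA, _ = marginal_genotype_values(additive_map, le_state)
        np.testing.assert_allclose(vA, [0.75, 0.5, 0.25])

    def test_coupled_gametes_read_diagonal(self, axa_map):
        s = HaplotypeState(np.array([0.5, 0.0, 0.0, 0.5]))
        vA, _ = marginal_genotype_values(axa_map, s)
        np.testing.assert_allclose(vA, [1.0, 0.5, 1.0])


class TestMarginalAdditiveVariance:
    def test_closed_form(self):
        VA, alpha = marginal_additive_variance(np.array([0.75, 0.5, 0.25]), 0.5)
        assert alpha == pytest.approx(0.25)
        assert VA == pytest.approx(0.03125)

    def test_flat_values_no_variance(self):
        VA, _ = marginal_additive_variance(np.array([0.5, 0.5, 0.5]), 0.3)
        assert VA == 0.0

    def test_symmetric_overdominance_zero_at_half(self):
        VA, alpha = marginal_additive_variance(np.array([0.0, 1.0, 0.0]), 0.5)
        assert alpha == 0.0
        assert VA == 0.0


class TestRegressionOracle:
    def test_axa_at_le(self, axa_map, le_state):
        VA, VG = regression_oracle(axa_map, genotype_distribution(le_state))
        assert VA == pytest.approx(0.0, abs=1e-12)
        assert VG == pytest.approx(0.0625)

    def test_additive_exact_fit(self, additive_map, le_state):
        VA, VG = regression_oracle(additive_map, genotype_distribution(le_state))
        assert VA == pytest.approx(0.0625)
        assert VG == pytest.approx(0.0625)

    def test_recessive_single_locus_split(self, le_state):
        VA, VG = regression_oracle(RECESSIVE_A, genotype_distribution(le_state))
        assert VG == pytest.approx(0.1875)
        assert VA == pytest.approx(0.125)


class TestJointAdditiveVariance:
    def test_le_equals_sum_of_marginals(self, additive_map, le_state):
        assert joint_additive_variance(additive_map, le_state) == pytest.approx(0.0625)

    def test_matches_regression_oracle_under_ld(self, coupled_state, catalogue):
        for entry in catalogue[::5]:
            if entry.gpmap.is_constant:
                continue
            got = joint_additive_variance(entry.gpmap, coupled_state)
            want, _ = regression_oracle(
                entry.gpmap, genotype_distribution(coupled_state)
            )
            assert got == pytest.approx(want, abs=1e-10)


class TestNOIA:
    def test_axa_pure_interaction(self, axa_map):
        vc = noia_decomposition(axa_map, HWE_HALF, HWE_HALF)
        assert vc.VAA == pytest.approx(0.0625)
        assert vc.VG == pytest.approx(0.0625)
        for name in ("VA1", "VD1", "VA2", "VD2", "VAD", "VDA", "VDD"):
            assert getattr(vc, name) == pytest.approx(0.0, abs=1e-12)

    def test_recessive_single_locus(self):
        vc = noia_decomposition(RECESSIVE_A, HWE_HALF, HWE_HALF)
        assert vc.VA1 == pytest.approx(0.125)
        assert vc.VD1 == pytest.approx(0.0625)
        for name in ("VA2", "VD2", "VAA", "VAD", "VDA", "VDD"):
            assert getattr(vc, name) == pytest.approx(0.0, abs=1e-12)

    def test_components_sum_to_vg_across_catalogue(self, catalogue):
        for entry in catalogue:
            vc = noia_decomposition(entry.gpmap, HWE_HALF, HWE_HALF)
            assert vc.component_sum == pytest.approx(vc.VG, abs=1e-10)

    def test_orthogonal_at_non_hwe_frequencies(self, axa_map):
        wA = np.array([0.3, 0.4, 0.3])
        wB = np.array([0.1, 0.2, 0.7])
        vc = noia_decomposition(axa_map, wA, wB)
        assert vc.component_sum == pytest.approx(vc.VG, abs=1e-10)

    def test_monomorphic_locus_rejected(self, axa_map):
        with pytest.raises(ValueError):
            noia_decomposition(axa_map, np.array([1.0, 0.0, 0.0]), HWE_HALF)


class TestInvariances:
    def test_shift_invariance_and_quadratic_scaling(self, coupled_state):
        m = GPMap([[1, 0.2, 0], [0.7, 0.5, 0.1], [0, 0.9, 1]])
        base = variance_components(m, coupled_state)
        shifted = variance_components(GPMap(m.values + 5.0), coupled_state)
        scaled = variance_components(GPMap(3.0 * m.values), coupled_state)
        for name, val in base.as_dict().items():
            if name.startswith("alpha"):
                continue
            assert getattr(shifted, name) == pytest.approx(val, abs=1e-10)
            assert getattr(scaled, name) == pytest.approx(9.0 * val, abs=1e-9)

    def test_le_va_joint_equals_noia_marginal_additive(self, catalogue, le_state):
        for entry in catalogue[::5]:
            vc = variance_components(entry.gpmap, le_state)
            assert vc.VA_joint == pytest.approx(vc.VA1 + vc.VA2, abs=1e-10)

    def test_vg_nonnegative_along_trajectories(self, catalogue):
        from epistasim.dynamics import run_deterministic

        for entry in catalogue[5:56:17]:
            traj = run_deterministic(entry.gpmap, (0.5, 0.5, 0.0), max_gen=50)
            for s in traj.states:
                if not (0 < s.pA < 1 and 0 < s.pB < 1):
                    break
                vc = variance_components(entry.gpmap, s)
                assert vc.VG >= -1e-12
                want, _ = regression_oracle(entry.gpmap, genotype_distribution(s))
                assert vc.VA_joint == pytest.approx(want, abs=1e-10)
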