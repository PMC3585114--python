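"""Expected-F detection rules and the 1D/2D power trade-off."""

import pytest

from epistasim.dynamics import state_from_allele_freqs
from epistasim.gpmaps import GPMap
from epistasim.power import (
    StudyDesign,
    TestSpec,
    detect,
    detect_1d,
    detect_2d,
    environmental_variance,
    expected_F,
    f_critical,
)
from epistasim.varcomp import variance_components

RECESSIVE_A = GPMap([[1, 1, 1], [1, 1, 1], [0, 0, 0]])


class TestEnvironmentalVariance:
    @pytest.mark.parametrize(
        "VG0, H2, expected",
        [(0.0625, 0.5, 0.0625), (0.42, 1.0, 0.0), (0.1, 0.25, 0.3)],
    )
    def test_closed_form(self, VG0, H2, expected):
        assert environmental_variance(VG0, H2) == pytest.approx(expected)

    def test_h2_out_of_range(self):
        with pytest.raises(ValueError):
            environmental_variance(0.1, 0.0)


class TestExpectedF:
    def test_zero_model_variance(self):
        assert expected_F(0.0, 1.0, 1000, 1) == 0.0

    def test_half_variance_full_model(self):
        assert expected_F(0.5, 1.0, 1000, 8) == pytest.approx(123.875)

    def test_small_fraction_one_df(self):
        assert expected_F(0.05, 1.0, 1000, 1) == pytest.approx(0.05 / 0.95 * 998)

    def test_model_exceeding_phenotypic_variance_rejected(self):
        with pytest.raises(ValueError):
            expected_F(1.0, 1.0, 1000, 1)


class TestFCritical:
    def test_chi2_limits(self):
        assert f_critical(0.05, 1, 10**6) == pytest.approx(3.8415, abs=1e-3)
        assert f_critical(0.05, 2, 10**6) == pytest.approx(2.9957, abs=1e-3)

    def test_monotone_in_alpha(self):
        crits = [f_critical(a, 4, 1000) for a in (0.1, 0.01, 1e-4, 1e-8)]
        assert crits == sorted(crits)


class TestDetection:
    def test_axa_equilibrium_invisible_to_1d(self, axa_map, le_state):
        vc = variance_components(axa_map, le_state)
        design = StudyDesign(n=100000)
        for param in ("A", "AD"):
            res = detect_1d(vc, design, param)
            assert res.detected_VA == 0.0
            assert not any(res.significant)

    def test_axa_equilibrium_visible_to_2d(self, axa_map, le_state):
        vc = variance_components(axa_map, le_state)
        design = StudyDesign(n=5000)
        for param, v_model in [("marginal", 0.0), ("epistatic", 0.0625), ("full", 0.0625)]:
            res = detect_2d(vc, design, param)
            if v_model == 0.0:
                assert not res.significant[0]
            else:
                assert res.significant[0]

    def test_ad_model_variance_dominates_a(self, le_state):
        vc = variance_components(RECESSIVE_A, le_state)
        design = StudyDesign(n=5000)
        res_a = detect_1d(vc, design, "A")
        res_ad = detect_1d(vc, design, "AD")
        # AD's model variance strictly contains A's; with k=2 the F need
        # not be larger, but the modelled variance is
        assert vc.VA1 + vc.VD1 > vc.VA1

    def test_both_loci_significant_credits_joint_va(self, additive_map, le_state):
        vc = variance_components(additive_map, le_state)
        res = detect_1d(vc, StudyDesign(n=5000), "A")
        assert all(res.significant)
        assert res.detected_VA == pytest.approx(vc.VA_joint)

    def test_detected_is_zero_or_joint_for_2d(self, catalogue, le_state):
        design = StudyDesign(n=2000)
        for entry in catalogue[::8]:
            if entry.gpmap.is_constant:
                continue
            vc = variance_components(entry.gpmap, le_state)
            res = detect_2d(vc, design, "full")
            assert res.detected_VA in (0.0, pytest.approx(vc.VA_joint))

    def test_strategy_parameterisation_pairing_enforced(self, axa_map, le_state):
        vc = variance_components(axa_map, le_state)
        with pytest.raises(ValueError):
            detect_1d(vc, StudyDesign(), "full")
        with pytest.raises(ValueError):
            detect_2d(vc, StudyDesign(), "A")

    def test_detected_never_exceeds_joint_additive(self, catalogue, coupled_state):
        design = StudyDesign(n=5000)
        for entry in catalogue[::6]:
            if entry.gpmap.is_constant:
                continue
            vc = variance_components(entry.gpmap, coupled_state)
            for spec in (TestSpec("A"), TestSpec("AD"), TestSpec("full")):
                res = detect(vc, design, spec)
                assert res.detected_VA <= vc.VA_joint + 1e-12


class TestPowerTradeOff:
    def test_full_vs_1d_crossover_in_sample_size(self, axa_map):
        """The multiple-testing penalty creates a regime where the 2D full
        test detects the AxA system but 1D tests cannot, and a small-n
        regime where neither detects anything; scanning n locates the
        crossover the trade-off implies."""
        # slightly perturbed frequencies so the 1D tests see *some*
        # marginal variance
        state = state_from_allele_freqs(0.6, 0.6, 0.0)
        vc = variance_components(axa_map, state)
        full_only = one_d_only = False
        for n in (100, 300, 1000, 3000, 10000, 30000, 100000, 10**6):
            design = StudyDesign(n=n)
            got_full = detect_2d(vc, design, "full").detected_VA > 0
            got_1d = detect_1d(vc, design, "AD").detected_VA > 0
            if got_full and not got_1d:
                full_only = True
            if got_1d:
                one_d_only = True
        assert full_only, "2D full should win at intermediate n"
        assert one_d_only, "1D should eventually detect at large n"


class TestComponentSweepEquivalence:
    def test_vectorised_accounting_matches_per_record_detection(self, catalogue):
        """power_from_components must agree with calling detect() on every
        generation record individually."""
        from epistasim.power import (
            component_sweep,
            environmental_variance,
            power_from_components,
        )
        from epistasim.varcomp import VarianceComponents

        subset = [catalogue[i] for i in (0, 5, 21, 51, 55)]
        grid = [(0.3, 0.5), (0.5, 0.5), (0.7, 0.9)]
        comp = component_sweep(subset, freq_grid=grid, r2_grid=[1.0, 0.6], max_gen=60)
        design = StudyDesign(n=1200, H2=0.2)
        tests = [TestSpec("A"), TestSpec("AD"), TestSpec("marginal"), TestSpec("epistatic"), TestSpec("full")]
        fast = power_from_components(comp, design, tests)

        slow = {}
        for rec in comp.itertuples(index=False):
            vc = VarianceComponents(
                VA1=rec.VA1, VD1=rec.VD1, VA2=rec.VA2, VD2=rec.VD2,
                VAA=rec.VAA, VAD=rec.VAD, VDA=rec.VDA, VDD=rec.VDD,
                VG=rec.VG, VA_joint=rec.VA_joint,
                alphaA=rec.alphaA, alphaB=rec.alphaB,
            )
            VE = environmental_variance(rec.causal_VG0, design.H2)
            for t in tests:
                key = (rec.map_id, rec.r2, t.name)
                slow[key] = slow.get(key, 0.0) + detect(vc, design, t, VE=VE).detected_VA
        for row in fast.itertuples(index=False):
            assert row.detected_VA == pytest.approx(
                slow[(row.map_id, row.r2, row.test)], abs=1e-12
            )
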