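"""Synthetic generator: determinism, closed forms, expectation correctness."""

from dataclasses import replace

import numpy as np
import pytest

from darkdic import (
    CONTROL,
    DMSO,
    KILLED,
    PA,
    SyntheticTruth,
    ammonia_oxidation_profile,
    dic_fixation_profile,
    generate_dic_incubation,
    generate_incubations,
    generate_leucine_incubation,
    generate_nitrification_series,
    generate_station,
    incubation_tables,
    labeling_fraction,
)
from darkdic.isotope import HOURS_PER_DAY


class TestLabelingFraction:
    def test_mixing_arithmetic(self, constants):
        # 200 nM at 0.99 atom fraction into 50 nM natural-abundance substrate
        expected = (200 * 0.99 + 50 * constants.a_nat_15n) / 250
        assert labeling_fraction(200, 0.99, 50) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.79273, abs=5e-6)

    def test_no_ambient_limit(self):
        assert labeling_fraction(100, 0.98, 0.0) == 0.98

    def test_low_label_regime(self):
        # a small spike into a large ambient pool: the ~5% labelling regime
        assert labeling_fraction(70, 0.98, 1330) == pytest.approx(0.05248, abs=5e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            labeling_fraction(0.0, 0.99, 10)
        with pytest.raises(ValueError):
            labeling_fraction(100, 0.99, -1)


class TestTruthValidation:
    @pytest.mark.parametrize("bad", [
        {"yield_aoa_true": 0.25}, {"tracer_add_15n": 50},
        {"tracer_add_15n": 250}, {"replicate_cv": -0.1}, {"ao_peak_rate": -1},
    ])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            SyntheticTruth(**bad)

    def test_null_yield_admitted(self):
        # the no-inhibition null configuration
        assert SyntheticTruth(yield_aoa_true=0.0).yield_aoa_true == 0.0


class TestTrueProfiles:
    def test_dic_fixation_closed_form(self):
        # only ammonia oxidation active: F = yield * R_AO at the peak
        t = SyntheticTruth(ao_peak_rate=20, ao_deep_tail=0, no_rate_scale=0,
                           hetero_surface_rate=0, background_dic_fix=0,
                           yield_aoa_true=0.05)
        assert float(dic_fixation_profile(t, t.peak_depth)) == pytest.approx(1.0, rel=1e-12)

    def test_composition_identity(self, truth, constants):
        z = np.asarray(truth.depths, float)
        _, rates = generate_station(truth)
        recomposed = (
            truth.yield_aoa_true * rates["ammonia_oxidation"]
            + constants.yield_nob * rates["nitrite_oxidation"]
            + constants.hetero_dic_fraction * rates["hetero_production"]
            + truth.background_dic_fix
        )
        np.testing.assert_allclose(rates["dic_fixation_total"], recomposed, rtol=1e-12)

    def test_peak_location_matches_configuration(self, truth):
        z_fine = np.arange(0.0, 600.0, 0.5)
        r = ammonia_oxidation_profile(truth, z_fine)
        assert z_fine[np.argmax(r)] == pytest.approx(truth.peak_depth, abs=0.5)
        # and on the sampled grid, within one grid step
        _, rates = generate_station(truth)
        z = rates["depths"]
        imax = int(np.argmax(rates["ammonia_oxidation"]))
        step = np.max(np.diff(z)[max(imax - 1, 0):imax + 1])
        assert abs(z[imax] - truth.peak_depth) <= step

    def test_euphotic_depth_recoverable(self, truth):
        from darkdic import estimate_euphotic_depth
        profile, _ = generate_station(truth)
        z_eu = estimate_euphotic_depth(profile)
        assert z_eu == pytest.approx(truth.euphotic_depth_true, abs=5.0)


class TestDeterminism:
    def test_same_seed_identical(self, truth):
        iso1, radio1 = incubation_tables(truth)
        iso2, radio2 = incubation_tables(truth)
        assert iso1.equals(iso2) and radio1.equals(radio2)

    def test_distinct_seeds_differ(self, truth):
        other = replace(truth, seed=truth.seed + 1)
        iso1, _ = incubation_tables(truth)
        iso2, _ = incubation_tables(other)
        assert not np.allclose(iso1["af_product"], iso2["af_product"])


class TestIncubationObservables:
    def test_nitrification_series_closed_form(self, noise_free_truth, constants):
        t = noise_free_truth
        s = generate_nitrification_series(t, 90.0, CONTROL, "15NH4")
        rate = float(ammonia_oxidation_profile(t, 90.0))
        expected_excess = rate * s.substrate_label_fraction * 1.0 / s.product_pool_nm
        excess = s.af_product[:, -1] - s.af_product[:, 0]
        np.testing.assert_allclose(excess, expected_excess, rtol=1e-10)
        assert s.af_product[0, 0] == pytest.approx(constants.a_nat_15n, rel=1e-12)

    def test_pa_zeroes_ammonia_oxidation_series(self, noise_free_truth):
        s = generate_nitrification_series(noise_free_truth, 90.0, PA, "15NH4")
        assert np.ptp(s.af_product) == 0.0

    def test_pa_leaves_nitrite_oxidation(self, noise_free_truth):
        s_pa = generate_nitrification_series(noise_free_truth, 90.0, PA, "15NO2")
        s_ct = generate_nitrification_series(noise_free_truth, 90.0, CONTROL, "15NO2")
        np.testing.assert_allclose(s_pa.af_product, s_ct.af_product, rtol=1e-12)

    def test_killed_bottles_match_blank(self, noise_free_truth):
        inc = generate_dic_incubation(noise_free_truth, 90.0, KILLED)
        np.testing.assert_allclose(inc.dpm_live, np.mean(inc.dpm_killed), rtol=1e-12)

    def test_dmso_equals_control_in_expectation(self, truth, constants):
        from darkdic.synthetic import _dic_components
        np.testing.assert_allclose(
            _dic_components(truth, 90.0, CONTROL, constants),
            _dic_components(truth, 90.0, DMSO, constants))

    def test_treatment_contract(self, noise_free_truth, constants):
        # E[control] - E[+PA] = yield * R_AO at every sampled depth
        t = noise_free_truth
        for depth in t.depths:
            ctrl = generate_dic_incubation(t, float(depth), CONTROL)
            pa = generate_dic_incubation(t, float(depth), PA)
            to_rate = ctrl.dic_um * 1000.0 / ctrl.dpm_total_added / ctrl.duration_d
            diff = (np.mean(ctrl.dpm_live) - np.mean(pa.dpm_live)) * to_rate
            expected = t.yield_aoa_true * float(ammonia_oxidation_profile(t, depth))
            assert diff == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_unknown_treatment_rejected(self, truth):
        with pytest.raises(ValueError):
            generate_dic_incubation(truth, 90.0, "bleach")

    def test_expectation_correctness(self, truth):
        # means over 1000 noisy replicates match noise-free values within 3 SE
        noisy = replace(truth, n_replicates=1000)
        clean = truth.noise_free()

        inc_noisy = generate_dic_incubation(noisy, 90.0, CONTROL)
        inc_clean = generate_dic_incubation(clean, 90.0, CONTROL)
        se = np.std(inc_noisy.dpm_live, ddof=1) / np.sqrt(1000)
        assert abs(np.mean(inc_noisy.dpm_live) - inc_clean.dpm_live[0]) < 3 * se

        s_noisy = generate_nitrification_series(noisy, 90.0, CONTROL, "15NH4")
        s_clean = generate_nitrification_series(clean, 90.0, CONTROL, "15NH4")
        end_noisy = s_noisy.af_product[:, -1]
        se = np.std(end_noisy, ddof=1) / np.sqrt(1000)
        assert abs(np.mean(end_noisy) - s_clean.af_product[0, -1]) < 3 * se

        leu_noisy = generate_leucine_incubation(noisy, 90.0, CONTROL)
        leu_clean = generate_leucine_incubation(clean, 90.0, CONTROL)
        se = np.std(leu_noisy.dpm_live, ddof=1) / np.sqrt(1000)
        assert abs(np.mean(leu_noisy.dpm_live) - leu_clean.dpm_live[0]) < 3 * se

    def test_generate_incubations_bundle(self, truth):
        incs = generate_incubations(truth, 120.0, CONTROL)
        assert set(incs) == {"15NH4", "15NO2", "14C", "3H"}
        assert incs["14C"].isotope == "14C" and incs["3H"].isotope == "3H"


class TestTables:
    def test_schema_and_size(self, truth):
        iso, radio = incubation_tables(truth)
        assert set(iso.columns) >= {"experiment_id", "station", "depth_m",
                                    "treatment", "tracer", "replicate",
                                    "timepoint_h", "af_product", "pool_nm", "f_label"}
        n_depths = len(truth.depths)
        assert len(iso) == n_depths * 2 * 2 * truth.n_replicates * len(truth.incubation_times_h)
        assert len(radio) == n_depths * 2 * 2 * truth.n_replicates
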