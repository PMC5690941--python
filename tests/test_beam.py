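"""Spectrum generation, filtration and bowtie decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odmsim.attenuation import MATERIALS, mass_atten
from odmsim.beam import (
    FILTER_STACKS,
    BowtieProfile,
    FilterStack,
    Spectrum,
    apply_filtration,
    compare_to_qef,
    decompose_bowtie,
    generate_spectrum,
    inverse_square_correct,
    reconstruct_profile,
)
from odmsim.synthetic import bowtie_truth, gen_bowtie_measurements


class TestGenerateSpectrum:
    def test_no_fluence_above_tube_potential(self):
        s = generate_spectrum(120)
        assert s.fluence[s.energy_kev > 120].sum() == 0
        assert s.fluence[s.energy_kev <= 120].sum() > 0

    def test_k_lines_only_above_excitation_threshold(self):
        # a K-alpha spike at ~59 keV appears for 120 kVp but not for 69 kVp
        def spike(s):
            i = int(np.argmin(np.abs(s.energy_kev - 59.5)))
            neighbours = 0.5 * (s.fluence[i - 2] + s.fluence[i + 2])
            return s.fluence[i] / neighbours

        assert spike(generate_spectrum(120)) > 1.5
        assert spike(generate_spectrum(69)) == pytest.approx(1.0, abs=0.1)

    def test_low_kvp_has_no_characteristic_lines(self):
        s = generate_spectrum(50)
        assert s.fluence[s.energy_kev > 50].sum() == 0

    def test_kvp_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="kvp"):
            generate_spectrum(30)
        with pytest.raises(ValueError, match="kvp"):
            generate_spectrum(200)

    def test_beam_hardening_raises_mean_energy(self):
        """Filtration must shift the mean energy up (Beer-Lambert oracle)."""
        s = generate_spectrum(120, bin_width_kev=1.0)
        # independent oracle: direct exponential attenuation of each bin
        mu = mass_atten("aluminum", s.energy_kev) * MATERIALS["aluminum"].density
        f_filtered = s.fluence * np.exp(-mu * 0.575)
        oracle_mean = (s.energy_kev * f_filtered).sum() / f_filtered.sum()
        filtered = apply_filtration(s, FilterStack((("aluminum", 5.75),)))
        assert filtered.mean_energy > s.mean_energy
        assert filtered.mean_energy == pytest.approx(oracle_mean, rel=1e-12)


class TestApplyFiltration:
    def test_zero_thickness_is_identity(self):
        s = generate_spectrum(120)
        out = apply_filtration(s, FilterStack((("copper", 0.0),)))
        np.testing.assert_allclose(out.fluence, s.fluence)

    def test_single_line_beer_lambert(self, mono_60kev):
        out = apply_filtration(mono_60kev, FilterStack((("copper", 1.0),)))
        mu = mass_atten("copper", 60.0) * MATERIALS["copper"].density
        assert out.fluence[1] == pytest.approx(float(np.exp(-mu * 0.1)), rel=1e-12)

    def test_large_stack_attenuates_more_than_small(self):
        s = generate_spectrum(120)
        small = apply_filtration(s, FILTER_STACKS["small"])
        large = apply_filtration(s, FILTER_STACKS["large"])
        assert large.total_fluence < small.total_fluence

    def test_any_stack_strictly_reduces_fluence(self):
        s = generate_spectrum(120)
        for stack in FILTER_STACKS.values():
            assert apply_filtration(s, stack).total_fluence < s.total_fluence

    def test_unknown_material_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            FilterStack((("lead", 1.0),))

    @given(
        t1=st.floats(0.1, 3.0),
        t2=st.floats(0.05, 2.0),
    )
    @settings(max_examples=20, deadline=None)
    def test_layer_order_commutes(self, t1, t2):
        s = generate_spectrum(120)
        a = apply_filtration(s, FilterStack((("aluminum", t1), ("copper", t2))))
        b = apply_filtration(s, FilterStack((("copper", t2), ("aluminum", t1))))
        np.testing.assert_allclose(a.fluence, b.fluence, atol=1e-12)


class TestCompareToQef:
    def test_stack_against_itself_is_zero(self):
        s = generate_spectrum(120)
        stack = FilterStack((("aluminum", 5.9),), qef_mm_al=5.9)
        rep = compare_to_qef(s, stack)
        assert rep["overall_rel_diff"] == pytest.approx(0.0, abs=1e-12)
        assert np.max(rep["per_bin_rel_diff"]) == pytest.approx(0.0, abs=1e-12)

    def test_small_stack_reports_finite_per_bin_difference(self):
        rep = compare_to_qef(generate_spectrum(120), FILTER_STACKS["small"])
        assert np.all(np.isfinite(rep["per_bin_rel_diff"]))
        assert rep["overall_rel_diff"] > 0

    def test_scale_invariance(self):
        s = generate_spectrum(120)
        s2 = Spectrum(s.energy_kev, 2.0 * s.fluence)
        r1 = compare_to_qef(s, FILTER_STACKS["large"])
        r2 = compare_to_qef(s2, FILTER_STACKS["large"])
        assert r1["overall_rel_diff"] == pytest.approx(r2["overall_rel_diff"], rel=1e-12)


class TestInverseSquareCorrect:
    def test_closed_form_multiplier(self):
        x = np.linspace(-200, 200, 81)
        prof = BowtieProfile(x, np.ones_like(x), frame="line")
        out = inverse_square_correct(prof, 541.0)
        # flat input: corrected values ~ 1 + (x/sid)^2 before renormalization;
        # check the edge-to-center ratio against the closed form
        ratio = out.relative_dose[x == 200][0] / out.relative_dose[x == 0][0]
        assert ratio == pytest.approx(1.0 + (200 / 541) ** 2, rel=1e-12)
        assert out.frame == "arc"
        assert out.relative_dose.max() == pytest.approx(1.0, abs=1e-9)

    def test_invertible(self):
        x = np.linspace(-250, 250, 101)
        prof = BowtieProfile(x, bowtie_truth("small", x), frame="line")
        out = inverse_square_correct(prof, 541.0)
        undone = out.relative_dose / (1.0 + (x / 541.0) ** 2)
        undone /= undone.max()
        np.testing.assert_allclose(undone, prof.relative_dose / prof.relative_dose.max(), atol=1e-9)

    def test_bad_inputs_rejected(self):
        x = np.linspace(-10, 10, 21)
        prof = BowtieProfile(x, np.ones_like(x), frame="line")
        with pytest.raises(ValueError):
            inverse_square_correct(prof, -5.0)
        arc = inverse_square_correct(prof, 541.0)
        with pytest.raises(ValueError):
            inverse_square_correct(arc, 541.0)


class TestDecomposeBowtie:
    def test_flat_profile_gives_full_width_fields(self):
        x = np.linspace(-100, 100, 201)
        prof = BowtieProfile(x, np.ones_like(x), frame="arc")
        sf = decompose_bowtie(prof, n_fields=10, innermost_weight=0.08)
        assert np.all(sf.half_widths == pytest.approx(100.0))
        rec = reconstruct_profile(sf, x)
        assert rec.relative_dose == pytest.approx(sf.weights.sum())

    def test_configured_weights(self):
        x = np.linspace(-250, 250, 501)
        prof = BowtieProfile(x, bowtie_truth("small", x), frame="arc")
        sf = decompose_bowtie(prof, n_fields=10, innermost_weight=0.08)
        np.testing.assert_allclose(sf.weights, [0.1] * 9 + [0.08])

    def test_triangular_profile_oracle(self):
        """Field half-widths follow W*(1-L_k); staircase sup error <= 0.10."""
        W = 200.0
        x = np.linspace(-W, W, 2001)
        prof = BowtieProfile(x, 1.0 - np.abs(x) / W, frame="arc")
        sf = decompose_bowtie(prof, n_fields=10, innermost_weight=0.10)
        levels = np.arange(10) * 0.1 + 0.05
        np.testing.assert_allclose(sf.half_widths, W * (1 - levels), rtol=0.01)
        rec = reconstruct_profile(sf, x)
        assert np.max(np.abs(rec.relative_dose - prof.relative_dose)) <= 0.10

    def test_non_unimodal_rejected_with_diagnostic(self):
        x = np.linspace(-100, 100, 201)
        bimodal = 0.5 + 0.5 * (np.abs(x) > 50)
        with pytest.raises(ValueError, match="unimodal"):
            decompose_bowtie(BowtieProfile(x, bimodal, frame="arc"))

    def test_line_frame_rejected(self):
        x = np.linspace(-100, 100, 201)
        with pytest.raises(ValueError, match="arc"):
            decompose_bowtie(BowtieProfile(x, np.ones_like(x), frame="line"))

    @pytest.mark.parametrize("kind", ["small", "large"])
    def test_roundtrip_sup_error_within_quantization(self, kind):
        """decompose -> reconstruct of the synthetic filters stays within 1/n."""
        from odmsim.beam import INNERMOST_WEIGHT

        measured = gen_bowtie_measurements(kind, noise_sd=0.0, seed=0)
        arc = inverse_square_correct(measured, 541.0)
        sf = decompose_bowtie(arc, 10, INNERMOST_WEIGHT[kind])
        grid = np.linspace(-250, 250, 2001)
        rec = reconstruct_profile(sf, grid)
        assert np.max(np.abs(rec.relative_dose - bowtie_truth(kind, grid))) <= 0.10

    @given(flat=st.floats(20, 80), falloff=st.floats(40, 150))
    @settings(max_examples=15, deadline=None)
    def test_roundtrip_property_on_flat_top_profiles(self, flat, falloff):
        x = np.linspace(-250, 250, 1001)
        p = np.where(np.abs(x) <= flat, 1.0, np.exp(-(np.abs(x) - flat) / falloff))
        prof = BowtieProfile(x, p, frame="arc")
        sf = decompose_bowtie(prof, n_fields=10, innermost_weight=0.10)
        rec = reconstruct_profile(sf, x)
        assert np.max(np.abs(rec.relative_dose - p)) <= 0.101
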