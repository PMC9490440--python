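"""Spectrum IO, baseline correction, feature measurement and the ratio
battery, checked against closed-form band profiles and brute-force window
scans."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioapatite import spectra as sp
from bioapatite import synthetic as syn
from bioapatite.errors import AnchorError, EmptyInputError, FormatError, WindowError


def gaussian_spectrum(centers, amps, sigmas, lo=400.0, hi=4000.0, step=1.0):
    wn = np.arange(lo, hi + step / 2, step)
    ab = np.zeros_like(wn)
    for c, a, s in zip(centers, amps, sigmas):
        ab += a * np.exp(-0.5 * ((wn - c) / s) ** 2)
    return sp.Spectrum(wn, ab)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoad:
    def test_minimal_csv(self):
        spec = sp.load_spectrum(io.StringIO("1035,1.0\n1036,0.9"))
        assert len(spec) == 2
        assert spec.wavenumbers[0] == 1035.0

    def test_duplicate_wavenumbers_collapse_by_mean(self):
        spec = sp.load_spectrum(io.StringIO("1035,1.0\n1035,0.8\n1036,0.5"))
        assert len(spec) == 2
        assert spec.absorbance[0] == pytest.approx(0.9)

    def test_metadata_headers(self):
        text = "# sample_id: S1\n# state: burnt\n# pmi_days: 91\n1035,1.0\n1040,0.9"
        spec = sp.load_spectrum(io.StringIO(text))
        assert spec.sample_id == "S1" and spec.state == "burnt" and spec.pmi_days == 91

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            sp.load_spectrum(io.StringIO(""))

    def test_unparseable_line_names_line_number(self):
        with pytest.raises(FormatError, match="line 2"):
            sp.load_spectrum(io.StringIO("1035,1.0\n10x5,abc"))

    @pytest.mark.parametrize("fmt,writer", [
        ("csv", sp.write_spectrum_csv),
        ("jcamp", sp.write_spectrum_jcamp),
    ])
    def test_write_read_round_trip(self, tmp_path, fmt, writer, rng):
        bands = syn.default_bands("burnt", 91)
        spec = syn.simulate_spectrum(bands, noise_sd=0.002, rng=rng,
                                     sample_id="RT1", state="burnt", pmi_days=91)
        path = tmp_path / f"rt.{fmt}"
        writer(spec, path)
        back = sp.load_spectrum(path, fmt)
        np.testing.assert_allclose(back.wavenumbers, spec.wavenumbers, atol=1e-6)
        np.testing.assert_allclose(back.absorbance, spec.absorbance, rtol=1e-9)
        assert back.state == "burnt" and back.pmi_days == 91 and back.sample_id == "RT1"


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

class TestBaseline:
    def test_flat_zero_unchanged(self):
        wn = np.arange(400.0, 4001.0)
        spec = sp.Spectrum(wn, np.zeros_like(wn))
        out = sp.baseline_correct(spec)
        assert np.all(out.absorbance == 0.0)

    def test_linear_baseline_removed(self):
        # Gaussian (amp 1 at 1035) + tilted line: corrected height ~1
        wn = np.arange(400.0, 4001.0)
        ab = np.exp(-0.5 * ((wn - 1035) / 15.0) ** 2) + 1e-4 * (4000.0 - wn)
        out = sp.baseline_correct(sp.Spectrum(wn, ab))
        h = sp.feature_height(out, sp.FeatureQuery(1035)).height
        assert h == pytest.approx(1.0, rel=0.01)

    def test_idempotent(self):
        bands = syn.default_bands("unburnt", 0)
        spec = syn.simulate_spectrum(bands, baseline_coeffs=(0.05, 1e-5))
        once = sp.baseline_correct(spec)
        twice = sp.baseline_correct(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)

    def test_anchor_outside_range(self):
        spec = gaussian_spectrum([1035], [1.0], [10.0], lo=450, hi=2100)
        with pytest.raises(AnchorError):
            sp.baseline_correct(spec, anchors=[450, 3000])

    def test_original_not_modified(self):
        spec = gaussian_spectrum([1035], [1.0], [10.0])
        before = spec.absorbance.copy()
        sp.baseline_correct(spec)
        np.testing.assert_array_equal(spec.absorbance, before)


# ---------------------------------------------------------------------------
# feature heights
# ---------------------------------------------------------------------------

class TestFeatureHeight:
    def test_peak_centered_in_window(self):
        spec = gaussian_spectrum([1035], [1.0], [10.0])
        m = sp.feature_height(spec, sp.FeatureQuery(1035, 5))
        assert m.height == pytest.approx(1.0) and m.observed_center == 1035.0
        assert m.shift == 0.0

    def test_shifted_window_takes_edge_maximum(self):
        # window [1038, 1048] of a unit Gaussian (sigma 10) peaks at 1038
        spec = gaussian_spectrum([1035], [1.0], [10.0])
        m = sp.feature_height(spec, sp.FeatureQuery(1043, 5))
        assert m.observed_center == 1038.0
        assert m.height == pytest.approx(math.exp(-(3**2) / (2 * 10**2)), rel=1e-9)

    def test_valley_between_doublet(self):
        spec = gaussian_spectrum([565, 605], [0.55, 0.6], [13.0, 13.0])
        valley = sp.feature_height(spec, sp.FeatureQuery(587.5, 12.5, "valley"))
        grid = spec.wavenumbers
        mask = (grid >= 575) & (grid <= 600)
        assert valley.height == pytest.approx(spec.absorbance[mask].min())
        assert valley.height < 0.55

    def test_window_outside_range(self):
        spec = gaussian_spectrum([1035], [1.0], [10.0], lo=450, hi=2100)
        with pytest.raises(WindowError):
            sp.feature_height(spec, sp.FeatureQuery(2100, 5))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_peak_equals_brute_force_argmax(self, seed):
        """Property: peak extraction is exactly the window argmax."""
        r = np.random.default_rng(seed)
        wn = np.arange(450.0, 2101.0)
        ab = np.abs(r.normal(0, 1, wn.size)).cumsum() % 3.0  # arbitrary rough trace
        spec = sp.Spectrum(wn, ab)
        center = float(r.uniform(500, 2000))
        tol = float(r.uniform(1, 20))
        m = sp.feature_height(spec, sp.FeatureQuery(center, tol))
        mask = (wn >= center - tol) & (wn <= center + tol)
        assert m.height == ab[mask].max()
        assert abs(m.shift) <= tol

    def test_shoulder_on_flank_detected(self):
        # small narrow band on the rising flank of a larger one: no local
        # max, but negative curvature at the shoulder
        spec = gaussian_spectrum([565, 547], [0.55, 0.05], [13.0, 5.0], lo=450, hi=700)
        m = sp.feature_height(spec, sp.FeatureQuery(547, 5, "shoulder"))
        assert m.found

    def test_no_shoulder_on_smooth_flank(self):
        spec = gaussian_spectrum([565], [0.55], [13.0], lo=450, hi=700)
        m = sp.feature_height(spec, sp.FeatureQuery(547, 5, "shoulder"))
        assert not m.found


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

class TestRatios:
    def test_irsf_equal_heights_gives_two(self):
        # flat-top construction: peaks and valley all at the same height h
        wn = np.arange(450.0, 701.0)
        ab = np.full_like(wn, 0.5)
        rec = sp.compute_ratios(sp.Spectrum(wn, ab), battery=[sp.default_battery()[0]],
                                state="unburnt")
        assert rec["IRSF"] == pytest.approx(2.0)

    def test_state_applicability(self):
        bands = syn.default_bands("unburnt", 0)
        spec = syn.simulate_spectrum(bands, state="unburnt")
        rec = sp.compute_ratios(sp.baseline_correct(spec))
        assert not rec.applicable["API"] and not rec.applicable["C/C"]
        assert math.isnan(rec["API"])
        assert rec.applicable["IRSF"]

    def test_zero_denominator_not_applicable_no_exception(self):
        wn = np.arange(450.0, 2101.0)
        ab = np.zeros_like(wn)
        ab[(wn > 1400) & (wn < 1430)] = 0.3  # carbonate only, no phosphate
        rec = sp.compute_ratios(sp.Spectrum(wn, ab), state="unburnt")
        assert not rec.applicable["C/P"]
        assert math.isnan(rec["C/P"])

    def test_scale_invariance_exact_for_pow2(self):
        """Multiplying absorbance by 2^k leaves every ratio bit-identical."""
        bands = syn.default_bands("burnt", 14)
        spec = syn.simulate_spectrum(bands, noise_sd=0.003,
                                     rng=np.random.default_rng(3), state="burnt")
        base = sp.compute_ratios(sp.baseline_correct(spec), state="burnt")
        for k in (2.0, 8.0, 0.25):
            scaled = sp.Spectrum(spec.wavenumbers, spec.absorbance * k,
                                 state="burnt")
            rec = sp.compute_ratios(sp.baseline_correct(scaled), state="burnt")
            for name in base.values:
                if base.applicable[name]:
                    assert rec[name] == base[name], name

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.01, 100.0, allow_nan=False))
    def test_scale_invariance_any_positive(self, c):
        spec = syn.simulate_spectrum(syn.default_bands("unburnt", 91))
        base = sp.compute_ratios(sp.baseline_correct(spec), state="unburnt")
        scaled = sp.Spectrum(spec.wavenumbers, spec.absorbance * c)
        rec = sp.compute_ratios(sp.baseline_correct(scaled), state="unburnt")
        for name in base.values:
            if base.applicable[name]:
                assert rec[name] == pytest.approx(base[name], rel=1e-9), name

    def test_shift_containment(self):
        spec = syn.simulate_spectrum(syn.default_bands("burnt", 0),
                                     noise_sd=0.005, rng=np.random.default_rng(5))
        rec = sp.compute_ratios(sp.baseline_correct(spec), state="burnt")
        battery = {q.center: q.tolerance
                   for rd in sp.default_battery() for q in (*rd.numerator, *rd.denominator)}
        for key, shift in rec.shifts.items():
            center = float(key.rsplit("_", 1)[1])
            assert abs(shift) <= battery[center] + 1e-9

    def test_noiseless_ratios_match_analytic_band_values(self):
        """Generator round-trip: measured ratios within 1% of values computed
        directly from the band parameters."""
        for state, pmi in (("unburnt", 0), ("burnt", 91)):
            bands = syn.default_bands(state, pmi)
            spec = syn.simulate_spectrum(bands)
            rec = sp.compute_ratios(sp.baseline_correct(spec), state=state)

            def band_sum(x):
                return sum(b.amplitude * math.exp(-0.5 * ((x - b.center) / b.width) ** 2)
                           for b in bands)

            grid = np.arange(575.0, 600.5, 1.0)
            irsf_analytic = (max(band_sum(x) for x in np.arange(560, 570.5)) +
                             max(band_sum(x) for x in np.arange(600, 610.5))) / \
                min(band_sum(x) for x in grid)
            assert rec["IRSF"] == pytest.approx(irsf_analytic, rel=0.01)
            cp_analytic = max(band_sum(x) for x in np.arange(1410, 1420.5)) / \
                max(band_sum(x) for x in np.arange(1030, 1040.5))
            assert rec["C/P"] == pytest.approx(cp_analytic, rel=0.01)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

class TestMarkers:
    def test_null_case_btcp_absent(self):
        spec = gaussian_spectrum([1035], [1.0], [20.0])
        rep = sp.detect_markers(spec)
        assert not rep.btcp_peak_1123

    def test_injected_btcp_band_detected(self):
        spec = gaussian_spectrum([1035, 1123], [1.0, 0.08], [20.0, 6.0])
        rep = sp.detect_markers(spec)
        assert rep.btcp_peak_1123
        assert rep.btcp_peak_height == pytest.approx(0.08, rel=0.1)

    def test_default_burnt_has_extra_peak_and_ohcl_not_shoulder(self, cfg):
        spec = syn.simulate_spectrum(syn.default_bands("burnt", 0))
        rep = sp.detect_markers(spec)
        assert rep.extra_peak_1080_1100
        assert 1080 <= rep.extra_peak_center <= 1100
        assert rep.oh_cl_peak
        assert not rep.shoulder_547

    def test_default_unburnt_has_shoulder_not_extra_peak(self):
        spec = syn.simulate_spectrum(syn.default_bands("unburnt", 365))
        rep = sp.detect_markers(spec)
        assert rep.shoulder_547
        assert not rep.extra_peak_1080_1100
        assert not rep.oh_cl_peak

    def test_34_day_variant_configurable_to_absent(self):
        trends = syn.make_default_trends(extra_peak_absent_34d=True)
        spec = syn.simulate_spectrum(syn.default_bands("burnt", 34, trends))
        assert not sp.detect_markers(spec).extra_peak_1080_1100
        spec91 = syn.simulate_spectrum(syn.default_bands("burnt", 91, trends))
        assert sp.detect_markers(spec91).extra_peak_1080_1100
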