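"""Targeted XIC quantification: extraction, integration, envelope, MS2."""

import math

import numpy as np
import pytest

from enamelsex import chem, quant
from enamelsex.quant import (
    Chromatogram,
    QuantError,
    QuantParams,
    detect_and_integrate,
    envelope_score,
    extract_xic,
    ms2_validate,
    quantify_marker,
)
from enamelsex.simulate import SampleSpec, simulate_run
from enamelsex.spectra import Precursor, Run, Spectrum


def zero_noise_spec(**kw):
    base = dict(sample_id="zn", sex="male", era="modern", seed=1,
                mass_jitter_ppm=0.0, noise_cv=0.0, decoy_density=0.0,
                background_peptides=(), ms2_enabled=False)
    base.update(kw)
    return SampleSpec(**base)


class TestExtractXic:
    def test_no_signal_gives_all_zero_trace(self):
        run, _ = simulate_run(zero_noise_spec())
        [c] = extract_xic(run, [1000.0], 10.0)
        assert c.intensity.sum() == 0.0
        assert c.rt.size == len(run.ms1())

    def test_signal_confined_to_elution_window(self):
        spec = zero_noise_spec()
        run, _ = simulate_run(spec)
        [c] = extract_xic(run, [404.72123], 10.0)
        rt_c = spec.marker_rt["Y1"]
        inside = np.abs(c.rt - rt_c) <= 6 * spec.rt_sigma
        assert c.intensity[~inside].sum() == 0.0
        assert c.intensity[inside].sum() > 0.0

    def test_run_without_ms1_is_error(self):
        run = Run("m2only", [Spectrum("1", 2, 0.0, np.array([100.0]),
                                      np.array([1.0]), Precursor(400.0, 2))])
        with pytest.raises(QuantError, match="MS1"):
            extract_xic(run, [400.0], 10.0)

    def test_jittered_signal_mostly_captured_at_10ppm(self):
        """5 ppm mass jitter, 10 ppm window: each centroid lands in the
        window with P(|N(0,5)| <= 10) ~= 0.954; Monte-Carlo over seeds."""
        captured = []
        for seed in range(12):
            spec = zero_noise_spec(seed=seed, mass_jitter_ppm=5.0,
                                   run_length=200.0,
                                   marker_apex={"Y1": 1.0e8},
                                   marker_rt={"Y1": 100.0})
            run, truth = simulate_run(spec)
            env = chem.isotope_envelope(chem.elemental_composition(
                chem.ModifiedPeptide("LRYPYP")), 2, spec.n_peaks)
            chroms = extract_xic(run, [m for m, _ in env], 10.0)
            total = sum(c.intensity.sum() for c in chroms) * spec.scan_interval
            captured.append(total / truth.marker_area["Y1"])
        assert np.mean(captured) >= 0.90
        assert np.mean(captured) == pytest.approx(0.954, abs=0.04)


class TestDetectAndIntegrate:
    def test_all_zero_trace_gives_zero_area(self):
        rt = np.arange(100.0)
        c = Chromatogram(500.0, rt, np.zeros_like(rt))
        peak = detect_and_integrate([c])
        assert peak.area == 0.0 and peak.apex_rt is None

    def test_gaussian_area_matches_closed_form(self):
        apex, sigma, center = 1e6, 2.5, 60.0
        rt = np.arange(0.0, 120.0, 1.0)
        inten = apex * np.exp(-((rt - center) ** 2) / (2 * sigma ** 2))
        peak = detect_and_integrate([Chromatogram(500.0, rt, inten)])
        assert peak.area == pytest.approx(apex * sigma * math.sqrt(2 * math.pi),
                                          rel=0.02)
        assert peak.rt_start <= peak.apex_rt <= peak.rt_end
        assert peak.apex_rt == pytest.approx(center, abs=1.0)

    def test_expected_rt_window_selects_smaller_peak(self):
        rt = np.arange(0.0, 200.0, 1.0)
        big = 1e6 * np.exp(-((rt - 50.0) ** 2) / (2 * 2.5 ** 2))
        small = 1e5 * np.exp(-((rt - 150.0) ** 2) / (2 * 2.5 ** 2))
        c = Chromatogram(500.0, rt, big + small)
        peak = detect_and_integrate([c], expected_rt=150.0, rt_window=30.0)
        assert peak.apex_rt == pytest.approx(150.0, abs=1.0)
        assert peak.area == pytest.approx(1e5 * 2.5 * math.sqrt(2 * math.pi), rel=0.05)

    def test_earliest_rt_wins_on_ties(self):
        rt = np.arange(10.0)
        inten = np.zeros_like(rt)
        inten[[3, 6]] = 5.0
        peak = detect_and_integrate([Chromatogram(500.0, rt, inten)])
        assert peak.apex_rt == 3.0


class TestEnvelopeScore:
    def test_scale_invariance(self):
        theo = np.array([0.6, 0.3, 0.08, 0.02])
        for c in (0.5, 1.0, 1e6):
            assert envelope_score(c * theo, theo) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.uniform(0, 1, 4), rng.uniform(0, 1, 4)
            s = envelope_score(a, b)
            assert 0.0 <= s <= 1.0 + 1e-12
            assert s == pytest.approx(envelope_score(b, a), abs=1e-12)

    def test_zero_observed_scores_zero(self):
        assert envelope_score(np.zeros(4), np.array([0.6, 0.3, 0.08, 0.02])) == 0.0

    def test_a0_only_fails_default_threshold(self):
        comp = chem.elemental_composition(chem.ModifiedPeptide("LRYPYP"))
        theo = np.array([a for _, a in chem.isotope_envelope(comp, 2, 4)])
        assert envelope_score(np.array([1.0, 0, 0, 0]), theo) < 0.9


class TestMs2Validate:
    def test_male_run_matches_most_y1_fragments(self, male_run, panel):
        run, _ = male_run
        matched, passed = ms2_validate(run, panel["Y1"], 20.0, 4)
        assert passed is True
        assert matched >= 8  # b/y series of a 6-mer

    def test_decoy_only_ms2_fails(self, panel):
        marker = panel["Y1"]
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(1300, 1600, 20))  # far from any b/y ion
        spectra = [
            Spectrum("1", 1, 0.0, np.array([marker.mz]), np.array([1e6])),
            Spectrum("2", 2, 0.5, mz, np.ones(20),
                     Precursor(marker.mz, 2, 0.85)),
        ]
        matched, passed = ms2_validate(Run("d", spectra), marker, 20.0, 4)
        assert passed is False and matched < 4

    def test_no_targeting_ms2_is_not_evaluated(self, panel):
        run = Run("ms1only", [Spectrum("1", 1, 0.0, np.array([500.0]),
                                       np.array([1.0]))])
        matched, passed = ms2_validate(run, panel["Y1"], 20.0, 4)
        assert passed is None and matched == 0


class TestQuantifyMarker:
    def test_male_run_detects_amely(self, male_run, panel):
        run, truth = male_run
        r = quantify_marker(run, panel["Y1"], QuantParams())
        assert r.detected and not r.reasons
        assert r.area == pytest.approx(truth.marker_area["Y1"], rel=0.05)
        assert r.envelope_score >= 0.99

    def test_female_run_rejects_amely_with_reason(self, female_run, panel):
        run, _ = female_run
        r = quantify_marker(run, panel["Y1"], QuantParams())
        assert not r.detected
        assert "area below floor" in r.reasons

    def test_corrupted_envelope_rejected(self, panel):
        # emit only the monoisotopic channel: observed envelope is A0-only
        spec = zero_noise_spec(n_peaks=1)
        run, _ = simulate_run(spec)
        r = quantify_marker(run, panel["Y1"], QuantParams(n_peaks=4))
        assert not r.detected
        assert "envelope_score" in r.reasons

    def test_area_linearity_under_intensity_scaling(self, panel):
        run, _ = simulate_run(zero_noise_spec())
        scaled = Run(run.sample_id, [
            Spectrum(s.scan_id, s.ms_level, s.rt, s.mz_array,
                     s.intensity_array * 3.0, s.precursor)
            for s in run.spectra])
        r1 = quantify_marker(run, panel["Y2"], QuantParams(use_ms2=False))
        r3 = quantify_marker(scaled, panel["Y2"], QuantParams(use_ms2=False))
        assert r3.area == pytest.approx(3.0 * r1.area, rel=1e-12)

    def test_no_false_amely_on_female_runs(self, panel):
        """Empirical AmelY false-positive rate on female-spec runs."""
        for seed in range(6):
            spec = SampleSpec(sample_id=f"f{seed}", sex="female", seed=100 + seed)
            run, _ = simulate_run(spec)
            for mid in ("Y1", "Y2"):
                r = quantify_marker(run, panel[mid], QuantParams())
                assert not r.detected, (seed, mid, r)
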