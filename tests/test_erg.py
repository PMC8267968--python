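"""ERG filtering and feature-extraction chain.

The filter oracle is the closed-form two-pass analog Butterworth
magnitude |H(f)|² = 1 / (1 + (f/fc)^(2n)) applied twice; the feature
oracle is the waveform generator's own ground truth.
"""

import numpy as np
import pytest

from retphen import erg
from retphen import simulate as sim
from retphen.erg import (A_WAVE_FILTER, B_WAVE_FILTER, ErgTrace, FilterSpec,
                         PeakSearchWindows)

DT = 0.350 / 512


def sine_trace(freq, n=512):
    t = np.arange(n) * DT
    return ErgTrace(np.sin(2 * np.pi * freq * t))


def two_pass_butter_magnitude(f, fc, order=4):
    return 1.0 / (1.0 + (f / fc) ** (2 * order))


class TestZeroCenter:
    def test_constant_trace_goes_to_zero(self):
        tr = erg.zero_center(ErgTrace(np.full(512, 5.0)))
        assert np.allclose(tr.samples, 0.0)

    def test_prestimulus_mean_removed(self, rng):
        y = rng.normal(12.3, 1.0, 512)
        tr = erg.zero_center(ErgTrace(y), baseline_end=0.020)
        pre = tr.samples[tr.time() < 0.020]
        assert abs(pre.mean()) < 1e-9

    def test_dc_offset_does_not_change_features(self):
        p = sim.ErgSimParams(noise_sd=0.0, seed=11)
        tr = sim.simulate_erg_trace(p)
        base = erg.extract_features(erg.zero_center(tr))
        shifted = ErgTrace(tr.samples + 40.0)
        off = erg.extract_features(erg.zero_center(shifted))
        assert off.a_amplitude == pytest.approx(base.a_amplitude, abs=1e-9)
        assert off.b_absolute == pytest.approx(base.b_absolute, abs=1e-9)
        assert off.b_latency == base.b_latency

    def test_empty_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            erg.zero_center(ErgTrace(np.zeros(512)), baseline_end=0.0)


class TestLowpassZeroPhase:
    def test_dc_passes_unchanged(self):
        tr = ErgTrace(np.full(512, 3.5))
        out = erg.lowpass_zero_phase(tr, B_WAVE_FILTER)
        assert np.allclose(out.samples, 3.5, atol=1e-9)

    def test_120hz_removed_by_30hz_path(self):
        out = erg.lowpass_zero_phase(sine_trace(120.0), B_WAVE_FILTER)
        assert np.abs(out.samples[100:400]).max() < 1e-3

    def test_10hz_passes_within_1pct(self):
        out = erg.lowpass_zero_phase(sine_trace(10.0), B_WAVE_FILTER)
        assert np.abs(out.samples[100:400]).max() == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("mult", [2, 4, 8])
    def test_stopband_matches_closed_form_within_factor_3(self, mult):
        # long sinusoid so the steady-state response is measured, clear
        # of the start-up transients that dominate deep in the stopband
        fc = 30.0
        f = mult * fc
        out = erg.lowpass_zero_phase(sine_trace(f, n=8192), FilterSpec(order=4, cutoff=fc))
        measured = np.abs(out.samples[2048:6144]).max()
        expected = two_pass_butter_magnitude(f, fc)
        assert expected / 3 < measured < expected * 3

    @pytest.mark.parametrize("center_ms,width_ms", [(100, 10), (175, 25), (250, 5)])
    def test_symmetric_pulse_peak_index_unchanged(self, center_ms, width_ms):
        t = np.arange(512) * DT
        pulse = np.exp(-0.5 * ((t - center_ms * 1e-3) / (width_ms * 1e-3)) ** 2)
        tr = ErgTrace(pulse)
        for spec in (A_WAVE_FILTER, B_WAVE_FILTER):
            out = erg.lowpass_zero_phase(tr, spec)
            assert int(np.argmax(out.samples)) == int(np.argmax(pulse))

    def test_cutoff_at_nyquist_rejected(self):
        tr = sine_trace(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            erg.lowpass_zero_phase(tr, FilterSpec(order=4, cutoff=tr.fs / 2))


class TestExtractFeatures:
    def test_noiseless_recovery_within_tolerance(self):
        p = sim.ErgSimParams(noise_sd=0.0, op_amp=0.0, seed=1)
        f = erg.extract_features(erg.zero_center(sim.simulate_erg_trace(p)))
        truth = p.effective_amplitudes(30.0)
        assert f.a_detected and f.b_detected
        assert f.a_amplitude == pytest.approx(-truth["a_amp"], abs=0.05 * truth["a_amp"])
        assert f.b_amplitude == pytest.approx(truth["b_amp"], abs=0.05 * truth["b_amp"])
        assert f.b_absolute == pytest.approx(truth["b_absolute"], abs=0.1 * truth["b_absolute"])
        assert f.a_latency == pytest.approx(p.a_latency, abs=2.0)
        assert f.b_latency == pytest.approx(p.b_latency, abs=2.0)

    def test_flat_trace_flags_both_components(self):
        f = erg.extract_features(ErgTrace(np.zeros(512)))
        assert not f.a_detected and not f.b_detected
        assert f.a_amplitude is None and f.b_absolute is None

    def test_noisy_op_mean_recovery_within_5pct(self):
        vals = []
        for s in range(20):
            p = sim.ErgSimParams(noise_sd=5.0, seed=s)
            tr = sim.simulate_erg_trace(p, rng=np.random.default_rng(s))
            vals.append(erg.extract_features(erg.zero_center(tr)).b_absolute)
        truth = sim.ErgSimParams().effective_amplitudes(30.0)["b_absolute"]
        assert np.mean(vals) == pytest.approx(truth, rel=0.05)

    @pytest.mark.parametrize("scale", [0.3, 3.0, 30.0, 300.0])
    def test_linearity_across_three_decades(self, scale):
        p = sim.ErgSimParams(noise_sd=0.0, op_amp=0.0,
                             a_amp=150 * scale, b_amp=300 * scale, seed=2)
        f = erg.extract_features(erg.zero_center(sim.simulate_erg_trace(p)))
        truth = p.effective_amplitudes(30.0)
        assert f.a_amplitude == pytest.approx(-truth["a_amp"], rel=0.05)
        assert f.b_amplitude == pytest.approx(truth["b_amp"], rel=0.05)

    def test_b_absolute_identity_on_noisy_batch(self):
        for s in range(10):
            p = sim.ErgSimParams(noise_sd=8.0, seed=s)
            f = erg.extract_features(erg.zero_center(
                sim.simulate_erg_trace(p, rng=np.random.default_rng(100 + s))))
            if f.a_detected and f.b_detected:
                assert f.b_absolute == pytest.approx(f.b_amplitude - f.a_amplitude, abs=1e-12)

    def test_flicker_mode_rejected(self):
        p = sim.ErgSimParams(noise_sd=0.0, seed=1)
        tr = sim.simulate_flicker_trace(p)
        with pytest.raises(ValueError, match="single-flash"):
            erg.extract_features(tr)


class TestExtractFlicker:
    def test_synthetic_train_p1_p2(self):
        p = sim.ErgSimParams(noise_sd=0.0, seed=1)
        tr = sim.simulate_flicker_trace(p)
        f = erg.extract_flicker(tr)
        truth_amp = p.intensity_gain(30.0) * p.flicker_p_amp
        assert f.p1_latency == pytest.approx(p.flicker_p_latency, abs=2.0)
        assert f.p2_amplitude == pytest.approx(truth_amp, abs=5.0)
        assert f.flicker_detected

    def test_flat_trace_flagged_unrecordable(self):
        tr = ErgTrace(np.zeros(512), mode="flicker", flicker_hz=9.0)
        f = erg.extract_flicker(tr)
        assert not f.flicker_detected
        assert f.p1_latency is None and f.p2_amplitude is None

    def test_single_peak_gives_p1_but_flags_p2(self):
        t = np.arange(512) * DT
        y = 80 * np.exp(-0.5 * ((t - 0.060) / 0.012) ** 2)
        f = erg.extract_flicker(ErgTrace(y, mode="flicker", flicker_hz=9.0))
        assert f.p1_latency == pytest.approx(40.0, abs=2.0)
        assert f.p2_amplitude is None and not f.flicker_detected


class TestNormalizeFeatures:
    @staticmethod
    def _table():
        import pandas as pd
        return pd.DataFrame({
            "genotype": ["+/+"] * 4 + ["-/-"] * 4,
            "intensity": [30.0, 30.0, 0.3, 0.3] * 2,
            "b_absolute": [500, 500, 200, 200, 50, 50, 20, 20],
        })

    def test_simple_ratio(self):
        out = erg.normalize_features(self._table(), value_cols=("b_absolute",))
        ko = out[(out.genotype == "-/-") & (out.intensity == 30.0)]
        assert ko["b_absolute_norm"].iloc[0] == pytest.approx(0.10)

    def test_reference_maps_to_exactly_one(self):
        out = erg.normalize_features(self._table(), value_cols=("b_absolute",))
        wt = out[(out.genotype == "+/+") & (out.intensity == 30.0)]
        assert wt["b_absolute_norm"].iloc[0] == 1.0

    def test_missing_reference_errors(self):
        t = self._table()
        with pytest.raises(ValueError, match="reference"):
            erg.normalize_features(t[t.genotype != "+/+"], value_cols=("b_absolute",))

    def test_synthetic_cohort_knockout_scale_recovered(self):
        p = sim.ErgSimParams(seed=5)
        traces = sim.simulate_erg(p, genotypes=("+/+", "-/-"), n_animals=6)
        feats = []
        for tr in traces:
            feats.append(erg.extract_features(erg.zero_center(tr)))
        table = erg.features_table(feats)
        out = erg.normalize_features(table, value_cols=("b_absolute",))
        ko = out[(out.genotype == "-/-") & (out.intensity == 30.0)]["b_absolute_norm"].iloc[0]
        assert 0.05 <= ko <= 0.12
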