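"""Filtering, epoching, baseline, rejection, interpolation, referencing."""

import json

import numpy as np
import pandas as pd
import pytest

import p3attn as pa
from p3attn.containers import ContinuousEEG, EpochSet
from p3attn.preprocess import (
    PreprocessError,
    RejectionReport,
    apply_rejection,
    average_reference,
    bandpass_filter,
    baseline_correct,
    detect_bad,
    epoch_continuous,
    interpolate_channels,
    interpolation_matrix,
)
from p3attn.simulate import builtin_profiles, simulate_epochs


def _sine_recording(freqs, sfreq=250.0, dur_s=30.0, dc=0.0):
    t = np.arange(int(dur_s * sfreq)) / sfreq
    data = np.vstack([np.sin(2 * np.pi * f * t) + dc for f in freqs])
    names = tuple(f"C{i}" for i in range(len(freqs)))
    return ContinuousEEG(data, sfreq, names), t


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        cont, t = _sine_recording([5.0])
        out = bandpass_filter(cont)
        mid = slice(2500, 5000)
        ratio = out.data[0, mid].std() / cont.data[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation_at_50hz(self):
        cont, t = _sine_recording([50.0])
        out = bandpass_filter(cont)
        mid = slice(2500, 5000)
        atten_db = 20 * np.log10(
            cont.data[0, mid].std() / out.data[0, mid].std())
        assert atten_db >= 20

    def test_dc_removed(self):
        cont, t = _sine_recording([5.0], dc=37.0)
        out = bandpass_filter(cont)
        assert abs(out.data[0, 2500:5000].mean()) < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        cont, _ = _sine_recording([5.0])
        with pytest.raises(PreprocessError, match="Nyquist"):
            bandpass_filter(cont, 0.5, 130.0)


def _pulse_recording(montage, onset_ms, sfreq=250.0, dur_s=60.0):
    n = int(dur_s * sfreq)
    data = np.zeros((montage.n_channels, n))
    idx = int(round(onset_ms * sfreq / 1000.0))
    data[:, idx] = 5.0
    return ContinuousEEG(data, sfreq, montage.names)


class TestEpoching:
    def test_pulse_lands_at_event_latency(self, montage):
        cont = _pulse_recording(montage, onset_ms=10_000.0)
        events = pd.DataFrame(
            [{"onset_ms": 10_000.0, "category": "distractor"}])
        ep = epoch_continuous(cont, events, montage)
        assert ep.n_samples == 276
        t_idx = int(np.argmax(ep.data[0, 0]))
        assert ep.times_ms[t_idx] == 0.0
        assert list(ep.labels) == ["distractor"]

    def test_zero_events_empty_epochset(self, montage):
        cont = _pulse_recording(montage, onset_ms=10_000.0)
        ep = epoch_continuous(cont, pd.DataFrame(columns=["onset_ms",
                                                          "category"]),
                              montage)
        assert ep.n_epochs == 0 and ep.n_samples == 276

    def test_overlapping_epochs_match_direct_slicing(self, montage, rng):
        cont = ContinuousEEG(rng.standard_normal((91, 5000)), 250.0,
                             montage.names)
        events = pd.DataFrame(
            [{"onset_ms": 4000.0, "category": "distractor"},
             {"onset_ms": 4400.0, "category": "distractor"}])
        ep = epoch_continuous(cont, events, montage)
        for k, onset in enumerate((4000.0, 4400.0)):
            i0 = int(round(onset * 0.25)) - 75
            np.testing.assert_array_equal(ep.data[k],
                                          cont.data[:, i0:i0 + 276])

    def test_edge_event_skipped_or_strict_error(self, montage):
        cont = _pulse_recording(montage, onset_ms=10_000.0, dur_s=12.0)
        events = pd.DataFrame(
            [{"onset_ms": 11_900.0, "category": "distractor"},
             {"onset_ms": 5000.0, "category": "distractor"}])
        ep = epoch_continuous(cont, events, montage)
        assert ep.n_epochs == 1
        with pytest.raises(PreprocessError, match="edge"):
            epoch_continuous(cont, events, montage, strict=True)


class TestBaseline:
    def test_zero_mean_and_idempotent(self, healthy_small):
        out = baseline_correct(healthy_small)
        mask = (out.times_ms >= -300) & (out.times_ms < 0)
        np.testing.assert_allclose(
            out.data[:, :, mask].mean(axis=2), 0.0, atol=1e-4)
        again = baseline_correct(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-4)

    def test_whole_epoch_mode(self, healthy_small):
        out = baseline_correct(healthy_small, "whole_epoch")
        np.testing.assert_allclose(out.data.mean(axis=2), 0.0, atol=1e-4)

    def test_empty_window_errors(self, healthy_small):
        with pytest.raises(PreprocessError, match="no samples"):
            baseline_correct(healthy_small, (900.0, 1000.0))


class TestRejection:
    def test_injected_bad_channel_and_epoch_flagged(self, montage):
        prof = builtin_profiles()["NULL"]
        prof.n_trials = {"explicit_target": 10, "implicit_target": 10,
                         "distractor": 10}
        ep = simulate_epochs(prof, montage, rng=2)
        from p3attn.simulate import inject_variance_spike
        ep = inject_variance_spike(ep, channel=7, factor=10.0)
        ep = inject_variance_spike(ep, epoch=3, factor=10.0)
        report = detect_bad(ep)
        assert montage.names[7] in report.bad_channels
        assert 3 in report.bad_epochs
        cleaned = apply_rejection(ep, report)
        assert cleaned.n_epochs == ep.n_epochs - len(report.bad_epochs)

    def test_clean_data_rarely_flagged(self, montage):
        prof = builtin_profiles()["NULL"]
        prof.n_trials = {"explicit_target": 12, "implicit_target": 12,
                         "distractor": 12}
        frac = []
        for seed in range(15):
            ep = simulate_epochs(prof, montage, rng=100 + seed)
            rep = detect_bad(ep)
            frac.append((len(rep.bad_channels) + len(rep.bad_epochs))
                        / (ep.n_channels + ep.n_epochs))
        assert np.mean(frac) <= 0.05

    def test_report_json_round_trip(self, montage):
        rep = RejectionReport(["E07"], [3], {"E07": 9.0}, [1.0, 9.0],
                              5.0, 4.0)
        clone = RejectionReport.from_json(rep.to_json())
        assert clone == rep

    def test_too_small_input_rejected(self, montage, times, rng):
        ep = EpochSet(rng.standard_normal((4, 91, len(times))), times,
                      np.array(["distractor"] * 4, dtype=object), montage)
        with pytest.raises(PreprocessError, match="at least 8"):
            detect_bad(ep)


def _sph_harm_map(positions, degree):
    x, y, z = positions.T
    if degree == 1:
        return z
    if degree == 2:
        return x * z
    if degree == 3:
        return x * (5 * z**2 - 1)
    raise ValueError


class TestSphericalSpline:
    def _epochs_from_map(self, montage, values):
        data = np.tile(values[np.newaxis, :, np.newaxis], (2, 1, 4))
        times = np.arange(4) * 4.0
        return EpochSet(data, times, np.array(["distractor"] * 2,
                                              dtype=object), montage)

    def test_constant_map_reconstructed_exactly(self, montage):
        ep = self._epochs_from_map(montage, np.full(91, 3.7))
        out = interpolate_channels(ep, [montage.names[10]])
        np.testing.assert_allclose(out.data[:, 10], 3.7, atol=1e-8)

    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_low_degree_harmonics_within_5pct_rms(self, montage, degree):
        values = _sph_harm_map(montage.positions, degree)
        bad = [montage.names[i] for i in (5, 40, 77)]
        ep = self._epochs_from_map(montage, values)
        out = interpolate_channels(ep, bad)
        idx = [montage.index(n) for n in bad]
        err = out.data[0, idx, 0] - values[idx]
        rms_rel = np.sqrt((err**2).mean()) / np.sqrt((values**2).mean())
        assert rms_rel < 0.05

    def test_leave_one_out_recovers_smooth_simulated_maps(self, montage):
        """Deleting a good channel and interpolating it back lands within
        the smooth-map variation of its true value."""
        from p3attn.simulate import make_template
        values = 5.0 * make_template("P3a", montage).spatial_map
        ep = self._epochs_from_map(montage, values)
        M = interpolation_matrix(montage, [montage.names[20]])
        good = [i for i in range(91) if i != 20]
        est = float((M @ values[good])[0])
        assert est == pytest.approx(values[20], abs=0.15 * values.std())

    def test_good_channels_untouched(self, montage, rng):
        values = rng.standard_normal(91)
        ep = self._epochs_from_map(montage, values)
        out = interpolate_channels(ep, [montage.names[0]])
        np.testing.assert_array_equal(out.data[:, 1:], ep.data[:, 1:])

    def test_too_many_bad_channels(self, montage):
        ep = self._epochs_from_map(montage, np.ones(91))
        with pytest.raises(PreprocessError, match="20%"):
            interpolate_channels(ep, list(montage.names[:20]))


class TestAverageReference:
    def test_zero_mean_idempotent_and_gfp_invariant(self, healthy_small):
        out = average_reference(healthy_small)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-4)
        assert out.reference == "average"
        again = average_reference(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-3)
        erp = healthy_small.average("explicit_target")
        erp_ref = out.average("explicit_target")
        np.testing.assert_allclose(pa.gfp(erp), pa.gfp(erp_ref), atol=1e-4)

    def test_provenance_records_steps(self, healthy_small):
        out = average_reference(baseline_correct(healthy_small))
        steps = [p["step"] for p in out.provenance]
        assert steps[-2:] == ["baseline_correct", "average_reference"]
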