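"""Tests of the synthetic long-call generator: feature tables, F0 contours,
audio rendering, and whole-recording datasets."""

import numpy as np
import pandas as pd
import pytest

import longcall as lc
from longcall.synthetic import (
    CORE_FEATURES,
    DEFAULT_CLUSTER_MEANS,
    HIGH_CLASSES,
    feature_columns,
    simulate_observer_labels,
)


class TestFeatureTable:
    def test_two_archetypes_separate_without_grading(self):
        spec = lc.SyntheticSpec(n_pulses=200, graded_fraction=0.0,
                                n_extra_features=0, seed=3)
        table, _ = lc.generate_feature_table(spec)
        high = table["true_class"].isin(HIGH_CLASSES)
        # any frequency feature separates the two latent clusters
        assert table.loc[high, "center_freq"].min() > table.loc[~high, "center_freq"].mean()
        assert table.loc[high, "center_freq"].mean() > 380
        assert table.loc[~high, "center_freq"].mean() < 300

    def test_determinism_under_fixed_seed(self):
        spec = lc.SyntheticSpec(n_pulses=150, seed=11)
        t1, _ = lc.generate_feature_table(spec)
        t2, _ = lc.generate_feature_table(lc.SyntheticSpec(n_pulses=150, seed=11))
        pd.testing.assert_frame_equal(t1, t2)

    @pytest.mark.parametrize("cls,feature,mean", [
        ("SI", "center_freq", 203.0),
        ("VO", "center_freq", 483.1),
        ("LR", "freq_q1", 231.4),
    ])
    def test_class_means_match_archetypes(self, cls, feature, mean):
        """Sample means recover the archetype means within 3 standard errors."""
        spec = lc.SyntheticSpec(
            n_pulses=500, graded_fraction=0.0, n_extra_features=0, seed=5,
            class_probs={c: 1 / 6 for c in lc.synthetic.PULSE_CLASSES})
        table, _ = lc.generate_feature_table(spec)
        vals = table.loc[table["true_class"] == cls, feature]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - mean) < 3 * se

    def test_graded_pulses_interpolate_between_archetypes(self):
        spec = lc.SyntheticSpec(n_pulses=400, graded_fraction=1.0,
                                n_extra_features=0, seed=9)
        table, truth = lc.generate_feature_table(spec)
        lam = table["gradedness"].to_numpy()
        # center frequency tracks lambda monotonically (strong correlation)
        r = np.corrcoef(lam, table["center_freq"])[0, 1]
        assert r > 0.9
        # lambda banding drives the labels
        assert (table.loc[lam <= spec.lambda_low, "true_class"]
                .isin(lc.synthetic.LOW_CLASSES).all())
        assert (table.loc[lam >= spec.lambda_high, "true_class"]
                .isin(HIGH_CLASSES).all())
        mid = (lam > spec.lambda_low) & (lam < spec.lambda_high)
        assert (table.loc[mid, "true_class"] == "IN").all()

    def test_invalid_spec_names_offending_field(self):
        spec = lc.SyntheticSpec(class_probs={"HU": 0.5, "SI": 0.2})
        with pytest.raises(ValueError, match="class_probs"):
            lc.generate_feature_table(spec)
        with pytest.raises(ValueError, match="graded_fraction"):
            lc.generate_feature_table(lc.SyntheticSpec(graded_fraction=1.5))

    def test_physical_orderings_hold(self):
        table, _ = lc.generate_feature_table(lc.SyntheticSpec(n_pulses=300, seed=2))
        assert (table["freq_q1"] <= table["center_freq"]).all()
        assert (table["center_freq"] <= table["freq_q3"]).all()
        assert (table["f0_min"] <= table["f0_max"]).all()
        assert (table["duration"] >= 0.2).all()


class TestContours:
    def test_roar_peaks_at_requested_height_near_midpoint(self):
        c = lc.synthesize_f0_contour(
            "Roar", {"family": "roar", "peak_hz": 600.0}, 1.0, seed=1)
        assert np.nanmax(c.f0_hz) == pytest.approx(600.0)
        rel = c.frame_times[np.nanargmax(c.f0_hz)] / c.frame_times[-1]
        assert 0.35 <= rel <= 0.65

    def test_sigh_is_non_increasing_from_start(self):
        c = lc.synthesize_f0_contour(
            "Sigh", {"family": "sigh", "start_hz": 300.0}, 1.0, seed=1)
        f = c.f0_hz[c.voiced]
        assert f[0] == np.nanmax(c.f0_hz)
        assert np.all(np.diff(f) <= 1e-9)

    def test_huitus_has_interior_unvoiced_gap(self):
        c = lc.synthesize_f0_contour("HU", duration_s=0.8, seed=4)
        v = c.voiced
        assert v[0] and v[-1]
        assert (~v[1:-1]).any()

    def test_unknown_class_lists_registered(self):
        with pytest.raises(ValueError, match="registered"):
            lc.synthesize_f0_contour("warble", duration_s=1.0)

    def test_short_pulse_rejected(self):
        with pytest.raises(ValueError, match="0.2"):
            lc.synthesize_f0_contour("Roar", duration_s=0.1)


class TestAudio:
    SR = 5512.5

    def test_constant_tone_lands_in_correct_bin(self):
        from longcall.types import F0Contour
        t = np.arange(100) / 100
        c = F0Contour(t, np.full(100, 400.0))
        audio = lc.synthesize_pulse_audio(c, n_harmonics=1, snr_db=None,
                                          sample_rate=self.SR, seed=0)
        spec = lc.compute_spectrogram(audio, self.SR)
        peak_bins = spec.bin_freqs[np.argmax(spec.magnitudes_db, axis=1)]
        med = np.median(peak_bins)
        assert abs(med - 400.0) <= spec.bin_spacing

    def test_all_unvoiced_contour_gives_noise_only_clip(self):
        from longcall.types import F0Contour
        c = F0Contour(np.arange(50) / 100, np.full(50, np.nan))
        audio = lc.synthesize_pulse_audio(c, sample_rate=self.SR, seed=0)
        f0 = lc.track_f0(lc.compute_spectrogram(audio, self.SR))
        assert f0.n_voiced == 0

    def test_roar_roundtrip_recovers_peak(self):
        """Synthesize -> track round trip is near-identity for tonal pulses."""
        c = lc.synthesize_f0_contour(
            "Roar", {"family": "roar", "peak_hz": 600.0}, 1.0, seed=3)
        audio = lc.synthesize_pulse_audio(c, snr_db=30.0, sample_rate=self.SR, seed=0)
        spec = lc.compute_spectrogram(audio, self.SR)
        f0 = lc.track_f0(spec)
        assert abs(f0.f0_max - 600.0) <= 2 * spec.bin_spacing

    def test_aliasing_precondition_enforced(self):
        from longcall.types import F0Contour
        c = F0Contour(np.arange(50) / 100, np.full(50, 1000.0))
        with pytest.raises(ValueError, match="alias"):
            lc.synthesize_pulse_audio(c, n_harmonics=5, sample_rate=self.SR)

    def test_deterministic_under_seed(self):
        c = lc.synthesize_f0_contour("Roar", duration_s=0.5, seed=1)
        a1 = lc.synthesize_pulse_audio(c, sample_rate=self.SR, seed=9)
        a2 = lc.synthesize_pulse_audio(c, sample_rate=self.SR, seed=9)
        np.testing.assert_array_equal(a1, a2)


class TestLongcallDataset:
    def _small_spec(self, **kw):
        defaults = dict(n_males=2, calls_per_male=2, pulses_per_call=(2, 3),
                        silence_range=(0.3, 0.6), seed=21)
        defaults.update(kw)
        return lc.SyntheticSpec(**defaults)

    def test_males_times_calls_recordings(self):
        recs, ann, truth = lc.generate_longcall_dataset(self._small_spec())
        assert len(recs) == 4  # n_males x calls_per_male
        assert set(ann["male_id"]) == {"M00", "M01"}

    def test_annotations_bound_pulse_energy(self):
        """>= 90% of each recording's pulse RMS energy lies inside bounds."""
        recs, ann, _ = lc.generate_longcall_dataset(self._small_spec(seed=5))
        for rec_id, grp in ann.groupby("recording_id"):
            sr, samples = recs[rec_id]
            inside = np.zeros(len(samples), dtype=bool)
            for _, row in grp.iterrows():
                i0 = int(round(row.begin_time * sr))
                i1 = int(round(row.end_time * sr))
                inside[i0:i1] = True
            total = float((samples**2).sum())
            assert (samples[inside] ** 2).sum() >= 0.9 * total

    def test_zero_pulses_degenerate(self):
        recs, ann, truth = lc.generate_longcall_dataset(
            self._small_spec(pulses_per_call=(0, 0)))
        assert len(ann) == 0
        assert len(recs) == 0
        assert truth == []

    def test_wav_files_written(self, tmp_path):
        lc.generate_longcall_dataset(self._small_spec(), out_dir=tmp_path)
        wavs = list(tmp_path.glob("*.wav"))
        assert len(wavs) == 4


def test_simulated_observers_mostly_agree():
    labels = ["SI"] * 50 + ["HR"] * 50
    obs = simulate_observer_labels(labels, accuracy=0.9, seed=0)
    assert set(obs) == {"obs1", "obs2", "obs3"}
    agree = np.mean([a == b for a, b in zip(obs["obs1"], labels)])
    assert agree > 0.8
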