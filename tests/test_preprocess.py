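"""Preprocessing-chain tests: OD, TDDR, short-channel regression, MBLL,
band-pass, epoching."""

import numpy as np
import pandas as pd
import pytest

from nirsaware import (
    GroundTruth,
    ParadigmSpec,
    State,
    bandpass,
    epochs_from_runs,
    forward_to_intensity,
    make_epochs,
    mbll,
    preprocess_run,
    regress_short_channel,
    simulate_concentrations,
    simulate_run,
    tddr,
    to_optical_density,
)
from nirsaware.preprocess import HbSeries, ODSeries, PreprocessConfig, _detrend_epochs
from nirsaware.io import RawRecording


FS = 6.94


def _od_from(montage, arr):
    return ODSeries(od=arr, sampling_rate=FS, montage=montage)


class TestOpticalDensity:
    def test_constant_channel_gives_zero(self, quiet_run):
        rec, _ = quiet_run
        const = RawRecording(
            intensities=np.full_like(rec.intensities, 2.5),
            sampling_rate=rec.sampling_rate, montage=rec.montage,
            events=rec.events,
        )
        od = to_optical_density(const)
        assert np.allclose(od.od, 0.0)

    def test_analytic_value(self, montage):
        n = 100
        i = np.ones((montage.n_channels, 2, n))
        # one sample at mean * exp(-0.5) must map to od = 0.5 (up to the
        # change of the mean itself, so use a long series)
        i[0, 0, 0] = np.exp(-0.5)
        events = pd.DataFrame({"onset": [1.0], "duration": [1.0],
                               "trial_type": ["IMAGERY"]})
        rec = RawRecording(intensities=i, sampling_rate=FS, montage=montage,
                           events=events)
        od = to_optical_density(rec)
        mean = i[0, 0].mean()
        assert od.od[0, 0, 0] == pytest.approx(0.5 - np.log(1 / mean))

    def test_intensity_scale_invariance(self, quiet_run):
        rec, _ = quiet_run
        od1 = to_optical_density(rec)
        scaled = RawRecording(intensities=3.7 * rec.intensities,
                              sampling_rate=rec.sampling_rate,
                              montage=rec.montage, events=rec.events)
        od2 = to_optical_density(scaled)
        assert np.allclose(od1.od, od2.od)


class TestTDDR:
    def test_clean_signal_preserved(self, montage):
        # integer number of periods (400 s of 0.05 Hz): the repair removes
        # any net linear drift of the slow component, so a fractional final
        # period would read as drift by design
        n = int(400 * FS)
        t = np.arange(n) / FS
        sig = 0.05 * np.sin(2 * np.pi * 0.05 * t)
        arr = np.tile(sig, (montage.n_channels, 2, 1))
        out = tddr(_od_from(montage, arr))
        r = np.corrcoef(out.od[0, 0], sig)[0, 1]
        assert r >= 0.99

    def test_step_artifact_suppressed(self, montage):
        rng = np.random.default_rng(0)
        n = int(400 * FS)
        t = np.arange(n) / FS
        # noise-dominated derivative (TDDR's operating regime) with a small
        # slow oscillation riding on top
        clean = 0.01 * np.sin(2 * np.pi * 0.05 * t) + rng.normal(0, 0.002, n)
        robust_sd = 1.4826 * np.median(np.abs(np.diff(clean)))
        spiky = clean.copy()
        spiky[n // 2:] += 50 * robust_sd        # baseline shift
        arr = np.zeros((montage.n_channels, 2, n))
        arr[0, 0] = spiky
        out = tddr(_od_from(montage, arr)).od[0, 0]

        def rms_centered(x):
            # the DC level of an optical-density change is arbitrary
            return np.sqrt(np.mean((x - x.mean()) ** 2))

        dev_before = rms_centered(spiky - clean)
        dev_after = rms_centered(out - clean)
        assert dev_after <= 0.1 * dev_before

    def test_shape_preserved_and_short_input_rejected(self, montage):
        arr = np.random.default_rng(1).normal(size=(montage.n_channels, 2, 50))
        assert tddr(_od_from(montage, arr)).od.shape == arr.shape
        with pytest.raises(ValueError):
            tddr(_od_from(montage, arr[:, :, :2]))

    def test_matches_reference_implementation(self, montage):
        """Independent oracle: the published algorithm as shipped in MNE."""
        mne_tddr = pytest.importorskip("mne.preprocessing.nirs._tddr")
        rng = np.random.default_rng(2)
        t = np.arange(2000) / FS
        sig = 0.04 * np.sin(2 * np.pi * 0.08 * t) + rng.normal(0, 0.01, len(t))
        sig[800:] += 0.3
        arr = np.zeros((montage.n_channels, 2, len(t)))
        arr[0, 0] = sig
        ours = tddr(_od_from(montage, arr)).od[0, 0]
        theirs = mne_tddr._TDDR(sig.copy(), FS)
        assert np.corrcoef(ours, theirs)[0, 1] > 0.999


class TestShortChannelRegression:
    def test_proportional_signal_removed(self, montage):
        rng = np.random.default_rng(3)
        n = 1000
        short = rng.normal(size=n)
        arr = np.zeros((montage.n_channels, 2, n))
        arr[montage.short_channel_index] = short
        for c in montage.long_indices:
            arr[c] = 2.0 * short
        out = regress_short_channel(_od_from(montage, arr))
        assert np.max(np.abs(out.od)) < 1e-10
        assert out.od.shape[0] == montage.n_long
        assert not out.montage.has_short

    def test_orthogonal_signal_untouched(self, montage):
        n = 2000
        t = np.arange(n)
        short = np.sin(2 * np.pi * t / 40)
        long = np.cos(2 * np.pi * t / 40)
        arr = np.zeros((montage.n_channels, 2, n))
        arr[montage.short_channel_index] = short
        j = montage.long_indices[0]
        arr[j] = long
        out = regress_short_channel(_od_from(montage, arr))
        assert np.allclose(out.od[0, 0], long, atol=1e-6)

    def test_recovers_evoked_against_generator_truth(self, default_spec,
                                                     montage):
        truth = GroundTruth(mayer_amp=0.8, cardiac_amp=0.0, drift_slope=0.0,
                            white_noise_sd=0.0, intensity_noise_sd=0.0, seed=4)
        conc = simulate_concentrations(default_spec, montage, truth)
        rec = forward_to_intensity(conc, montage, truth)
        od = regress_short_channel(to_optical_density(rec))
        hb = mbll(od)
        ch = np.argmax(np.abs(conc.evoked_hbo).max(axis=1))
        pos = list(montage.long_indices).index(ch)
        r = np.corrcoef(hb.hbo[pos], conc.evoked_hbo[ch])[0, 1]
        assert r >= 0.95

    def test_missing_short_channel_raises(self, montage):
        arr = np.random.default_rng(5).normal(size=(montage.n_long, 2, 100))
        od = _od_from(montage.drop_short(), arr)
        with pytest.raises(ValueError):
            regress_short_channel(od)


class TestMBLL:
    def test_forward_inverse_round_trip(self, quiet_run, montage):
        rec, conc = quiet_run
        od = to_optical_density(rec)
        hb = mbll(od)
        # compare on long channels; OD mean-normalization removes each
        # channel's mean concentration, so compare after centring
        for pos, ch in enumerate(montage.long_indices):
            truth_c = conc.hbo[ch] - conc.hbo[ch].mean()
            err = np.sqrt(np.mean((hb.hbo[pos] - truth_c) ** 2))
            rms = np.sqrt(np.mean(truth_c ** 2))
            if rms > 1e-12:
                assert err <= 0.01 * rms

    def test_zero_od_gives_zero_concentration(self, montage):
        od = _od_from(montage, np.zeros((montage.n_channels, 2, 50)))
        hb = mbll(od)
        assert np.allclose(hb.hbo, 0.0) and np.allclose(hb.hbr, 0.0)

    def test_halving_distance_doubles_concentration(self, montage):
        rng = np.random.default_rng(6)
        arr = rng.normal(0, 0.01, size=(montage.n_channels, 2, 64))
        hb1 = mbll(_od_from(montage, arr))
        from nirsaware.montage import Montage

        halved = Montage(
            source_labels=montage.source_labels,
            detector_labels=montage.detector_labels,
            channel_pairs=montage.channel_pairs,
            distances_cm=montage.distances_cm / 2,
            short_channel_index=montage.short_channel_index,
            wavelengths_nm=montage.wavelengths_nm,
        )
        hb2 = mbll(_od_from(halved, arr))
        assert np.allclose(hb2.hbo, 2 * hb1.hbo)


class TestBandpass:
    def _hb(self, montage, sig):
        arr = np.tile(sig, (montage.n_long, 1))
        return HbSeries(hbo=arr, hbr=arr.copy(), sampling_rate=FS,
                        montage=montage.drop_short())

    def test_dc_removed(self, montage):
        hb = bandpass(self._hb(montage, np.ones(4000)))
        assert np.max(np.abs(hb.hbo[:, 500:-500])) < 1e-6

    def test_passband_gain_near_unity(self, montage):
        t = np.arange(8000) / FS
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(self._hb(montage, sig)).hbo[0]
        gain = out[1000:-1000].std() / sig[1000:-1000].std()
        assert 0.9 <= gain <= 1.05

    def test_stopband_attenuation(self, montage):
        t = np.arange(8000) / FS
        sig = np.sin(2 * np.pi * 1.0 * t)
        out = bandpass(self._hb(montage, sig)).hbo[0]
        assert out[1000:-1000].std() <= 0.05 * sig[1000:-1000].std()

    def test_invalid_band_rejected(self, montage):
        hb = self._hb(montage, np.ones(100))
        with pytest.raises(ValueError):
            bandpass(hb, 0.4, 0.1)
        with pytest.raises(ValueError):
            bandpass(hb, 0.1, 10.0)


class TestEpochs:
    def test_two_runs_give_sixty_epochs(self):
        from nirsaware import simulate_dataset

        runs = simulate_dataset(State.RESPONSIVE, n_runs=2, seed=0)
        ep = epochs_from_runs(runs, "HBO")
        assert ep.n_trials == 60
        assert (ep.labels == "IMAGERY").sum() == 30

    def test_epoch_length_84_samples(self, quiet_run):
        rec, _ = quiet_run
        hb = preprocess_run(rec)
        ep = make_epochs(hb, rec.events, "HBO")
        assert ep.data.shape[2] == int(np.floor(12 * FS)) + 1 == 84

    def test_channel_doubling_for_both(self, quiet_run, montage):
        rec, _ = quiet_run
        hb = preprocess_run(rec)
        assert make_epochs(hb, rec.events, "BOTH").n_channels == 2 * montage.n_long
        assert make_epochs(hb, rec.events, "HBR").n_channels == montage.n_long

    def test_detrended_slope_is_zero(self, quiet_run):
        rec, _ = quiet_run
        hb = preprocess_run(rec)
        ep = make_epochs(hb, rec.events, "BOTH")
        n = ep.data.shape[2]
        t = np.arange(n) - (n - 1) / 2
        slopes = ep.data @ t / (t @ t)
        assert np.max(np.abs(slopes)) < 1e-10

    def test_late_onset_dropped_with_warning(self, quiet_run):
        rec, _ = quiet_run
        hb = preprocess_run(rec)
        ev = rec.events.copy()
        ev.loc[len(ev)] = [575.0, 3.0, "IMAGERY"]
        with pytest.warns(UserWarning, match="dropping epoch"):
            ep = make_epochs(hb, ev, "HBO")
        assert ep.n_trials == len(rec.events)

    def test_no_epochs_raises(self, quiet_run):
        rec, _ = quiet_run
        hb = preprocess_run(rec)
        ev = pd.DataFrame({"onset": [579.9], "duration": [3.0],
                           "trial_type": ["IMAGERY"]})
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            make_epochs(hb, ev, "HBO")


class TestPipelineProperties:
    def test_deterministic(self, quiet_run):
        rec, _ = quiet_run
        ep1 = make_epochs(preprocess_run(rec), rec.events, "BOTH")
        ep2 = make_epochs(preprocess_run(rec), rec.events, "BOTH")
        assert np.array_equal(ep1.data, ep2.data)

    def test_condition_contrast_recovers_evoked_shape(self, montage):
        spec = ParadigmSpec(state=State.RESPONSIVE)
        truth = GroundTruth(mayer_amp=0.0, cardiac_amp=0.0, drift_slope=0.0,
                            white_noise_sd=0.0, intensity_noise_sd=0.0, seed=8)
        rec, conc = simulate_run(spec, montage, truth)
        # TDDR's robust derivative weighting assumes noise-dominated
        # derivatives; on exactly noise-free data it would clip the isolated
        # evoked bumps, so the chain identity is checked with repair off
        hb = preprocess_run(rec, PreprocessConfig(tddr_enabled=False))
        ep = make_epochs(hb, rec.events, "HBO")
        contrast = (ep.data[ep.labels == "IMAGERY"].mean(axis=0)
                    - ep.data[ep.labels == "NO_IMAGERY"].mean(axis=0))
        ch = np.argmax(np.abs(conc.evoked_hbo).max(axis=1))
        pos = list(montage.long_indices).index(ch)
        fs = spec.sampling_rate
        i0 = int(round((40.0 + spec.cue_s) * fs))
        template = conc.evoked_hbo[ch, i0 - int(round(spec.cue_s * fs)):]
        template = template[: ep.data.shape[2]]
        template = template - np.polyval(
            np.polyfit(np.arange(len(template)), template, 1),
            np.arange(len(template)),
        )
        r = np.corrcoef(contrast[pos], template)[0, 1]
        assert r >= 0.95

    def test_unresponsive_contrast_is_flat(self, montage):
        spec = ParadigmSpec(state=State.UNRESPONSIVE)
        truth = GroundTruth(mayer_amp=0.0, cardiac_amp=0.0, drift_slope=0.0,
                            white_noise_sd=0.0, intensity_noise_sd=0.0, seed=8)
        rec, conc = simulate_run(spec, montage, truth)
        ep = make_epochs(preprocess_run(rec), rec.events, "HBO")
        contrast = (ep.data[ep.labels == "IMAGERY"].mean(axis=0)
                    - ep.data[ep.labels == "NO_IMAGERY"].mean(axis=0))
        assert np.max(np.abs(contrast)) < 1e-8

    def test_config_recorded_in_provenance(self):
        from nirsaware import simulate_dataset

        runs = simulate_dataset(State.RESPONSIVE, n_runs=1, seed=0)
        cfg = PreprocessConfig(band_high_hz=0.3)
        ep = epochs_from_runs(runs, "HBO", cfg)
        assert ep.provenance["config"]["band_high_hz"] == 0.3
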