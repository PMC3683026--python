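"""Preprocessing: filter contracts, montages, epoching, sub-bands, I/O."""

import numpy as np
import pytest
from scipy.signal import periodogram

import eegdetect as ed
from eegdetect.montage import default_neighbor_graph
from eegdetect.preprocess import (
    BAND_NAMES,
    ConfigurationError,
    MontageError,
    epoch_index_table,
    read_recording_csv,
    rejection_mask,
)
from tests.conftest import make_epoch

FS = 200.0


def tone(freq, n, amp=10.0):
    """Whole-cycle tone fixture: endpoints at zero crossings, so the
    measurement probes steady-state filter response, not edge transients."""
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / FS)


def recording(x, labels):
    return ed.EegRecording(np.tile(x, (len(labels), 1)), labels, FS)


class TestFilterChain:
    def test_notch_removes_mains(self, sim_channels):
        x = tone(60.0, 4001)
        out = ed.filter_chain(recording(x, sim_channels))
        assert out.data[0].std() < 0.05 * x.std()

    def test_passband_preserves_alpha(self, sim_channels):
        x = tone(10.0, 4001)
        out = ed.filter_chain(recording(x, sim_channels))
        assert out.data[0].std() == pytest.approx(x.std(), rel=0.10)

    def test_highpass_removes_dc(self, sim_channels):
        rec = ed.EegRecording(np.full((16, 4001), 50.0), sim_channels, FS)
        out = ed.filter_chain(rec)
        assert np.abs(out.data.mean(axis=1)).max() < 1.0

    def test_low_sampling_rate_rejected(self, sim_channels):
        rec = ed.EegRecording(np.zeros((16, 1000)), sim_channels, 100.0)
        with pytest.raises(ConfigurationError):
            ed.filter_chain(rec)

    def test_denoise_switch_changes_output(self, sim_channels):
        rng = np.random.default_rng(0)
        rec = ed.EegRecording(rng.standard_normal((16, 2000)) * 10, sim_channels, FS)
        a = ed.filter_chain(rec, wavelet_denoise=True)
        b = ed.filter_chain(rec, wavelet_denoise=False)
        assert not np.allclose(a.data, b.data)


class TestBipolarDerivation:
    def test_identical_electrodes_cancel(self, montage, sim_channels):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((16, 100))
        rec = ed.EegRecording(data, sim_channels, FS)
        rec.data[sim_channels.index("F8")] = rec.data[sim_channels.index("T4")]
        bip = ed.derive_bipolar(rec, montage)
        assert np.allclose(bip.channel("F8-T4"), 0.0)

    def test_constant_offset_pair(self, montage, sim_channels):
        rec = ed.EegRecording(np.zeros((16, 50)), sim_channels, FS)
        rec.data[sim_channels.index("Fp1")] = 7.0
        bip = ed.derive_bipolar(rec, montage)
        assert np.allclose(bip.channel("Fp1-F7"), 7.0)

    def test_matches_direct_subtraction_oracle(self, montage):
        # a 21-channel recording including midline electrodes
        labels = tuple(list(ed.SimConfig().channels) + ["Fz", "Cz", "Pz", "A1", "A2"])
        rng = np.random.default_rng(2)
        rec = ed.EegRecording(rng.standard_normal((21, 200)), labels, FS)
        bip = ed.derive_bipolar(rec, montage)
        for (anode, cathode), lab in zip(montage.bipolar_pairs, bip.labels):
            want = rec.data[labels.index(anode)] - rec.data[labels.index(cathode)]
            assert np.array_equal(bip.channel(lab), want)

    def test_linearity(self, montage, sim_channels):
        rng = np.random.default_rng(3)
        a = ed.EegRecording(rng.standard_normal((16, 80)), sim_channels, FS)
        b = ed.EegRecording(rng.standard_normal((16, 80)), sim_channels, FS)
        ab = ed.EegRecording(a.data + b.data, sim_channels, FS)
        lhs = ed.derive_bipolar(ab, montage).data
        rhs = ed.derive_bipolar(a, montage).data + ed.derive_bipolar(b, montage).data
        assert np.allclose(lhs, rhs)

    def test_missing_electrode_named_in_error(self, montage):
        rec = ed.EegRecording(np.zeros((2, 10)), ("Fp1", "Fp2"), FS)
        with pytest.raises(MontageError, match="F7"):
            ed.derive_bipolar(rec, montage)


class TestEpochingAndRejection:
    def test_single_hot_sample_drops_its_epoch(self, sim_channels):
        data = np.zeros((16, 2000))
        data[4, 2 * 400 + 17] = 101.0
        rec = ed.EegRecording(data, sim_channels, FS)
        epochs = ed.epoch_and_reject(rec)
        assert [e.index for e in epochs] == [0, 1, 3, 4]

    def test_threshold_is_strict(self, sim_channels):
        rec = ed.EegRecording(np.full((16, 1200), 99.0), sim_channels, FS)
        assert len(ed.epoch_and_reject(rec)) == 3
        rec = ed.EegRecording(np.full((16, 1200), 100.0), sim_channels, FS)
        assert len(ed.epoch_and_reject(rec)) == 3  # exactly 100 survives
        rec = ed.EegRecording(np.full((16, 1200), -100.5), sim_channels, FS)
        assert len(ed.epoch_and_reject(rec)) == 0  # absolute value

    def test_trailing_partial_window_dropped(self, sim_channels):
        rec = ed.EegRecording(np.zeros((16, 900)), sim_channels, FS)
        assert len(ed.epoch_and_reject(rec)) == 2

    def test_empty_recording_gives_empty_list(self, sim_channels):
        rec = ed.EegRecording(np.zeros((16, 100)), sim_channels, FS)
        assert ed.epoch_and_reject(rec) == []

    def test_epoching_is_index_stable(self, sim_channels):
        rng = np.random.default_rng(4)
        first = rng.standard_normal((16, 1200)) * 10
        second = rng.standard_normal((16, 800)) * 10
        rec1 = ed.EegRecording(first, sim_channels, FS)
        rec12 = ed.EegRecording(np.hstack([first, second]), sim_channels, FS)
        e1 = ed.epoch_and_reject(rec1)
        e12 = ed.epoch_and_reject(rec12)
        for a, b in zip(e1, e12):
            assert a.index == b.index
            assert np.array_equal(a.data, b.data)

    def test_rejection_shared_between_montage_views(self, montage, sim_channels):
        rec, gt = ed.simulate_dataset(8, 4, 0, seed=21)
        # plant an artifact in epoch 1
        rec.data[0, 450] = 150.0
        uni, bip = ed.make_epoch_pairs(rec, montage, truth_labels=gt.labels)
        assert [e.index for e in uni] == [e.index for e in bip]
        assert 1 not in [e.index for e in uni]
        assert all(e.montage == "unipolar" for e in uni)
        assert all(e.montage == "bipolar" for e in bip)

    def test_index_table_reports_reason(self, sim_channels):
        data = np.zeros((16, 1200))
        data[0, 500] = 250.0
        rec = ed.EegRecording(data, sim_channels, FS)
        table = epoch_index_table(rec)
        assert list(table["kept_flag"]) == [True, False, True]
        assert table.loc[1, "reject_reason"].startswith("amplitude")


class TestSubbands:
    @pytest.mark.parametrize("method", ["wavelet", "fir"])
    @pytest.mark.parametrize("freq,band", [(6.0, "theta"), (40.0, "gamma")])
    def test_pure_tone_lands_in_its_band(self, sim_channels, method, freq, band):
        x = tone(freq, 400, amp=5.0)
        ep = make_epoch(np.tile(x, (16, 1)), sim_channels, "unipolar")
        sb = ed.decompose_bands(ep, method=method)
        energies = {name: float((arr[0] ** 2).sum()) for name, arr in sb.bands.items()}
        assert energies[band] / sum(energies.values()) >= 0.8

    @pytest.mark.parametrize("method", ["wavelet", "fir"])
    def test_band_energy_tracks_bandwidth_on_white_noise(self, sim_channels, method):
        """Flat-spectrum input: per-band energy proportional to bandwidth,
        checked against a periodogram oracle on the same epochs (averaged
        over seeds to tame the high variance of the few sub-4 Hz bins)."""
        ratios = {name: [] for name, _, _ in ed.BANDS}
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(400)
            ep = make_epoch(np.tile(x, (16, 1)), sim_channels, "unipolar")
            sb = ed.decompose_bands(ep, method=method)
            f, p = periodogram(x, fs=FS)
            for name, lo, hi in ed.BANDS:
                got = (sb.bands[name][0] ** 2).sum()
                want = p[(f >= lo) & (f < hi)].sum() / p.sum() * (x ** 2).sum()
                ratios[name].append(got / want)
        for name, r in ratios.items():
            assert 0.5 <= np.mean(r) <= 2.0, (name, np.mean(r))

    @pytest.mark.parametrize("method", ["wavelet", "fir"])
    def test_bands_reconstruct_the_epoch(self, sim_channels, method):
        rec, _ = ed.simulate_dataset(1, 0, 0, seed=13)
        filt = ed.filter_chain(rec)
        ep = make_epoch(filt.data[:, :400], rec.labels, "unipolar")
        sb = ed.decompose_bands(ep, method=method)
        total = sum(sb.bands.values())
        err = np.linalg.norm(total - ep.data) / np.linalg.norm(ep.data)
        assert err < 0.15

    def test_band_order_and_edges(self):
        assert BAND_NAMES == ("delta", "theta", "alpha", "beta", "gamma")
        assert ed.BANDS[2][1:] == (8.0, 15.0)  # alpha upper edge at 15 Hz

    def test_unknown_method_rejected(self, sim_channels):
        ep = make_epoch(np.zeros((16, 400)), sim_channels, "unipolar")
        with pytest.raises(ConfigurationError):
            ed.decompose_bands(ep, method="dct")


class TestRoundTrips:
    def test_csv_dialect_roundtrip(self, tmp_path, sim_channels):
        rec = ed.generate_background(ed.SimConfig(seed=1, duration_s=4))
        path = tmp_path / "rec.csv"
        ed.write_recording_csv(rec, path)
        back = read_recording_csv(path)
        assert back.labels == rec.labels
        assert back.fs == pytest.approx(rec.fs)
        assert np.allclose(back.data, rec.data, atol=1e-5)

    def test_neighbor_graph_has_six_neighbors(self):
        graph = default_neighbor_graph()
        assert len(graph) == 16
        assert all(len(v) == 6 for v in graph.values())

    def test_rejection_mask_matches_epoching(self, sim_channels):
        rng = np.random.default_rng(8)
        rec = ed.EegRecording(rng.standard_normal((16, 2000)) * 45, sim_channels, FS)
        mask = rejection_mask(rec)
        kept = [e.index for e in ed.epoch_and_reject(rec)]
        assert kept == list(np.flatnonzero(mask))
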