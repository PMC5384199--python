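"""Synthetic-data generator: determinism, coupling calibration, artifacts."""

import numpy as np
import pytest

from ofcnet.connectivity import subject_matrix
from ofcnet.io import Recording
from ofcnet.protocol import EpochSet, SessionProtocol, conditioning_epochs
from ofcnet.spectral import theta_filter
from ofcnet.stats import spearman
from ofcnet.synth import (
    CouplingSpec,
    GroupSpec,
    SimConfig,
    generate_coupled_lfp,
    generate_group_dataset,
    generate_movement_trace,
    generate_plaque_image,
    inject_shock_artifacts,
)


def pair_config(sigma, seed=0, duration=60.0, gain=1.0, fs=1600.0):
    return SimConfig(
        n_channels=2,
        duration=duration,
        fs=fs,
        noise_sd=sigma,
        coupling_spec=(CouplingSpec(("ch0", "ch1"), "all", gain),),
        seed=seed,
    )


def epoch_mean_theta_corr(rec, n_epochs=None):
    eps = [(12 * k + 3.0, 12 * k + 11.0) for k in range(int(rec.duration // 12))]
    if n_epochs:
        eps = eps[:n_epochs]
    vals = []
    for s, e in eps:
        seg = theta_filter(rec.samples[:, int(s * rec.fs):int(e * rec.fs)], rec.fs)
        vals.append(np.corrcoef(seg)[0, 1])
    return float(np.mean(vals))


class TestGenerateCoupledLfp:
    def test_deterministic_under_seed(self):
        a = generate_coupled_lfp(pair_config(1.0, seed=42))
        b = generate_coupled_lfp(pair_config(1.0, seed=42))
        assert np.array_equal(a.samples, b.samples)

    def test_different_seed_differs(self):
        a = generate_coupled_lfp(pair_config(1.0, seed=1))
        b = generate_coupled_lfp(pair_config(1.0, seed=2))
        assert not np.array_equal(a.samples, b.samples)

    def test_noiseless_shared_source_perfectly_correlated(self):
        rec = generate_coupled_lfp(pair_config(0.0, seed=3))
        assert epoch_mean_theta_corr(rec) == pytest.approx(1.0, abs=1e-6)

    def test_uncoupled_channels_near_zero(self):
        cfg = SimConfig(n_channels=2, duration=240.0, noise_sd=1.0, seed=11)
        rec = generate_coupled_lfp(cfg)
        assert abs(epoch_mean_theta_corr(rec)) < 0.05

    def test_invalid_carrier_band_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                n_channels=2, duration=10.0,
                coupling_spec=(CouplingSpec(("ch0", "ch1"), "all", 0.5, band=(8, 3)),),
            )

    def test_band_reaching_nyquist_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                n_channels=2, duration=10.0, fs=100.0,
                coupling_spec=(CouplingSpec(("ch0", "ch1"), "all", 0.5, band=(3, 60)),),
            )

    def test_gain_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                n_channels=2, duration=10.0,
                coupling_spec=(CouplingSpec(("ch0", "ch1"), "all", 1.5),),
            )

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                n_channels=2, duration=10.0,
                coupling_spec=(CouplingSpec(("ch0", "nope"), "all", 0.5),),
            )

    def test_default_labels_for_eight_channels(self):
        cfg = SimConfig(n_channels=8, duration=1.0)
        assert "AI_L" in cfg.labels and "BLA_R" in cfg.labels


class TestInjectShockArtifacts:
    @pytest.fixture
    def short_protocol(self):
        return SessionProtocol(habituation_duration=12.0, conditioning_duration=48.0)

    @pytest.fixture
    def recording(self, short_protocol, rng):
        return Recording(
            samples=rng.standard_normal((2, int(60.0 * 400))),
            fs=400.0,
            labels=("ch0", "ch1"),
        )

    def test_zero_amplitude_identity(self, recording, short_protocol):
        out = inject_shock_artifacts(recording, short_protocol, amplitude=0.0)
        assert np.array_equal(out.samples, recording.samples)

    def test_samples_outside_shocks_untouched(self, recording, short_protocol):
        out = inject_shock_artifacts(recording, short_protocol, amplitude=50.0)
        mask = np.ones(recording.n_samples, dtype=bool)
        for onset, end in short_protocol.shock_intervals():
            mask[int(onset * 400):int(end * 400)] = False
        assert np.array_equal(out.samples[:, mask], recording.samples[:, mask])
        assert not np.array_equal(out.samples[:, ~mask], recording.samples[:, ~mask])

    def test_guard_trimmed_epochs_identical(self, recording, short_protocol):
        out = inject_shock_artifacts(recording, short_protocol, amplitude=50.0)
        for sl in conditioning_epochs(short_protocol).sample_slices(400.0):
            assert np.array_equal(out.samples[:, sl], recording.samples[:, sl])

    def test_shock_outside_recording_rejected(self, recording):
        long_proto = SessionProtocol(habituation_duration=50.0,
                                     conditioning_duration=48.0)
        with pytest.raises(ValueError):
            inject_shock_artifacts(recording, long_proto, amplitude=1.0)


class TestGenerateMovementTrace:
    def test_immobile_fraction(self):
        trace = generate_movement_trace([(10.0, 2.0), (30.0, 5.0)], total=100.0,
                                        fs_beh=30.0)
        assert trace.immobile.mean() == pytest.approx(7.0 / 100.0, abs=1e-9)

    def test_empty_bouts_all_mobile(self):
        trace = generate_movement_trace([], total=50.0)
        assert not trace.immobile.any()

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError):
            generate_movement_trace([(10.0, 5.0), (12.0, 2.0)], total=50.0)

    def test_bout_outside_range_rejected(self):
        with pytest.raises(ValueError):
            generate_movement_trace([(48.0, 5.0)], total=50.0)


class TestGeneratePlaqueImage:
    def test_target_fraction_by_construction(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[5:95, 5:95] = True
        _, truth = generate_plaque_image(mask, 10.0, seed=0)
        burden = 100.0 * truth.sum() / mask.sum()
        assert burden == pytest.approx(10.0, abs=0.5)

    def test_zero_target_empty(self):
        mask = np.ones((50, 50), dtype=bool)
        image, truth = generate_plaque_image(mask, 0.0, seed=0)
        assert not truth.any()

    def test_blobs_inside_region_only(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[20:60, 20:60] = True
        _, truth = generate_plaque_image(mask, 25.0, seed=1)
        assert not (truth & ~mask).any()

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_plaque_image(np.ones((10, 10), dtype=bool), 120.0)

    def test_bad_blob_params_rejected(self):
        with pytest.raises(ValueError):
            generate_plaque_image(
                np.ones((10, 10), dtype=bool), 10.0,
                blob_params={"radius_range": (0, 0)},
            )

    def test_deterministic(self):
        mask = np.ones((60, 60), dtype=bool)
        img1, t1 = generate_plaque_image(mask, 15.0, seed=9)
        img2, t2 = generate_plaque_image(mask, 15.0, seed=9)
        assert np.array_equal(img1, img2) and np.array_equal(t1, t2)


class TestGenerateGroupDataset:
    @pytest.fixture
    def small_protocol(self):
        return SessionProtocol(habituation_duration=60.0, conditioning_duration=48.0)

    def test_deterministic(self, small_protocol):
        spec = GroupSpec(n_subjects=2, fs=400.0)
        a = generate_group_dataset(spec, small_protocol, seed=5)
        b = generate_group_dataset(spec, small_protocol, seed=5)
        for sa, sb in zip(a["subjects"], b["subjects"]):
            assert np.array_equal(sa["recording"].samples, sb["recording"].samples)
            assert np.array_equal(sa["trace"].immobile, sb["trace"].immobile)
            assert sa["plaque_burden"] == sb["plaque_burden"]

    def test_subject_count_and_ids(self, small_protocol):
        spec = GroupSpec(n_subjects=3, fs=400.0)
        data = generate_group_dataset(spec, small_protocol, seed=1)
        assert [s["id"] for s in data["subjects"]] == ["Tg-1", "Tg-2", "Tg-3"]

    def test_elevated_conditioning_coupling_recovered(self, small_protocol):
        spec = GroupSpec(n_subjects=1, fs=400.0)
        data = generate_group_dataset(spec, small_protocol, seed=2)
        rec = data["subjects"][0]["recording"]
        from ofcnet.protocol import habituation_epochs

        hab = subject_matrix(rec, habituation_epochs(small_protocol))
        cond = subject_matrix(rec, conditioning_epochs(small_protocol))
        assert cond.pair("AI_L", "BLA_R") > hab.pair("AI_L", "BLA_R")

    def test_plaque_freezing_monotone_link(self, small_protocol):
        spec = GroupSpec(n_subjects=8, fs=400.0, plaque_noise=0.5)
        data = generate_group_dataset(spec, small_protocol, seed=3)
        freeze = [s["freezing_pct"] for s in data["subjects"]]
        burden = [s["plaque_burden"]["AI"] for s in data["subjects"]]
        res = spearman(np.asarray(burden), np.asarray(freeze))
        assert res.coefficient > 0

    def test_wildtype_spec_has_flat_gains(self):
        wt = GroupSpec.wildtype()
        assert len(set(wt.cond_gains)) == 1
        assert wt.cond_gains[0] == wt.hab_gain
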