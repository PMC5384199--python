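"""Cross-correlation matrices, Euclidean dissimilarity, and trajectories."""

import numpy as np
import pytest

from ofcnet.connectivity import (
    ConnectivityMatrix,
    DEFAULT_REGIONS,
    dissimilarity_trajectory,
    group_matrix,
    matrix_dissimilarity,
    pair_coefficient,
    subject_matrix,
)
from ofcnet.io import Recording
from ofcnet.protocol import EpochSet
from ofcnet.spectral import theta_filter

FS = 400.0


def make_matrix(values, phase="habituation", labels=None):
    n = values.shape[0]
    labels = labels or DEFAULT_REGIONS[:n]
    return ConnectivityMatrix(labels=tuple(labels), values=values, band=(3, 8), phase=phase)


def offdiag_matrix(n, value):
    m = np.full((n, n), float(value))
    np.fill_diagonal(m, 1.0)
    return m


@pytest.fixture
def noise_recording(rng):
    """8 channels of independent noise, 60 s at 400 Hz."""
    return Recording(
        samples=rng.standard_normal((8, int(60 * FS))),
        fs=FS,
        labels=DEFAULT_REGIONS,
    )


@pytest.fixture
def epochs_60s():
    return EpochSet(
        phase="conditioning",
        intervals=tuple((6.0 * k + 1.0, 6.0 * k + 5.0) for k in range(10)),
        window=4.0,
    )


class TestPairCoefficient:
    def test_self_correlation_is_one(self, rng):
        x = theta_filter(rng.standard_normal(4000), FS)
        assert pair_coefficient(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_gives_minus_one(self, rng):
        x = theta_filter(rng.standard_normal(4000), FS)
        assert pair_coefficient(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pair_coefficient(np.zeros(100), np.ones(100))

    def test_lagged_max_recovers_shifted_signal(self, rng):
        x = theta_filter(rng.standard_normal(8000), FS)
        shift = 20  # 50 ms at 400 Hz
        y = np.roll(x, shift)
        zero_lag = pair_coefficient(x[100:-100], y[100:-100])
        lagged = pair_coefficient(x[100:-100], y[100:-100], mode="lagged-max", fs=FS)
        assert lagged > 0.98
        assert lagged > zero_lag

    def test_lagged_max_requires_fs(self, rng):
        x = theta_filter(rng.standard_normal(1000), FS)
        with pytest.raises(ValueError):
            pair_coefficient(x, x, mode="lagged-max")


class TestSubjectMatrix:
    def test_identical_channels_give_all_ones(self, rng, epochs_60s):
        base = rng.standard_normal(int(60 * FS))
        rec = Recording(samples=np.tile(base, (8, 1)), fs=FS, labels=DEFAULT_REGIONS)
        m = subject_matrix(rec, epochs_60s)
        assert np.allclose(m.values, 1.0, atol=1e-9)

    def test_independent_noise_near_zero(self, noise_recording, epochs_60s):
        m = subject_matrix(noise_recording, epochs_60s)
        off = m.values[np.triu_indices(8, k=1)]
        assert np.abs(off.mean()) < 0.05

    def test_matrix_is_mean_of_epoch_stack(self, noise_recording, epochs_60s):
        m = subject_matrix(noise_recording, epochs_60s)
        assert m.epoch_stack.shape[0] == len(epochs_60s)
        direct = m.epoch_stack.mean(axis=0)
        np.fill_diagonal(direct, 1.0)
        assert np.allclose(m.values, direct, atol=1e-12)

    def test_missing_channel_named_in_error(self, noise_recording, epochs_60s):
        with pytest.raises(ValueError, match="HPC_L"):
            subject_matrix(noise_recording, epochs_60s, labels=("AI_L", "HPC_L"))

    def test_permutation_equivariance(self, noise_recording, epochs_60s):
        m = subject_matrix(noise_recording, epochs_60s)
        order = tuple(reversed(DEFAULT_REGIONS))
        rel = m.relabel(order)
        for a in ("AI_L", "BLA_R"):
            for b in ("RSC_L", "ACC_R"):
                assert rel.pair(a, b) == m.pair(a, b)

    def test_fisher_mean_close_to_arithmetic_for_small_r(
        self, noise_recording, epochs_60s
    ):
        m1 = subject_matrix(noise_recording, epochs_60s)
        m2 = subject_matrix(noise_recording, epochs_60s, fisher_mean=True)
        assert np.allclose(m1.values, m2.values, atol=0.02)


class TestGroupMatrix:
    def test_single_subject_identity(self):
        m = make_matrix(offdiag_matrix(4, 0.3))
        g, table = group_matrix([m])
        assert np.array_equal(g.values, m.values)
        assert len(table) == 6  # 4 choose 2 pairs

    def test_two_subjects_average(self):
        a = make_matrix(offdiag_matrix(4, 0.2))
        b = make_matrix(offdiag_matrix(4, 0.6))
        g, _ = group_matrix([a, b])
        assert np.allclose(g.values, offdiag_matrix(4, 0.4))

    def test_subject_order_irrelevant(self):
        a = make_matrix(offdiag_matrix(4, 0.1))
        b = make_matrix(offdiag_matrix(4, 0.5))
        g1, _ = group_matrix([a, b])
        g2, _ = group_matrix([b, a])
        assert np.allclose(g1.values, g2.values)

    def test_label_mismatch_rejected(self):
        a = make_matrix(offdiag_matrix(4, 0.1))
        b = make_matrix(offdiag_matrix(4, 0.1), labels=("w", "x", "y", "z"))
        with pytest.raises(ValueError):
            group_matrix([a, b])


class TestMatrixDissimilarity:
    def test_identical_matrices_zero(self):
        m = make_matrix(offdiag_matrix(8, 0.4))
        assert matrix_dissimilarity(m, m) == 0.0

    def test_single_pair_delta(self):
        a = offdiag_matrix(8, 0.0)
        b = a.copy()
        b[0, 1] = b[1, 0] = 0.37
        assert matrix_dissimilarity(make_matrix(a), make_matrix(b)) == pytest.approx(0.37)

    def test_all_zero_vs_all_one_is_sqrt_28(self):
        a = make_matrix(offdiag_matrix(8, 0.0))
        b = make_matrix(offdiag_matrix(8, 1.0))
        assert matrix_dissimilarity(a, b) == pytest.approx(np.sqrt(28), abs=1e-12)

    def test_matches_brute_force_sum(self, rng):
        for _ in range(50):
            a = rng.uniform(-1, 1, (8, 8))
            b = rng.uniform(-1, 1, (8, 8))
            expected = 0.0
            for i in range(8):
                for j in range(i + 1, 8):
                    expected += (a[i, j] - b[i, j]) ** 2
            assert matrix_dissimilarity(a, b) == pytest.approx(np.sqrt(expected), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            matrix_dissimilarity(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDissimilarityTrajectory:
    def test_constant_quarters_flat_zero(self):
        hab = make_matrix(offdiag_matrix(8, 0.3))
        quarters = [make_matrix(offdiag_matrix(8, 0.3), phase=f"q{k}") for k in range(4)]
        traj = dissimilarity_trajectory(hab, quarters)
        assert traj.values == (0.0, 0.0, 0.0, 0.0)
        assert traj.slope == 0.0

    def test_linear_growth_in_one_pair(self):
        delta = 0.11
        hab = make_matrix(offdiag_matrix(8, 0.0))
        quarters = []
        for k in range(1, 5):
            v = offdiag_matrix(8, 0.0)
            v[0, 1] = v[1, 0] = k * delta
            quarters.append(make_matrix(v, phase=f"q{k}"))
        traj = dissimilarity_trajectory(hab, quarters)
        assert np.allclose(traj.values, [delta, 2 * delta, 3 * delta, 4 * delta])
        assert traj.slope == pytest.approx(delta)

    def test_fewer_than_two_quarters_rejected(self):
        hab = make_matrix(offdiag_matrix(8, 0.0))
        with pytest.raises(ValueError):
            dissimilarity_trajectory(hab, [hab])


class TestConnectivityMatrixInvariants:
    def test_asymmetric_rejected(self):
        v = offdiag_matrix(3, 0.2)
        v[0, 1] = 0.9
        with pytest.raises(ValueError):
            make_matrix(v)

    def test_bad_diagonal_rejected(self):
        v = offdiag_matrix(3, 0.2)
        v[0, 0] = 0.5
        with pytest.raises(ValueError):
            make_matrix(v)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_matrix(offdiag_matrix(3, 1.5))

    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd

        m = make_matrix(offdiag_matrix(4, 0.25))
        m.write(tmp_path / "m.tsv", tmp_path / "m.json")
        back = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
        assert np.allclose(back.to_numpy(), m.values)
        assert list(back.columns) == list(m.labels)
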