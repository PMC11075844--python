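import numpy as np
import pytest

from emgbicoh.hosa import (
    BicoherenceEstimator,
    EstimationError,
    HosaParams,
    average_maps,
    bicoherence,
    bicoherence_bruteforce,
    bispectrum_direct,
    segment_signal,
)
from emgbicoh.records import EmgRecord

from conftest import TINY_PARAMS, tiny_random_record


class TestSegmentation:
    @pytest.mark.parametrize(
        "n,seg,overlap,expected_k",
        [(1024, 256, 0.5, 7), (1024, 256, 0.0, 4), (512, 256, 0.5, 3)],
    )
    def test_segment_count(self, n, seg, overlap, expected_k):
        rec = EmgRecord(np.random.default_rng(0).normal(size=n), fs=100.0)
        params = HosaParams(nfft=seg, seg_len=seg, overlap_frac=overlap)
        assert segment_signal(rec, params).shape == (expected_k, seg)

    def test_too_short_signal_reports_minimum(self):
        rec = EmgRecord(np.ones(255), fs=100.0)
        with pytest.raises(ValueError, match="256"):
            segment_signal(rec, HosaParams(nfft=256, seg_len=256))

    def test_segments_are_zero_mean_before_windowing(self):
        rec = EmgRecord(
            np.random.default_rng(1).normal(loc=5.0, size=64), fs=10.0
        )
        params = HosaParams(nfft=16, seg_len=16, overlap_frac=0.0, window="rect")
        segs = segment_signal(rec, params)
        assert np.allclose(segs.mean(axis=1), 0.0, atol=1e-12)


class TestBispectrum:
    def test_symmetry_in_f1_f2(self):
        segs = np.random.default_rng(2).normal(size=(4, 16))
        est = bispectrum_direct(segs, TINY_PARAMS)
        assert np.allclose(est.b, est.b.T, atol=1e-12)
        assert np.allclose(est.p12, est.p12.T, atol=1e-12)

    def test_zero_segments_give_zero_estimate(self):
        est = bispectrum_direct(np.zeros((3, 16)), TINY_PARAMS)
        assert not est.b.any() and not est.p12.any() and not est.p3.any()

    def test_single_segment_rejected(self):
        with pytest.raises(EstimationError):
            bispectrum_direct(np.ones((1, 16)), TINY_PARAMS)


class TestBicoherence:
    def test_oracle_equivalence_on_tiny_inputs(self):
        """Vectorized estimator equals the explicit triple-loop on 20 inputs."""
        for seed in range(20):
            rec = tiny_random_record(seed)
            fast = bicoherence(rec, TINY_PARAMS)
            slow = bicoherence_bruteforce(rec, TINY_PARAMS)
            assert np.array_equal(fast.mask, slow.mask)
            assert np.allclose(
                fast.values, slow.values, rtol=1e-10, atol=1e-12
            )

    def test_bounds_and_symmetry_on_random_signals(self):
        for seed in range(25):
            rec = tiny_random_record(seed, n=200)
            m = bicoherence(rec, HosaParams(nfft=32, seg_len=32, overlap_frac=0.5))
            assert m.values[m.mask].max() <= 1.0 + 1e-12
            assert m.values.min() >= 0.0
            assert np.allclose(m.values, m.values.T, atol=1e-12)

    def test_coupled_signal_peaks_at_coupled_bin(self, coupled_record):
        params = HosaParams(nfft=512, seg_len=512, overlap_frac=0.0)
        m = bicoherence(coupled_record, params)
        assert m.at(60.0, 90.0) >= 0.95

    def test_uncoupled_signal_low_at_coupled_bin(self, uncoupled_record):
        params = HosaParams(nfft=512, seg_len=512, overlap_frac=0.0)
        m = bicoherence(uncoupled_record, params)
        assert m.at(60.0, 90.0) <= 0.2

    def test_white_noise_floor_shrinks_with_averaging(self):
        rng = np.random.default_rng(7)
        rec = EmgRecord(rng.normal(size=128 * 512), fs=1500.0)
        m = bicoherence(rec, HosaParams(nfft=512, seg_len=512, overlap_frac=0.0))
        assert np.median(m.values[m.mask]) <= 0.3

    def test_coupled_estimate_improves_with_segments(self):
        spec_vals = []
        from emgbicoh.synth import QpcSpec, generate_qpc_signal

        for k in (8, 32, 128):
            vals = [
                bicoherence(
                    generate_qpc_signal(
                        QpcSpec(f1=60, f2=90, coupling=1.0, snr_db=10.0),
                        k * 512, 1500.0, seed=50 + r, block_len=512,
                    ),
                    HosaParams(nfft=512, seg_len=512, overlap_frac=0.0),
                ).at(60, 90)
                for r in range(3)
            ]
            spec_vals.append(np.mean(vals))
        assert spec_vals[0] <= spec_vals[1] + 0.02
        assert spec_vals[1] <= spec_vals[2] + 0.02

    def test_degenerate_inputs_raise_same_errors_as_oracle(self):
        zero = EmgRecord(np.zeros(64), fs=10.0)
        for fn in (bicoherence, bicoherence_bruteforce):
            with pytest.raises(EstimationError, match="degenerate"):
                fn(zero, TINY_PARAMS)
        single = EmgRecord(np.random.default_rng(0).normal(size=16), fs=10.0)
        for fn in (bicoherence, bicoherence_bruteforce):
            with pytest.raises(EstimationError):
                fn(single, TINY_PARAMS)


class TestAverageMaps:
    def test_identity_and_convexity(self):
        rec = tiny_random_record(0)
        m = bicoherence(rec, TINY_PARAMS)
        avg = average_maps([m, m, m])
        assert np.allclose(avg.values, m.values)
        m2 = bicoherence(tiny_random_record(1), TINY_PARAMS)
        avg2 = average_maps([m, m2])
        assert avg2.values.max() <= 1.0 + 1e-12
        assert np.allclose(avg2.values, (m.values + m2.values) / 2)

    def test_mask_is_conjunction(self):
        rec = tiny_random_record(0)
        m1 = bicoherence(rec, TINY_PARAMS)
        m2 = bicoherence(tiny_random_record(1), TINY_PARAMS)
        m2.mask[0, 0] = False
        avg = average_maps([m1, m2])
        assert not avg.mask[0, 0]

    def test_mismatched_grids_rejected(self):
        m1 = bicoherence(tiny_random_record(0), TINY_PARAMS)
        m2 = bicoherence(
            tiny_random_record(1, n=200),
            HosaParams(nfft=32, seg_len=32, overlap_frac=0.0),
        )
        with pytest.raises(ValueError, match="grid"):
            average_maps([m1, m2])


def test_transformer_stacks_maps():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(3, 200))
    est = BicoherenceEstimator(fs=100.0, nfft=32, seg_len=32)
    out = est.fit_transform(X)
    assert out.shape == (3, 32, 32)
    direct = bicoherence(
        EmgRecord(X[0], fs=100.0), HosaParams(nfft=32, seg_len=32)
    )
    assert np.array_equal(out[0], direct.values)
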