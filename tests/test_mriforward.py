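import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import ks_2samp

from flow4d.errors import InvalidParameterError
from flow4d.mriforward import (AcquisitionConfig, compose_signal, corrupt,
                               decode_velocity, encode_pc, random_rotate,
                               simulate_acquisition, synth_background)


@pytest.fixture(scope="module")
def tube_frame(steady_tube_field):
    frame = steady_tube_field.velocity[0].astype(float)
    frac = steady_tube_field.mask.fraction.astype(float)
    return frame, frac


class TestRotation:
    def test_identity_rotation_is_noop(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(3, 12, 12, 12))
        out, _, _ = random_rotate(f, rng, rotation=Rotation.identity())
        assert np.abs(out - f).max() < 1e-12

    def test_quarter_turn_rotates_vectors(self):
        rng = np.random.default_rng(0)
        f = np.zeros((3, 16, 16, 16))
        f[0] = 1.0
        out, _, _ = random_rotate(f, rng,
                                  rotation=Rotation.from_euler("z", 90, degrees=True))
        center = out[:, 8, 8, 8]
        assert center == pytest.approx([0.0, 1.0, 0.0], abs=1e-9)

    def test_speed_histogram_preserved(self):
        # needs a well-resolved vessel fully contained under any rotation:
        # a short tube centered in a cube, ~20 voxels across the lumen
        from conftest import steady_profile
        from flow4d.flowsynth import FlowSolver
        from flow4d.geometry import make_idealized_geometry
        g = make_idealized_geometry("straight", diameter=4.0, length=12.0,
                                    n_points=25)
        fld = FlowSolver(g, 0.2, min_shape=100).solve(steady_profile(3.0),
                                                      n_frames=1)
        frame = fld.velocity[0].astype(float)
        frac = fld.mask.fraction.astype(float)
        rng = np.random.default_rng(3)
        out, ofrac, _ = random_rotate(frame, rng, mask_fraction=frac)
        s_in = np.sqrt((frame ** 2).sum(0))[frac >= 0.5]
        s_out = np.sqrt((out ** 2).sum(0))[ofrac >= 0.5]
        ks = ks_2samp(s_in, s_out).statistic
        assert ks < 0.05


class TestBackground:
    def test_range_and_zero_fraction(self):
        bg = synth_background((32, 32, 32), np.random.default_rng(1))
        assert bg.min() >= 0.0 and bg.max() == pytest.approx(1.0)
        # soft threshold creates flat exactly-zero regions
        assert (bg == 0.0).mean() > 0.0

    def test_seeded_determinism(self):
        a = synth_background((24, 24, 24), np.random.default_rng(7))
        b = synth_background((24, 24, 24), np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_small_shape_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth_background((4, 8, 8), np.random.default_rng(0))


class TestComposeSignal:
    def test_zero_ratio_is_normalized_fraction(self):
        frac = np.random.default_rng(0).random((8, 8, 8))
        bg = np.random.default_rng(1).random((8, 8, 8))
        out = compose_signal(frac, bg, 0.0)
        assert np.allclose(out, frac / frac.max())

    def test_contrast_at_ratio_two(self):
        frac = np.zeros((6, 6, 6))
        frac[3, 3, 3] = 1.0
        bg = np.ones((6, 6, 6))
        out = compose_signal(frac, bg, 2.0)
        assert out[3, 3, 3] == pytest.approx(1.0)       # vessel: (1+2)/3
        assert out[0, 0, 0] == pytest.approx(2.0 / 3.0)  # background: 2/3

    def test_empty_mask_gives_normalized_background(self):
        bg = np.random.default_rng(2).random((8, 8, 8))
        out = compose_signal(np.zeros((8, 8, 8)), bg, 1.5)
        assert np.allclose(out, bg / bg.max())

    def test_negative_ratio_rejected(self):
        with pytest.raises(InvalidParameterError):
            compose_signal(np.ones((6, 6, 6)), np.ones((6, 6, 6)), -0.1)


class TestEncodeDecode:
    def test_phase_definition(self):
        f = np.zeros((3, 8, 8, 8))
        f[0] = 50.0
        img = encode_pc(f, np.ones((8, 8, 8)), 100.0)
        assert np.angle(img.encodings[1][0, 0, 0]) == pytest.approx(np.pi / 2)
        assert np.angle(img.encodings[0][0, 0, 0]) == pytest.approx(0.0)

    def test_roundtrip_exact_below_venc(self, tube_frame):
        frame, _ = tube_frame
        img = encode_pc(frame, np.ones(frame.shape[1:]), 100.0)
        vel, mag = decode_velocity(img)
        assert np.abs(vel - frame).max() < 1e-10
        assert np.allclose(mag, 1.0)

    def test_aliasing_wraps(self):
        f = np.zeros((3, 8, 8, 8))
        f[0] = 150.0  # 1.5 * venc
        vel, _ = decode_velocity(encode_pc(f, np.ones((8, 8, 8)), 100.0))
        assert vel[0, 0, 0, 0] == pytest.approx(-50.0)

    def test_linearity_of_phase(self):
        rng = np.random.default_rng(0)
        f = np.zeros((3, 6, 6, 6))
        f[1] = rng.uniform(-80, 80, (6, 6, 6))
        img = encode_pc(f, np.ones((6, 6, 6)), 100.0)
        phase = np.angle(img.encodings[2])
        assert np.allclose(phase, np.pi * f[1] / 100.0, atol=1e-12)

    def test_nonpositive_venc_rejected(self):
        with pytest.raises(InvalidParameterError):
            encode_pc(np.zeros((3, 4, 4, 4)), np.ones((4, 4, 4)), 0.0)

    @given(v=st.lists(st.floats(-99.0, 99.0, allow_nan=False), min_size=3,
                      max_size=3),
           venc=st.floats(100.0, 200.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_roundtrip_property_below_venc(self, v, venc):
        # decode(encode(v)) == v for any velocity with |components| < venc
        frame = np.array(v).reshape(3, 1, 1, 1)
        vel, _ = decode_velocity(encode_pc(frame, np.ones((1, 1, 1)), venc))
        assert np.allclose(vel, frame, atol=1e-9 * venc)


class TestCorrupt:
    def test_noop_limit(self, tube_frame):
        frame, frac = tube_frame
        img = encode_pc(frame, frac / frac.max(), 100.0)
        out = corrupt(img, 1e12, 1.0, np.random.default_rng(0),
                      vessel_mask=frac >= 0.5)
        rel = np.abs(out.encodings - img.encodings).max() / np.abs(img.encodings).max()
        assert rel < 1e-6

    def test_crop_shape(self):
        img = encode_pc(np.zeros((3, 64, 64, 64)), np.ones((64, 64, 64)), 100.0)
        out = corrupt(img, 1e9, 0.25, np.random.default_rng(0))
        assert out.shape == (16, 16, 16)

    def test_zero_fill_preserves_shape(self):
        img = encode_pc(np.zeros((3, 32, 32, 32)), np.ones((32, 32, 32)), 100.0)
        out = corrupt(img, 1e9, 0.25, np.random.default_rng(0), zero_fill=True)
        assert out.shape == (32, 32, 32)

    def test_overcrop_rejected(self):
        img = encode_pc(np.zeros((3, 8, 8, 8)), np.ones((8, 8, 8)), 100.0)
        with pytest.raises(InvalidParameterError):
            corrupt(img, 100.0, 0.25, np.random.default_rng(0))

    def test_parseval(self):
        # FFT implementation preserves energy (no noise, no crop)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(16, 16, 16)) + 1j * rng.normal(size=(16, 16, 16))
        k = np.fft.fftn(x)
        rel = abs((np.abs(k) ** 2).sum() / x.size - (np.abs(x) ** 2).sum())
        assert rel / (np.abs(x) ** 2).sum() < 1e-10

    @pytest.mark.parametrize("snr", [10.0, 100.0, 1000.0])
    def test_snr_calibration(self, tube_frame, snr):
        frame, frac = tube_frame
        binary = frac >= 0.5
        mag = frac / frac.max()
        img = encode_pc(frame, mag, 100.0)
        signal = np.abs(img.encodings[0])[binary].mean()
        stds = []
        for rep in range(20):
            out = corrupt(img, snr, 1.0, np.random.default_rng(1000 + rep),
                          vessel_mask=binary)
            stds.append((out.encodings[0] - img.encodings[0]).real.std())
        measured = signal / np.mean(stds)
        assert measured == pytest.approx(snr, rel=0.05)


class TestSimulateAcquisition:
    def test_degenerate_pipeline_is_identity(self, tube_frame):
        frame, frac = tube_frame
        cfg = AcquisitionConfig(venc_fraction_range=(0.9, 0.9),
                                snr_range=(1e12, 1e12), crop_factor=1.0,
                                background_ratio_range=(0.0, 0.0), rotate=False)
        pair = simulate_acquisition(frame, frac, cfg, np.random.default_rng(5))
        speed = np.sqrt((pair.truth.astype(float) ** 2).sum(0))
        ok = speed < pair.config_draw["venc"]
        err = np.abs(pair.corrupted_velocity - pair.truth)[:, ok]
        assert err.max() < 1e-4

    def test_seeded_determinism(self, tube_frame):
        frame, frac = tube_frame
        cfg = AcquisitionConfig()
        a = simulate_acquisition(frame, frac, cfg, np.random.default_rng(9))
        b = simulate_acquisition(frame, frac, cfg, np.random.default_rng(9))
        assert np.array_equal(a.corrupted_velocity, b.corrupted_velocity)
        assert a.config_draw == b.config_draw

    def test_draws_within_ranges(self, tube_frame):
        frame, frac = tube_frame
        cfg = AcquisitionConfig(rotate=False)
        rng = np.random.default_rng(2)
        small = frame[:, :24, :24, :24]
        sfrac = frac[:24, :24, :24]
        for _ in range(40):
            d = cfg.draw(rng)
            assert 0.1 <= d["venc_fraction"] <= 0.9
            assert 10.0 <= d["snr"] <= 10000.0
            assert 0.0 <= d["background_ratio"] <= 2.0
        pair = simulate_acquisition(small, sfrac, cfg, rng)
        assert pair.truth.shape == pair.corrupted_velocity.shape

    def test_config_invariants(self):
        with pytest.raises(InvalidParameterError):
            AcquisitionConfig(venc_fraction_range=(0.0, 0.9))
        with pytest.raises(InvalidParameterError):
            AcquisitionConfig(snr_range=(0.5, 100.0))
        with pytest.raises(InvalidParameterError):
            AcquisitionConfig(crop_factor=0.0)
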