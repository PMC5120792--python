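"""EMA preprocessing: head correction, down-sampling, parameterizations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import emasynth as es
from emasynth.artic import CANONICAL_SENSORS, MIDSAGITTAL_SENSORS


def make_recording(n=100, rate=400.0, rng=None, pose=None):
    rng = rng or np.random.default_rng(0)
    sensors = {s: rng.normal(0, 5, (n, 3)) for s in CANONICAL_SENSORS}
    if pose is None:
        pose = np.zeros((n, 6))
    return es.EmaRecording(sensors=sensors, reference_pose=pose, rate=rate)


class TestHeadCorrect:
    def test_identity_pose_no_change(self):
        rec = make_recording()
        out = es.head_correct(rec)
        for s in CANONICAL_SENSORS:
            assert np.allclose(out.sensors[s], rec.sensors[s])
        assert np.all(out.reference_pose == 0)

    def test_comoving_sensor_becomes_constant(self):
        """A sensor rigidly attached to the head must be motionless after
        correction."""
        rng = np.random.default_rng(1)
        n = 200
        angles = 0.3 * rng.standard_normal((n, 3))
        trans = 5.0 * rng.standard_normal((n, 3))
        pose = np.column_stack([trans, angles])
        rot = Rotation.from_euler("xyz", angles)
        local = np.array([3.0, -2.0, 1.0])
        world = rot.apply(np.tile(local, (n, 1))) + trans
        rec = make_recording(n, pose=pose)
        rec.sensors["jaw"] = world
        out = es.head_correct(rec)
        assert np.max(out.sensors["jaw"].std(axis=0)) < 1e-9
        assert np.allclose(out.sensors["jaw"][0], local)

    def test_pure_translation(self):
        n = 50
        pose = np.zeros((n, 6))
        pose[:, :3] = [1.0, 2.0, 3.0]
        rec = make_recording(n, pose=pose)
        out = es.head_correct(rec)
        for s in CANONICAL_SENSORS:
            assert np.allclose(out.sensors[s], rec.sensors[s] - [1, 2, 3])


class TestDownsample:
    def test_frame_count_and_rate(self):
        rec = make_recording(4000, rate=400.0)
        out = es.downsample_frames(rec, 4)
        assert out.n_frames == 1000
        assert out.rate == 100.0

    def test_constant_preserved(self):
        rec = make_recording(400)
        for s in rec.sensors:
            rec.sensors[s] = np.tile([1.0, -2.0, 0.5], (400, 1))
        out = es.downsample_frames(rec, 4)
        assert np.allclose(out.sensors["jaw"], [1.0, -2.0, 0.5], atol=1e-6)

    def test_slow_sinusoid_amplitude_preserved(self):
        n = 4000
        t = np.arange(n) / 400.0
        rec = make_recording(n)
        rec.sensors["jaw"] = np.column_stack([np.sin(2 * np.pi * 1.0 * t)] * 3)
        out = es.downsample_frames(rec, 4)
        mid = out.sensors["jaw"][100:-100, 0]
        assert abs(mid.max() - 1.0) < 0.01

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            es.downsample_frames(make_recording(100), 2.5)


class TestMidsagittal:
    def test_dims_and_sensor_drop(self):
        feats = es.project_midsagittal(make_recording())
        assert feats.dim == 14
        assert feats.parameterization == "midsag14"
        assert len(MIDSAGITTAL_SENSORS) == 7

    def test_planar_data_unchanged(self):
        rec = make_recording()
        for s in rec.sensors:
            rec.sensors[s][:, 2] = 0.0
        feats = es.project_midsagittal(rec)
        expected = np.hstack([rec.sensors[s][:, :2] for s in MIDSAGITTAL_SENSORS])
        assert np.array_equal(feats.frames, expected)

    def test_mirrored_lateral_offsets_identical(self):
        rec_l = make_recording()
        rec_r = make_recording()
        for s in rec_l.sensors:
            rec_r.sensors[s] = rec_l.sensors[s].copy()
            rec_r.sensors[s][:, 2] = -rec_l.sensors[s][:, 2]
        assert np.array_equal(
            es.project_midsagittal(rec_l).frames, es.project_midsagittal(rec_r).frames
        )

    def test_missing_sensor_rejected(self):
        rec = make_recording()
        del rec.sensors["velum"]
        with pytest.raises(ValueError, match="velum"):
            es.project_midsagittal(rec)


class TestPca:
    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        feats = es.ArticulatoryFeatures(rng.normal(0, 3, (200, 27)), "raw27")
        model = es.fit_pca(feats, 27)
        scores = es.apply_pca(model, feats)
        # k=27 keeps everything; reconstruct through the stored transform
        rec = es.artic.reconstruct_pca(model, scores.frames)
        assert np.allclose(rec, feats.frames, atol=1e-8)

    def test_latent_structure_recovered(self):
        """Data from a 5-dim linear latent model: 5 components capture
        nearly all variance, and reconstruction error shrinks with k."""
        rng = np.random.default_rng(3)
        latent = rng.normal(0, 1, (2000, 5))
        mix = rng.normal(0, 1, (5, 27))
        x = latent @ mix + 0.01 * rng.standard_normal((2000, 27))
        feats = es.ArticulatoryFeatures(x, "raw27")
        errors = []
        for k in (7, 10):
            model = es.fit_pca(feats, k)
            z = (x - model.mean) / model.sd
            proj = (z @ model.components.T) @ model.components
            resid = np.sum((z - proj) ** 2)
            errors.append(resid)
            assert 1 - resid / np.sum(z**2) >= 0.99
        assert errors[1] <= errors[0]  # error monotone non-increasing in k

    def test_orthonormal_components(self):
        rng = np.random.default_rng(4)
        feats = es.ArticulatoryFeatures(rng.normal(0, 2, (100, 27)), "raw27")
        model = es.fit_pca(feats, 10)
        assert np.allclose(model.components @ model.components.T, np.eye(10), atol=1e-8)

    def test_degenerate_input_rejected(self):
        x = np.zeros((100, 27))
        x[:, 0] = np.arange(100)
        feats = es.ArticulatoryFeatures(x, "raw27")
        with pytest.raises(ValueError, match="zero-variance"):
            es.fit_pca(feats, 7)
        with pytest.raises(ValueError, match="exceeds"):
            es.fit_pca(es.ArticulatoryFeatures(np.random.default_rng(0).normal(size=(50, 27)), "raw27"), 28)


class TestSilenceRemoval:
    def test_speech_only_identity(self):
        seg = es.Segmentation([("a", 0.0, 2.0)])
        frames = np.arange(200).reshape(-1, 1).astype(float)
        kept, idx = es.remove_silence(frames, seg, rate=100.0)
        assert np.array_equal(kept, frames) and np.array_equal(idx, np.arange(200))

    def test_all_silence_warns_empty(self):
        seg = es.Segmentation([("SILENCE", 0.0, 1.0)])
        with pytest.warns(UserWarning, match="silence"):
            kept, _ = es.remove_silence(np.zeros((100, 2)), seg, rate=100.0)
        assert kept.shape[0] == 0

    def test_half_silence_arithmetic(self):
        seg = es.Segmentation([("a", 0.0, 1.0), ("SILENCE", 1.0, 2.0)])
        kept, idx = es.remove_silence(np.zeros((200, 3)), seg, rate=100.0)
        assert kept.shape[0] == 100
        assert idx.max() == 99


class TestNormalizer:
    def test_train_stats_and_roundtrip(self):
        rng = np.random.default_rng(5)
        x = rng.normal(3, 2, (500, 4))
        norm = es.fit_normalizer(x)
        z = es.apply_normalizer(norm, x)
        assert np.max(np.abs(z.mean(axis=0))) < 1e-10
        assert np.max(np.abs(z.std(axis=0) - 1)) < 1e-10
        assert np.allclose(es.invert_normalizer(norm, z), x)

    def test_no_leakage_on_heldout(self):
        rng = np.random.default_rng(6)
        norm = es.fit_normalizer(rng.normal(0, 1, (500, 3)))
        held = es.apply_normalizer(norm, rng.normal(2.0, 1, (500, 3)))
        assert np.all(np.abs(held.mean(axis=0)) > 1.0)

    def test_constant_dimension_named_in_error(self):
        x = np.random.default_rng(7).normal(size=(50, 3))
        x[:, 1] = 4.2
        with pytest.raises(ValueError, match=r"\[1\]"):
            es.fit_normalizer(x)


class TestContextStacking:
    def test_dims(self):
        x = np.random.default_rng(8).normal(size=(30, 14))
        assert es.stack_context(x, 4).shape == (30, 70)

    def test_constant_input(self):
        x = np.tile([1.0, 2.0], (10, 1))
        s = es.stack_context(x, 4)
        assert np.all(s == np.tile([1.0, 2.0], (10, 5)))

    def test_causality(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(20, 3))
        y = x.copy()
        y[10] += 100.0
        sx, sy = es.stack_context(x, 4), es.stack_context(y, 4)
        assert np.array_equal(sx[:10], sy[:10])
        assert not np.array_equal(sx[10], sy[10])

    def test_startup_replication(self):
        x = np.arange(6, dtype=float).reshape(-1, 1)
        s = es.stack_context(x, 4)
        assert np.array_equal(s[0], [0, 0, 0, 0, 0])
        assert np.array_equal(s[2], [2, 1, 0, 0, 0])


def test_pipeline_bookkeeping():
    """Full chain raw -> corrected -> 100 Hz -> midsag -> silence removal ->
    z-score -> context keeps frame counts consistent at every stage."""
    rec = make_recording(800, rate=400.0)
    rec = es.head_correct(rec)
    rec = es.downsample_frames(rec, 4)
    assert rec.n_frames == 200
    feats = es.project_midsagittal(rec)
    seg = es.Segmentation([("SILENCE", 0.0, 0.5), ("a", 0.5, 2.0)])
    kept, idx = es.remove_silence(feats.frames, seg, rate=100.0)
    assert kept.shape == (150, 14)
    norm = es.fit_normalizer(kept)
    stacked = es.stack_context(es.apply_normalizer(norm, kept), 4)
    assert stacked.shape == (150, 70)
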