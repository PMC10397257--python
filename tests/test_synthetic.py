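"""Statistical and structural checks of the synthetic cohort generator."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

import endodx as e
from endodx.synthetic import _patient_latents


def _cfg(**kw):
    return e.SyntheticCohortConfig(**kw)


class TestScoreStreams:
    def test_reproducible_bit_for_bit(self):
        cfg = _cfg(n_pos=3, n_neg=3, frames_per_patient=80, master_seed=42)
        s1, l1 = e.generate_score_streams(cfg)
        s2, l2 = e.generate_score_streams(cfg)
        assert l1 == l2
        for a, b in zip(s1, s2):
            assert a.patient_id == b.patient_id
            np.testing.assert_array_equal(a.scores, b.scores)

    def test_scores_bounded_and_labelled(self):
        cfg = _cfg(n_pos=5, n_neg=7, frames_per_patient=(30, 60), master_seed=3)
        streams, labels = e.generate_score_streams(cfg)
        assert len(streams) == 12
        assert sum(v == "IP" for v in labels.values()) == 5
        for s in streams:
            assert s.scores.min() >= 0.0 and s.scores.max() <= 1.0
            assert 30 <= len(s) <= 60

    def test_no_signal_symmetry(self):
        """separation=0, rho=0: both classes share one score distribution."""
        cfg = _cfg(n_pos=30, n_neg=30, frames_per_patient=200,
                   separation=0.0, ar1_rho=0.0, noise_sd=1.0, master_seed=11)
        streams, labels = e.generate_score_streams(cfg)
        scores = np.concatenate([s.scores for s in streams])
        y = np.concatenate([np.full(len(s), labels[s.patient_id] == "IP")
                            for s in streams])
        auc = roc_auc_score(y, scores)
        assert abs(auc - 0.5) < 0.05

    def test_noise_free_limit(self):
        """noise_sd=0, lesion_fraction=1: constant class-conditional streams."""
        cfg = _cfg(n_pos=2, n_neg=2, frames_per_patient=50, separation=4.0,
                   noise_sd=0.0, lesion_fraction=1.0, master_seed=5)
        streams, labels = e.generate_score_streams(cfg)
        for s in streams:
            expected = expit(2.0) if labels[s.patient_id] == "IP" else expit(-2.0)
            np.testing.assert_allclose(s.scores, expected, atol=1e-12)

    def test_ar1_autocorrelation_matches_rho(self):
        """Lag-1 autocorrelation of logit residuals ~ ar1_rho.

        Negative patients have a constant logit offset, so the sample
        autocorrelation of their logit-scale scores estimates rho
        directly; pooled over 50 patients x 300 frames the estimate
        must land within +/-0.05 of the configured 0.9.
        """
        cfg = _cfg(n_pos=50, n_neg=50, frames_per_patient=300, separation=4.0,
                   noise_sd=1.0, ar1_rho=0.9, master_seed=21)
        streams, labels = e.generate_score_streams(cfg)
        acs = []
        for s in streams:
            if labels[s.patient_id] != "CRSwNP":
                continue
            res = logit(s.scores)
            res = res - res.mean()
            acs.append((res[:-1] * res[1:]).sum() / (res * res).sum())
        assert abs(np.mean(acs) - 0.9) < 0.05

    def test_lesion_run_length_converges_to_dwell(self):
        """Mean visible-run length approaches lesion_dwell at 1e5 frames.

        With zero noise the positive-patient stream is bi-valued, so
        thresholding recovers the visibility chain exactly.
        """
        cfg = _cfg(n_pos=1, n_neg=0, frames_per_patient=100_000,
                   separation=4.0, noise_sd=0.0, lesion_dwell=25.0,
                   lesion_fraction=0.3, master_seed=9)
        (stream,), _ = e.generate_score_streams(cfg)
        vis = stream.scores > 0.6
        padded = np.concatenate([[0], vis.astype(int), [0]])
        edges = np.flatnonzero(np.diff(padded))
        runs = edges[1::2] - edges[::2]
        assert abs(runs.mean() - 25.0) / 25.0 < 0.10
        assert abs(vis.mean() - 0.3) < 0.03

    @pytest.mark.parametrize("bad", [
        {"separation": float("nan")},
        {"noise_sd": -1.0},
        {"ar1_rho": 1.0},
        {"lesion_fraction": 1.5},
        {"n_pos": -1},
        {"frames_per_patient": 0},
        {"fps": 0.0},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            _cfg(**bad)


class TestFrameImages:
    def test_counts_and_manifest(self, tmp_path):
        cfg = _cfg(n_pos=1, n_neg=1, frames_per_patient=10, master_seed=4,
                   image_size=32)
        records, manifest = e.generate_frame_images(cfg, tmp_path)
        assert len(records) == 2
        pngs = sorted(tmp_path.glob("*/frame_*.png"))
        assert len(pngs) == 20
        assert pngs[0].name == "frame_000001.png"
        back = e.read_manifest(manifest)
        assert back == records

    def test_image_determinism_byte_for_byte(self, tmp_path):
        cfg = _cfg(n_pos=1, n_neg=1, frames_per_patient=5, master_seed=13,
                   image_size=32)
        e.generate_frame_images(cfg, tmp_path / "a")
        e.generate_frame_images(cfg, tmp_path / "b")
        for pa in sorted((tmp_path / "a").rglob("*")):
            pb = tmp_path / "b" / pa.relative_to(tmp_path / "a")
            if pa.is_file():
                assert pa.read_bytes() == pb.read_bytes(), pa.name

    def test_no_signal_images_indistinguishable(self, tmp_path, rng):
        """separation=0 leaves no class-specific texture to find."""
        from endodx.committee import _texture_features
        from PIL import Image
        cfg = _cfg(n_pos=6, n_neg=6, frames_per_patient=25, master_seed=17,
                   separation=0.0, image_size=32, lesion_fraction=1.0)
        records, _ = e.generate_frame_images(cfg, tmp_path)
        feats, ys = [], []
        for r in records:
            for t in range(r.n_frames):
                img = np.asarray(Image.open(
                    tmp_path / r.source / e.synthetic.frame_filename(t)))
                feats.append(_texture_features(img))
                ys.append(r.label == "IP")
        feats, ys = np.stack(feats), np.array(ys)
        # high-pass energy (the lesion cue) must not separate the classes
        auc = roc_auc_score(ys, feats[:, 6])
        assert 0.35 < auc < 0.65

    def test_pixel_variance_separates_lesion_frames(self, tmp_path):
        """At large separation a single high-pass-energy threshold wins."""
        from endodx.committee import _texture_features
        from PIL import Image
        cfg = _cfg(n_pos=5, n_neg=5, frames_per_patient=30, master_seed=19,
                   separation=8.0, noise_sd=0.5, lesion_fraction=1.0,
                   image_size=32)
        records, _ = e.generate_frame_images(cfg, tmp_path)
        vals, ys = [], []
        for r in records:
            for t in range(r.n_frames):
                img = np.asarray(Image.open(
                    tmp_path / r.source / e.synthetic.frame_filename(t)))
                vals.append(_texture_features(img)[6])
                ys.append(r.label == "IP")
        assert roc_auc_score(ys, vals) > 0.95

    def test_truth_streams_match_score_generator(self, tmp_path):
        cfg = _cfg(n_pos=2, n_neg=2, frames_per_patient=15, master_seed=23,
                   image_size=32)
        e.generate_frame_images(cfg, tmp_path)
        truth = e.read_score_streams(tmp_path / "truth_streams.csv", fps=cfg.fps)
        streams, _ = e.generate_score_streams(cfg)
        for s in streams:
            np.testing.assert_allclose(
                truth[(s.patient_id, "truth")].scores, s.scores, atol=1e-9)

    def test_image_size_floor(self, tmp_path):
        cfg = _cfg(n_pos=1, n_neg=0, frames_per_patient=2, image_size=16)
        with pytest.raises(ValueError, match="image_size"):
            e.generate_frame_images(cfg, tmp_path)


def test_latents_deterministic_per_patient_index():
    cfg = _cfg(n_pos=2, n_neg=2, frames_per_patient=40, master_seed=31)
    a = _patient_latents(cfg, 1)
    # adding patients elsewhere must not disturb patient 1's stream
    cfg2 = dataclasses.replace(cfg, n_pos=2, n_neg=10)
    b = _patient_latents(cfg2, 1)
    np.testing.assert_array_equal(a["scores"], b["scores"])
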