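import numpy as np
import pandas as pd
import pytest

from cordmotion.ldmcm import (
    FeatureTrackTable,
    LdMcmConfig,
    filter_by_likelihood,
    qc_features,
    read_feature_table,
    run_ld_mcm,
    track_features_ncc,
    write_feature_table,
)
from cordmotion.synthetic import make_feature_table


def long_table(rows):
    return FeatureTrackTable(
        pd.DataFrame(rows, columns=["feature_id", "frame", "x", "y", "likelihood"])
    )


DLC_CSV = """scorer,model,model,model,model,model,model
bodyparts,vein,vein,vein,branch,branch,branch
coords,x,y,likelihood,x,y,likelihood
0,10.0,20.0,0.999,30.0,40.0,0.5
1,11.0,21.0,0.995,31.0,41.0,0.98
2,12.0,22.0,0.2,32.0,42.0,0.999
"""


class TestFeatureCsv:
    def test_read_pose_estimation_dialect(self, tmp_path):
        path = tmp_path / "tracks.csv"
        path.write_text(DLC_CSV)
        table = read_feature_table(path)
        assert len(table.records) == 6
        assert table.feature_ids == ["vein", "branch"]
        vein = table.positions("vein")
        np.testing.assert_allclose(vein["x"], [10, 11, 12])
        np.testing.assert_allclose(vein["likelihood"], [0.999, 0.995, 0.2])

    def test_missing_likelihood_column_rejected(self, tmp_path):
        bad = DLC_CSV.replace("likelihood", "score")
        path = tmp_path / "bad.csv"
        path.write_text(bad)
        with pytest.raises(ValueError, match="likelihood"):
            read_feature_table(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y\n1,2\n")
        with pytest.raises(ValueError):
            read_feature_table(path)

    def test_roundtrip_identity(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(DLC_CSV)
        table = read_feature_table(path)
        out = write_feature_table(table, tmp_path / "back.csv")
        back = read_feature_table(out)
        pd.testing.assert_frame_equal(
            back.records.sort_values(["feature_id", "frame"]).reset_index(drop=True),
            table.records.sort_values(["feature_id", "frame"]).reset_index(drop=True),
        )

    def test_duplicate_records_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            long_table([("a", 0, 1, 2, 1.0), ("a", 0, 3, 4, 1.0)])


class TestFilterByLikelihood:
    def test_zero_threshold_is_identity(self):
        t = long_table([("a", 0, 1, 2, 0.1), ("b", 0, 3, 4, 0.9)])
        out = filter_by_likelihood(t, 0.0)
        assert len(out.records) == 2

    def test_gate_is_per_record(self):
        t = long_table([("a", 0, 1, 2, 0.5), ("a", 1, 1, 2, 0.995)])
        out = filter_by_likelihood(t, 0.99)
        assert len(out.records) == 1
        assert out.records.iloc[0]["frame"] == 1


class TestQcFeatures:
    def test_comoving_features_all_kept(self):
        rows = []
        shifts = np.sin(np.linspace(0, 3, 20)) * 30
        for fid, x0 in [("a", 10), ("b", 50), ("c", 90)]:
            for t, s in enumerate(shifts):
                rows.append((fid, t, x0, 40 + s, 1.0))
        _, report = qc_features(long_table(rows), min_mean_correlation=0.5)
        np.testing.assert_allclose(report.correlation, 1.0, atol=1e-12)
        assert report.dropped == []

    def test_antiphase_feature_dropped(self):
        rows = []
        shifts = np.sin(np.linspace(0, 3, 20)) * 30
        for fid, sign in [("a", 1), ("b", 1), ("c", -1)]:
            for t, s in enumerate(shifts):
                rows.append((fid, t, 10, 40 + sign * s, 1.0))
        filtered, report = qc_features(long_table(rows), min_mean_correlation=0.0)
        assert report.dropped == ["c"]
        assert report.mean_correlation["c"] < -0.9
        assert "c" not in filtered.feature_ids

    def test_random_walker_dropped(self, rng):
        rows = []
        shifts = np.sin(np.linspace(0, 6, 100)) * 30
        stray = rng.standard_normal(100) * 10  # tracks something unrelated
        for t in range(100):
            rows.append(("a", t, 10, 40 + shifts[t], 1.0))
            rows.append(("b", t, 50, 40 + shifts[t], 1.0))
            rows.append(("c", t, 90, 40 + shifts[t], 1.0))
            rows.append(("w", t, 70, 40 + stray[t], 1.0))
        _, report = qc_features(long_table(rows), min_mean_correlation=0.5)
        assert "w" in report.dropped
        assert set(report.kept) == {"a", "b", "c"}

    def test_needs_three_features(self):
        t = long_table([("a", 0, 1, 2, 1.0), ("b", 0, 3, 4, 1.0)])
        with pytest.raises(ValueError):
            qc_features(t)


class TestNccTracker:
    def test_static_movie_constant_tracks(self, quiet_sim):
        movie, gt = quiet_sim
        feats = {k: v for k, v in list(gt.feature_points.items())[:3]}
        feats = {
            k: v for k, v in feats.items()
            if 10 < v[0] < 85 and 10 < v[1] < 85
        }
        table = track_features_ncc(movie, feats, search_radius=20)
        for fid in table.feature_ids:
            pos = table.positions(fid)
            assert pos["x"].std() == 0 and pos["y"].std() == 0
            assert (pos["likelihood"] > 0.99).all()

    def test_shifted_frames_tracked(self, quiet_sim, rng):
        movie, gt = quiet_sim
        data = movie.data.copy()
        data[1:] = np.roll(data[0], 12, axis=0)  # shift down 12 rows
        shifted = movie.with_data(data)
        feats = {
            k: v for k, v in gt.feature_points.items()
            if 15 < v[0] < 80 and 15 < v[1] < 60
        }
        table = track_features_ncc(shifted, feats, search_radius=20)
        for fid in table.feature_ids:
            pos = table.positions(fid).set_index("frame")
            assert abs(pos.loc[1, "y"] - pos.loc[0, "y"] - 12) <= 0.5
            assert abs(pos.loc[1, "x"] - pos.loc[0, "x"]) <= 0.5

    def test_occlusion_lowers_likelihood(self, quiet_sim):
        movie, gt = quiet_sim
        data = movie.data.copy()
        feats = {k: v for k, v in gt.feature_points.items() if 20 < v[0] < 70 and 20 < v[1] < 70}
        name, (fx, fy) = next(iter(feats.items()))
        data[3, int(fy) - 6 : int(fy) + 7, int(fx) - 6 : int(fx) + 7] = data.max() * 2
        table = track_features_ncc(movie.with_data(data), {name: (fx, fy)}, search_radius=10)
        lk = table.positions(name).set_index("frame")["likelihood"]
        assert lk.loc[3] < 0.99
        assert lk.drop(3).min() > 0.99


class TestRunLdMcm:
    def test_zero_motion_gives_identity_transforms(self, quiet_sim):
        movie, gt = quiet_sim
        table = make_feature_table(gt, seed=0)
        corrected, transforms, _ = run_ld_mcm(
            movie, table, 0, LdMcmConfig(residual_pass=False)
        )
        for t in transforms:
            assert np.hypot(t.dx, t.dy) < 1e-6
        interior = np.s_[:, 2:-2, 2:-2]
        np.testing.assert_allclose(
            corrected.data[interior], movie.data[interior], atol=1e-5
        )

    def test_known_shift_recovery(self, moving_sim):
        movie, gt = moving_sim
        table = make_feature_table(gt, jitter_sigma_px=0.2, seed=2)
        _, transforms, _ = run_ld_mcm(movie, table, 0)
        res = residual_feature_error(gt, transforms)
        assert res < 0.5

    def test_outlier_features_tolerated(self, moving_sim):
        movie, gt = moving_sim
        table = make_feature_table(gt, jitter_sigma_px=0.2, outlier_fraction=0.3, seed=3)
        _, transforms, _ = run_ld_mcm(movie, table, 0)
        assert residual_feature_error(gt, transforms) < 0.5

    def test_deterministic_given_seed(self, moving_sim):
        movie, gt = moving_sim
        table = make_feature_table(gt, jitter_sigma_px=0.2, seed=2)
        out1 = run_ld_mcm(movie, table, 0, LdMcmConfig(seed=5))
        out2 = run_ld_mcm(movie, table, 0, LdMcmConfig(seed=5))
        np.testing.assert_array_equal(
            np.stack([t.matrix for t in out1[1]]), np.stack([t.matrix for t in out2[1]])
        )
        np.testing.assert_array_equal(out1[0].data, out2[0].data)

    def test_feature_spread_collapses(self, moving_sim):
        # tracked landmark clouds tighten after correction
        movie, gt = moving_sim
        table = make_feature_table(gt, jitter_sigma_px=0.2, seed=2)
        _, transforms, _ = run_ld_mcm(movie, table, 0)
        for fid, (x0, y0) in gt.feature_points.items():
            raw_pts = np.array(
                [gt.feature_positions(t)[fid] for t in range(movie.n_frames)]
            )
            corr_pts = np.array(
                [transforms[t].apply(raw_pts[t][None])[0] for t in range(movie.n_frames)]
            )
            raw_dev = np.linalg.norm(raw_pts - raw_pts.mean(0), axis=1).mean()
            corr_dev = np.linalg.norm(corr_pts - corr_pts.mean(0), axis=1).mean()
            assert corr_dev < raw_dev

    def test_sparse_frames_inherit_and_flagged(self, quiet_sim):
        movie, gt = quiet_sim
        table = make_feature_table(gt, seed=0)
        # drop all gated features on frame 2
        recs = table.records
        recs.loc[recs["frame"] == 2, "likelihood"] = 0.1
        table = type(table)(recs)
        _, transforms, _ = run_ld_mcm(movie, table, 0, LdMcmConfig(residual_pass=False))
        assert transforms[2].flags.get("interpolated")


def residual_feature_error(gt, transforms):
    ref_pos = gt.feature_positions(0)
    res = []
    for t in range(len(transforms)):
        for name, (x, y) in gt.feature_positions(t).items():
            fx, fy = transforms[t].apply(np.array([[x, y]]))[0]
            rx, ry = ref_pos[name]
            res.append(np.hypot(fx - rx, fy - ry))
    return float(np.mean(res))
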