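import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specfuse import fusion as fu
from specfuse import spa as spa_mod
from specfuse.evaluation import partition

from conftest import group_ids


class TestZScore:
    def test_values_at_mean_map_to_zero(self):
        np.testing.assert_array_equal(fu.zscore([5.0, 5.0], 5.0, 2.0), [0.0, 0.0])

    def test_hand_example_with_own_stats(self):
        v = np.array([10.0, 20.0, 30.0])
        stats = fu.GroupStats.from_values(v)
        assert stats.sd == pytest.approx(10.0)
        np.testing.assert_allclose(fu.zscore(v, stats.mean, stats.sd),
                                   [-1.0, 0.0, 1.0], atol=1e-12)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=20),
           st.floats(-100, 100), st.floats(0.1, 50))
    @settings(max_examples=25, deadline=None)
    def test_round_trip(self, values, mean, sd):
        v = np.array(values)
        back = fu.inverse_zscore(fu.zscore(v, mean, sd), mean, sd)
        np.testing.assert_allclose(back, v, atol=1e-9 * max(1, np.abs(v).max()))

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="sd > 0"):
            fu.zscore([1.0], 0.0, 0.0)


class TestPairing:
    def test_balanced_design_pairs_everything(self, small_world):
        _, design, _, _ = small_world
        ns = design[design.group == "NS"]
        ss = design[design.group == "SS"]
        pairs = fu.pair_samples(ns, ss)
        assert len(pairs) == len(ns) == len(ss)

    def test_removed_sample_drops_exactly_one_pair(self, small_world):
        _, design, _, _ = small_world
        ns = design[design.group == "NS"].iloc[1:]
        ss = design[design.group == "SS"]
        pairs = fu.pair_samples(ns, ss)
        assert len(pairs) == len(ss) - 1

    def test_pairing_is_a_bijection(self, small_world):
        _, design, _, _ = small_world
        pairs = fu.pair_samples(design[design.group == "NS"],
                                design[design.group == "SS"])
        assert len({a for a, _ in pairs}) == len(pairs)
        assert len({b for _, b in pairs}) == len(pairs)

    def test_disjoint_cells_rejected(self, small_world):
        _, design, _, _ = small_world
        ns = design[(design.group == "NS") & (design.year == 1)]
        ss = design[(design.group == "SS") & (design.year == 2)]
        with pytest.raises(ValueError, match="design cell"):
            fu.pair_samples(ns, ss.assign(year=3))


class TestFuseTargets:
    def test_equal_zscores_average_to_themselves(self):
        y = pd.Series([10.0, 20, 30], index=["a", "b", "c"])
        stats = fu.GroupStats.from_values(y)
        fused = fu.fuse_targets(y, y, [("a", "a"), ("b", "b"), ("c", "c")],
                                stats, stats)
        np.testing.assert_allclose(fused, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_hand_example_different_scales(self):
        y_ss = pd.Series([10.0, 20, 30], index=["s1", "s2", "s3"])
        y_ns = pd.Series([1.0, 2, 3], index=["n1", "n2", "n3"])
        y = pd.concat([y_ss, y_ns])
        fused = fu.fuse_targets(y, y, [("n1", "s1"), ("n2", "s2"), ("n3", "s3")],
                                fu.GroupStats.from_values(y_ns),
                                fu.GroupStats.from_values(y_ss))
        np.testing.assert_allclose(fused, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_calibration_fused_mean_is_zero(self, rng):
        y_ns = pd.Series(rng.normal(50, 5, 40),
                         index=[f"n{i}" for i in range(40)])
        y_ss = pd.Series(rng.normal(30, 8, 40),
                         index=[f"s{i}" for i in range(40)])
        y = pd.concat([y_ns, y_ss])
        pairs = [(f"n{i}", f"s{i}") for i in range(40)]
        fused = fu.fuse_targets(y, y, pairs,
                                fu.GroupStats.from_values(y_ns),
                                fu.GroupStats.from_values(y_ss))
        assert fused.mean() == pytest.approx(0.0, abs=1e-10)

    def test_missing_pair_member_rejected(self):
        y = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="missing pair member"):
            fu.fuse_targets(y, y, [("a", "zz")],
                            fu.GroupStats(1.0, 1.0), fu.GroupStats(1.0, 1.0))


def _toy_feature_sets(spectra):
    fs_ns = spa_mod.FeatureSet(indices=[100, 300, 500], parameter="ETR",
                               wavelengths=[450.0, 650.0, 850.0],
                               stress="NS", tag="SG")
    fs_ss = spa_mod.FeatureSet(indices=[1200, 1400], parameter="ETR",
                               wavelengths=[1550.0, 1750.0],
                               stress="SS", tag="SG-SNV")
    return fs_ns, fs_ss


class TestBuildFusedX:
    @pytest.fixture(scope="class")
    def groups(self, small_world):
        _, design, physio, spectra = small_world
        by_group = {g: spectra.subset(group_ids(design, g))
                    for g in ("NS", "SS", "NS*SS")}
        cal = {g: by_group[g].sample_ids[:20] for g in by_group}
        return design, physio, spectra, by_group, cal

    def test_training_width_is_block_sum(self, groups):
        design, _, spectra, by_group, cal = groups
        fs_ns, fs_ss = _toy_feature_sets(spectra)
        pairs = fu.pair_samples(design[design.group == "NS"],
                                design[design.group == "SS"])[:10]
        X = fu.build_fused_X(by_group, fs_ns, fs_ss, pairs=pairs,
                             calibration_ids_by_group=cal)
        assert X.shape == (10, 5)

    def test_prediction_rows_use_target_group_spectra_only(self, groups):
        design, _, spectra, by_group, cal = groups
        fs_ns, fs_ss = _toy_feature_sets(spectra)
        X = fu.build_fused_X(by_group, fs_ns, fs_ss, group="NS*SS",
                             calibration_ids_by_group=cal)
        assert X.shape == (len(by_group["NS*SS"].sample_ids), 5)

    def test_column_matches_independent_recomputation(self, groups):
        from specfuse import preprocessing as pp
        design, _, spectra, by_group, cal = groups
        fs_ns, fs_ss = _toy_feature_sets(spectra)
        X = fu.build_fused_X(by_group, fs_ns, fs_ss, group="NS",
                             calibration_ids_by_group=cal)
        # column 1 of the NS block = SG plane at band fs_ns.indices[1],
        # centered on the NS calibration cohort
        plane = pp.sg_smooth(by_group["NS"].values)
        cal_pos = [by_group["NS"].sample_ids.index(s) for s in cal["NS"]]
        col = plane[:, fs_ns.indices[1]] - plane[cal_pos, fs_ns.indices[1]].mean()
        np.testing.assert_allclose(X[:, 1], col, atol=1e-10)

    def test_exactly_one_mode_allowed(self, groups):
        _, _, spectra, by_group, cal = groups
        fs_ns, fs_ss = _toy_feature_sets(spectra)
        with pytest.raises(ValueError, match="exactly one"):
            fu.build_fused_X(by_group, fs_ns, fs_ss)


class TestTrainValidate:
    @pytest.fixture(scope="class")
    def outcome(self, small_world):
        _, design, physio, spectra = small_world
        fs_ns, fs_ss = _toy_feature_sets(spectra)
        return fu.train_and_validate_fusion(design, physio, spectra, "ETR",
                                            fs_ns, fs_ss, seed=0)

    def test_report_schema_three_groups(self, outcome):
        reports, _, _ = outcome
        assert [r.stress for r in reports] == ["NS", "SS", "NS*SS"]
        for r in reports:
            for field in ("r2_cal", "rmse_cal", "r2_val", "rmse_val"):
                assert np.isfinite(getattr(r, field))
            assert r.extra["rmse_val_raw"] > 0

    def test_denormalization_round_trip(self, outcome):
        _, _, stats = outcome
        rng = np.random.default_rng(0)
        z = rng.normal(0, 1, 30)
        for s in stats.values():
            back = fu.zscore(fu.inverse_zscore(z, s.mean, s.sd), s.mean, s.sd)
            np.testing.assert_allclose(back, z, atol=1e-12)

    def test_block_order_stable_across_runs(self, small_world):
        _, design, physio, spectra = small_world
        fs_ns, fs_ss = _toy_feature_sets(spectra)
        by_group = {g: spectra.subset(group_ids(design, g))
                    for g in ("NS", "SS", "NS*SS")}
        cal = {g: by_group[g].sample_ids[:20] for g in by_group}
        pairs = fu.pair_samples(design[design.group == "NS"],
                                design[design.group == "SS"])[:12]
        X1 = fu.build_fused_X(by_group, fs_ns, fs_ss, pairs=pairs,
                              calibration_ids_by_group=cal)
        X2 = fu.build_fused_X(by_group, fs_ns, fs_ss, pairs=pairs,
                              calibration_ids_by_group=cal)
        np.testing.assert_array_equal(X1, X2)
        # NS block first: its width equals the NS feature count
        assert X1.shape[1] == fs_ns.n_bands + fs_ss.n_bands
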