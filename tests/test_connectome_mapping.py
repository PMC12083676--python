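"""Seed time courses, connectivity maps, and surface-to-volume resampling."""

import numpy as np
import pytest

from atrophynet import (Connectome, GridSpace, MapKind, Seed, SubjectMap,
                        connectivity_map, resample_to_volume, seed_timecourse)
from atrophynet.connectome_mapping import R_CLIP

from conftest import make_map


def _random_connectome(rng, n_subjects=3, n_timepoints=30, n_units=20):
    space = GridSpace.full((n_units, 1, 1))
    series = [rng.normal(size=(n_timepoints, n_units))
              for _ in range(n_subjects)]
    return Connectome(space=space, series=series)


class TestSeedTimecourse:
    def test_single_voxel_seed_is_that_series(self, rng):
        conn = _random_connectome(rng)
        ts = conn.subject_series(0)
        out = seed_timecourse(Seed(indices=np.array([7])), ts)
        assert np.array_equal(out, ts[:, 7])

    def test_opposite_series_cancel(self, rng):
        s = rng.normal(size=30)
        series = np.column_stack([s, -s])
        out = seed_timecourse(Seed(indices=np.array([0, 1])), series)
        assert np.allclose(out, 0.0)

    def test_hand_computed_mean(self):
        series = np.array([[1.0, 2.0, 3.0],
                           [4.0, 5.0, 6.0],
                           [0.0, 0.0, 3.0],
                           [2.0, 2.0, 2.0],
                           [1.0, 0.0, -1.0]])
        out = seed_timecourse(Seed(indices=np.array([0, 1, 2])), series)
        assert np.allclose(out, [2.0, 5.0, 1.0, 2.0, 0.0])

    def test_weighted_mean(self):
        series = np.array([[1.0, 3.0], [2.0, 6.0]])
        seed = Seed(indices=np.array([0, 1]), weights=np.array([1.0, 3.0]))
        assert np.allclose(seed_timecourse(seed, series), [2.5, 5.0])

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            Seed(indices=np.array([], dtype=int))


class TestConnectivityMap:
    def test_matches_naive_triple_loop_oracle(self, rng):
        # brute force: per subject, per voxel, np.corrcoef + atanh; then mean
        conn = _random_connectome(rng, n_subjects=3, n_timepoints=30,
                                  n_units=20)
        seed = Seed(indices=np.array([0, 3, 11]))
        result = connectivity_map(seed, conn, aggregation="mean_z")
        zs = []
        for s in range(3):
            ts = conn.subject_series(s)
            tc = ts[:, [0, 3, 11]].mean(axis=1)
            z_subj = []
            for v in range(20):
                r = np.corrcoef(tc, ts[:, v])[0, 1]
                z_subj.append(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
            zs.append(z_subj)
        assert np.allclose(result.map.values, np.mean(zs, axis=0), atol=1e-10)

    def test_self_correlated_voxel_hits_clip_ceiling(self, rng):
        conn = _random_connectome(rng, n_subjects=2)
        result = connectivity_map(Seed(indices=np.array([4])), conn)
        assert result.map.values[4] == pytest.approx(np.arctanh(R_CLIP))
        assert result.degenerate

    def test_orthogonal_voxel_has_zero_z(self):
        t = np.arange(40)
        sin, cos = np.sin(2 * np.pi * t / 40), np.cos(2 * np.pi * t / 40)
        space = GridSpace.full((2, 1, 1))
        conn = Connectome(space=space, series=[np.column_stack([sin, cos])])
        result = connectivity_map(Seed(indices=np.array([0])), conn)
        assert result.map.values[1] == pytest.approx(0.0, abs=1e-10)

    def test_mean_z_is_average_of_per_subject_maps(self, rng):
        conn = _random_connectome(rng, n_subjects=2)
        seed = Seed(indices=np.array([1, 2]))
        both = connectivity_map(seed, conn).map.values
        one = connectivity_map(
            seed, Connectome(space=conn.space,
                             series=[conn.subject_series(0)])).map.values
        two = connectivity_map(
            seed, Connectome(space=conn.space,
                             series=[conn.subject_series(1)])).map.values
        assert np.allclose(both, (one + two) / 2, atol=1e-12)

    def test_invariant_to_affine_rescaling_of_seed_course(self, rng):
        # Pearson r is location/scale free: rescaling the seed's voxels'
        # series rescales its mean course, leaving the map unchanged
        conn = _random_connectome(rng)
        seed = Seed(indices=np.array([2, 5]))
        base = connectivity_map(seed, conn).map.values
        scaled = [s.copy() for s in [conn.subject_series(i) for i in range(3)]]
        for s in scaled:
            s[:, [2, 5]] = 3.0 * s[:, [2, 5]] + 7.0
        conn2 = Connectome(space=conn.space, series=scaled)
        assert np.allclose(connectivity_map(seed, conn2).map.values[np.r_[0:2, 3:5, 6:20]],
                           base[np.r_[0:2, 3:5, 6:20]], atol=1e-10)

    def test_streaming_matches_in_memory(self, rng, tmp_path):
        # the same connectome, loaded lazily from per-subject 4D files,
        # must give identical results
        space = GridSpace.full((3, 3, 2))
        series = [rng.normal(size=(25, 18)) for _ in range(4)]
        conn_mem = Connectome(space=space, series=series)
        conn_mem.save(tmp_path / "conn")
        conn_disk = Connectome.from_directory(tmp_path / "conn", space)
        seed = Seed(indices=np.array([0, 9, 17]))
        a = connectivity_map(seed, conn_mem).map.values
        b = connectivity_map(seed, conn_disk).map.values
        assert np.allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize("aggregation", ["mean_z", "t_stat"])
    def test_batched_multi_seed_equals_per_seed(self, rng, aggregation):
        # the one-pass matrix path for whole cohorts must agree with the
        # per-seed implementation to machine precision
        from atrophynet import connectivity_maps
        conn = _random_connectome(rng, n_subjects=4, n_timepoints=40,
                                  n_units=30)
        seeds = [Seed(indices=np.array([0, 5, 9])),
                 Seed(indices=np.array([2])),
                 Seed(indices=np.array([1, 7]),
                      weights=np.array([0.3, 1.7]))]
        batch = connectivity_maps(seeds, conn, aggregation=aggregation)
        for seed, cm in zip(seeds, batch):
            single = connectivity_map(seed, conn, aggregation=aggregation)
            assert np.allclose(cm.map.values, single.map.values, atol=1e-12)
            assert cm.degenerate == single.degenerate

    def test_t_aggregation_flags_degenerate(self, rng):
        conn = _random_connectome(rng, n_subjects=3)
        result = connectivity_map(Seed(indices=np.array([4])), conn,
                                  aggregation="t_stat")
        assert result.degenerate

    def test_abort_when_too_many_degenerate_seeds(self):
        space = GridSpace.full((3, 1, 1))
        flat = np.zeros((20, 3))
        flat[:, 1:] = np.random.default_rng(0).normal(size=(20, 2))
        conn = Connectome(space=space, series=[flat, flat])
        with pytest.raises(RuntimeError, match="degenerate"):
            connectivity_map(Seed(indices=np.array([0])), conn)


class TestResampleToVolume:
    def test_identity_lookup(self, rng):
        space = GridSpace.full((5, 1, 1))
        m = make_map(space, rng.uniform(1, 3, 5))
        out = resample_to_volume(m, {i: i for i in range(5)}, space)
        assert np.allclose(out.values, m.values)

    def test_two_vertices_average_into_one_voxel(self):
        surf = GridSpace.full((2, 1, 1))
        vol = GridSpace.full((3, 1, 1))
        m = SubjectMap(space=surf, values=np.array([-1.0, -3.0]),
                       kind=MapKind.wscore)
        out = resample_to_volume(m, {0: 1, 1: 1}, vol)
        assert out.values[1] == pytest.approx(-2.0)

    def test_empty_lookup_rejected(self, small_space, rng):
        m = make_map(small_space, rng.uniform(1, 3, 64))
        with pytest.raises(ValueError, match="empty"):
            resample_to_volume(m, {}, small_space)

    def test_out_of_mask_target_rejected(self, small_space, rng):
        m = make_map(small_space, rng.uniform(1, 3, 64))
        with pytest.raises(ValueError, match="out-of-mask"):
            resample_to_volume(m, {0: 99}, small_space)
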