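import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wormtrace.atlas import SEED_CLASSES, default_atlas, load_atlas, save_atlas
from wormtrace.core import Spot, Track
from wormtrace.identify import (
    assign_identities,
    build_body_frame,
    correlation_neighborhood,
    correlation_stats,
    find_seed_six,
    identify_tracks,
    track_groups,
)
from wormtrace.simulate import simulate_identification_scene
from wormtrace.traces import Trace


def _trace(tid, values):
    values = np.asarray(values, float)
    return Trace(track_id=tid, frames=np.arange(len(values)), values=values)


class TestCorrelationStats:
    def test_identical_traces_correlate_at_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 50)
        stats = correlation_stats([_trace(0, v), _trace(1, v), _trace(2, rng.normal(0, 1, 50))])
        assert stats.corr(0, 1) == pytest.approx(1.0)

    def test_negated_trace_correlates_at_minus_one(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, 50)
        stats = correlation_stats([_trace(0, v), _trace(1, -v), _trace(2, rng.normal(0, 1, 50))])
        assert stats.corr(0, 1) == pytest.approx(-1.0)

    def test_constant_trace_gets_zero_correlations(self, caplog):
        rng = np.random.default_rng(2)
        with caplog.at_level("WARNING"):
            stats = correlation_stats([
                _trace(0, np.full(20, 5.0)),
                _trace(1, rng.normal(0, 1, 20)),
                _trace(2, rng.normal(0, 1, 20)),
            ])
        assert stats.corr(0, 1) == 0.0

    def test_summary_matches_recomputation_on_seeded_draw(self):
        """C_mu / C_sigma recomputed independently from the upper triangle."""
        rng = np.random.default_rng(3)
        traces = [_trace(i, rng.normal(0, 1, 40)) for i in range(5)]
        stats = correlation_stats(traces)
        M = np.vstack([t.values for t in traces])
        C = np.corrcoef(M)
        iu = np.triu_indices(5, k=1)
        assert stats.c_mu == pytest.approx(C[iu].mean())
        assert stats.c_sigma == pytest.approx(C[iu].std())

    def test_backward_group_exceeds_mean_plus_sd(self):
        sc = simulate_identification_scene(seed=1)
        stats = correlation_stats(sc.traces)
        bw = [tid for tid, g in sc.groups.items() if g == "backward"]
        within = [stats.corr(a, b) for a in bw for b in bw if a < b]
        assert np.mean(within) > stats.c_mu + stats.c_sigma

    def test_too_few_traces_rejected(self):
        with pytest.raises(ValueError):
            correlation_stats([_trace(0, np.arange(20.0)), _trace(1, np.arange(20.0))])


class TestFindSeedSix:
    def test_planted_triplets_recovered(self):
        sc = simulate_identification_scene(seed=2)
        positions = {tr.track_id: tr.mean_position() for tr in sc.tracks}
        stats = correlation_stats(sc.traces)
        six, (a, b) = find_seed_six(stats, positions)
        names = {sc.true_labels[t] for t in six}
        assert names == set(SEED_CLASSES)
        # the split separates left from right
        sides = [{sc.true_labels[t][-1] for t in trip} for trip in (a, b)]
        assert sides == [{"L"}, {"R"}] or sides == [{"R"}, {"L"}]

    def test_equally_correlated_off_axis_decoys_rejected(self):
        """Three decoys share the backward signal but sit perpendicular to
        the dominant axis; the geometric filters must exclude them."""
        rng = np.random.default_rng(4)
        latent = np.cumsum(rng.normal(0, 1, 200))
        traces, positions = [], {}
        atlas = {a.class_name: a.position for a in default_atlas()}
        for i, cls in enumerate(SEED_CLASSES):
            traces.append(_trace(i, latent + rng.normal(0, 0.05, 200)))
            positions[i] = atlas[cls] * 25.0
        for j, p in enumerate([(0.0, 14.0, 3.0), (1.0, 18.0, -4.0), (-2.0, 22.0, 5.0)]):
            traces.append(_trace(6 + j, latent + rng.normal(0, 0.05, 200)))
            positions[6 + j] = np.array(p)
        for k in range(9, 21):  # uncorrelated filler defining the x spread
            traces.append(_trace(k, rng.normal(0, 1, 200)))
            positions[k] = np.array([rng.uniform(-40, 40), rng.uniform(-4, 4), rng.uniform(-6, 6)])
        stats = correlation_stats(traces)
        six, _ = find_seed_six(stats, positions)
        assert set(six) == set(range(6))

    def test_fewer_than_six_tracks_is_an_error(self):
        rng = np.random.default_rng(5)
        traces = [_trace(i, rng.normal(0, 1, 20)) for i in range(4)]
        stats = correlation_stats(traces)
        positions = {i: np.array([float(i), 0, 0]) for i in range(4)}
        with pytest.raises(ValueError, match="at least 6"):
            find_seed_six(stats, positions)

    def test_no_geometric_subset_raises(self):
        # scattered 3D positions: under tight collinearity demands no
        # 6-subset forms two clean triplets, so manual seeding is requested
        rng = np.random.default_rng(6)
        latent = np.cumsum(rng.normal(0, 1, 100))
        traces, positions = [], {}
        for i in range(14):
            traces.append(_trace(i, latent + rng.normal(0, 0.01, 100)))
            positions[i] = rng.uniform([-30, -10, -10], [30, 10, 10])
        stats = correlation_stats(traces)
        with pytest.raises(RuntimeError, match="manually"):
            find_seed_six(stats, positions, collinearity_tol=0.01, axis_angle_tol_deg=3.0)


class TestBodyFrame:
    def test_known_axes_recovered_within_five_degrees(self):
        # low placement noise isolates frame construction accuracy
        sc = simulate_identification_scene(seed=3, position_noise=0.03)
        positions = {tr.track_id: tr.mean_position() for tr in sc.tracks}
        stats = correlation_stats(sc.traces)
        six, _ = find_seed_six(stats, positions)
        frame = build_body_frame(
            np.array([positions[t] for t in six]), sc.head_direction,
            np.array(list(positions.values())),
        )
        R = sc.rotation
        for k, true_axis in enumerate([R[:, 0], R[:, 1], R[:, 2]]):
            cos = abs(float(frame.axes[k] @ true_axis))
            assert np.degrees(np.arccos(min(1.0, cos))) <= 5.0

    @staticmethod
    def _cloud(seed):
        """Random seeds + elongated cloud with head direction roughly along
        the dominant axis (as a user would supply it)."""
        rng = np.random.default_rng(seed)
        seeds = rng.uniform(-10, 10, (6, 3))
        allp = np.vstack([seeds, rng.uniform([-60, -10, -10], [60, 10, 10], (20, 3))])
        from wormtrace.identify import _principal_axis

        head = _principal_axis(allp) + rng.normal(0, 0.05, 3)
        return seeds, allp, head

    def test_equivariance_under_rotation(self):
        seeds, allp, head = self._cloud(7)
        f1 = build_body_frame(seeds, head, allp)
        R = Rotation.from_euler("xyz", [30, -50, 10], degrees=True).as_matrix()
        f2 = build_body_frame(seeds @ R.T, R @ head, allp @ R.T)
        np.testing.assert_allclose(f1.normalize(allp), f2.normalize(allp @ R.T), atol=1e-8)

    def test_scaling_leaves_normalized_coordinates_unchanged(self):
        seeds, allp, head = self._cloud(8)
        f1 = build_body_frame(seeds, head, allp)
        f2 = build_body_frame(seeds * 2.0, head, allp * 2.0)
        np.testing.assert_allclose(f1.normalize(allp), f2.normalize(allp * 2.0), atol=1e-8)

    def test_orthogonal_head_direction_rejected(self):
        rng = np.random.default_rng(9)
        seeds = np.column_stack([np.linspace(-5, 5, 6), np.zeros(6), np.zeros(6)])
        allp = np.vstack([seeds, rng.uniform(-20, 20, (10, 1)) * [1, 0, 0] + rng.uniform(-2, 2, (10, 3)) * [0, 1, 1]])
        with pytest.raises(ValueError, match="orthogonal"):
            build_body_frame(seeds, np.array([0.0, 1.0, 0.0]), allp)


class TestAssignIdentities:
    def test_atlas_consistent_scene_fully_recovered(self):
        sc = simulate_identification_scene(seed=4)
        asg, frame, stats = identify_tracks(sc.tracks, sc.traces, sc.head_direction)
        assert all(asg.mapping[tid] == sc.true_labels[tid] for tid in sc.true_labels)

    def test_seed_six_members_get_backward_classes(self):
        sc = simulate_identification_scene(seed=5)
        asg, _, _ = identify_tracks(sc.tracks, sc.traces, sc.head_direction)
        atlas_groups = {a.class_name: a.group for a in default_atlas()}
        for tid in asg.seed_six:
            assert atlas_groups[asg.mapping[tid]] == "backward"

    def test_mirroring_left_axis_swaps_left_right_labels(self):
        """With the lateral axis mirrored (the effect of resolving the
        left/right ambiguity the other way), bilateral class labels swap
        exactly while unsided classes keep their labels."""
        from wormtrace.identify import BodyFrame, find_seed_six

        sc = simulate_identification_scene(seed=6)
        positions = {tr.track_id: tr.mean_position() for tr in sc.tracks}
        stats = correlation_stats(sc.traces)
        six, _ = find_seed_six(stats, positions)
        frame = build_body_frame(
            np.array([positions[t] for t in six]), sc.head_direction,
            np.array(list(positions.values())),
        )
        mirrored = BodyFrame(
            origin=frame.origin,
            axes=np.vstack([frame.axes[0], frame.axes[1], -frame.axes[2]]),
            scale=frame.scale,
        )
        asg1 = assign_identities(list(positions), positions, frame, stats, six)
        asg2 = assign_identities(list(positions), positions, mirrored, stats, six)

        def flip(name):
            if name.endswith("L"):
                return name[:-1] + "R"
            if name.endswith("R"):
                return name[:-1] + "L"
            return name

        for tid, name in asg1.mapping.items():
            if name[-1] in "LR":
                assert asg2.mapping[tid] == flip(name)

    def test_group_classification_thresholds(self):
        sc = simulate_identification_scene(seed=7)
        stats = correlation_stats(sc.traces)
        bw = [tid for tid, g in sc.groups.items() if g == "backward"]
        seed_six = bw[:6]
        groups = track_groups(list(sc.groups), stats, seed_six)
        for tid, g in sc.groups.items():
            if g == "backward":
                assert groups[tid] == "backward"
            elif g == "forward":
                assert groups[tid] == "forward"

    def test_assignment_injective_over_classes(self):
        sc = simulate_identification_scene(seed=8)
        asg, _, _ = identify_tracks(sc.tracks, sc.traces, sc.head_direction)
        names = list(asg.mapping.values())
        assert len(names) == len(set(names))


class TestCorrelationNeighborhood:
    def test_backward_seed_pulls_its_group(self):
        sc = simulate_identification_scene(seed=9)
        stats = correlation_stats(sc.traces)
        bw = [tid for tid, g in sc.groups.items() if g == "backward"]
        fw = [tid for tid, g in sc.groups.items() if g == "forward"]
        corr, anti = correlation_neighborhood(bw[0], stats, threshold_sds=1.0)
        assert set(bw) - {bw[0]} <= set(corr)
        assert set(fw) <= set(anti)

    def test_infinite_threshold_empties_both_lists(self):
        sc = simulate_identification_scene(seed=10)
        stats = correlation_stats(sc.traces)
        corr, anti = correlation_neighborhood(0, stats, threshold_sds=1e9)
        assert corr == [] and anti == []

    def test_self_excluded_and_unknown_id_raises(self):
        sc = simulate_identification_scene(seed=11)
        stats = correlation_stats(sc.traces)
        corr, anti = correlation_neighborhood(0, stats)
        assert 0 not in corr and 0 not in anti
        with pytest.raises(KeyError):
            correlation_neighborhood(999, stats)


class TestAtlas:
    def test_default_atlas_normalized_on_seed_six(self):
        atlas = default_atlas()
        by_name = {a.class_name: a for a in atlas}
        from itertools import combinations

        seed_pos = np.array([by_name[c].position for c in SEED_CLASSES])
        np.testing.assert_allclose(seed_pos.mean(axis=0), 0.0, atol=1e-12)
        mean_dist = np.mean([np.linalg.norm(p - q) for p, q in combinations(seed_pos, 2)])
        assert mean_dist == pytest.approx(1.0)

    def test_atlas_round_trip(self, tmp_path):
        atlas = default_atlas()
        path = tmp_path / "atlas.csv"
        save_atlas(atlas, path)
        back = load_atlas(path)
        assert [a.class_name for a in back] == [a.class_name for a in atlas]
        np.testing.assert_allclose(
            np.array([a.position for a in back]), np.array([a.position for a in atlas]), atol=1e-12
        )

    def test_duplicate_class_names_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "class_name,x,y,z,group,side\n"
            + "\n".join(f"{c},0,0,0,backward,L" for c in list(SEED_CLASSES) + ["AVAL"])
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_atlas(path)
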