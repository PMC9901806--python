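import numpy as np
import pytest
from scipy.optimize import linprog

from filatrack import synthetic as syn
from filatrack.filament import Filament
from filatrack.tracking import (
    Segment,
    TrackingSettings,
    base_distance,
    consolidate,
    fragment_filament,
    link_filaments,
    solve_transport,
    track_stack,
)


def _seg(points, weight=None, orientation=0.0, fid=0):
    pts = np.asarray(points, dtype=float)
    if weight is None:
        weight = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))) or 1.0
    return Segment(filament_id=fid, points=pts, weight=weight, orientation=orientation)


def dense_lp_oracle(cost, wp, wc, max_dist=20.0):
    """Independent dense LP formulation built row by row; true pairs
    beyond the joining bound are priced out with a big-M cost."""
    R, C = cost.shape
    cost = cost.copy()
    over = cost > max_dist**2 + 1e-9
    over[R - 1, :] = False
    over[:, C - 1] = False
    cost[over] = 1e9
    n_var = R * C
    A = []
    b = []
    for j in range(R):
        row = np.zeros(n_var)
        row[j * C : (j + 1) * C] = 1.0
        A.append(row)
        b.append(wp[j])
    for k in range(C):
        row = np.zeros(n_var)
        row[k::C] = 1.0
        A.append(row)
        b.append(wc[k])
    res = linprog(cost.ravel(), A_eq=np.array(A), b_eq=np.array(b), bounds=(0, None))
    assert res.success
    return res.fun


def random_instance(rng, n, m, spread=60.0):
    producers, consumers = [], []
    for i in range(n):
        p = rng.uniform(0, spread, size=2)
        q = p + rng.uniform(-8, 8, size=2)
        producers.append(_seg([p, q], weight=rng.uniform(2, 12),
                              orientation=rng.uniform(0, 180), fid=i))
    for k in range(m):
        p = rng.uniform(0, spread, size=2)
        q = p + rng.uniform(-8, 8, size=2)
        consumers.append(_seg([p, q], weight=rng.uniform(2, 12),
                              orientation=rng.uniform(0, 180), fid=k))
    return producers, consumers


class TestFragmentFilament:
    def test_length_35_gives_10_10_15(self):
        f = Filament.from_points([(0, 0), (35, 0)], width=1)
        segs = fragment_filament(f, 10)
        assert [pytest.approx(s.weight) for s in segs] == [10, 10, 15]

    def test_short_filament_single_piece(self):
        f = Filament.from_points([(0, 0), (8, 0)], width=1)
        segs = fragment_filament(f, 10)
        assert len(segs) == 1
        assert segs[0].weight == pytest.approx(8)

    def test_weights_sum_to_length(self, rng):
        pts = np.cumsum(rng.integers(-6, 7, size=(12, 2)), axis=0) + 100
        f = Filament.from_points(pts, width=1)
        segs = fragment_filament(f, 10)
        assert sum(s.weight for s in segs) == pytest.approx(f.length, abs=1e-9)

    def test_large_remainder_kept_separate(self):
        f = Filament.from_points([(0, 0), (27, 0)], width=1)
        segs = fragment_filament(f, 10)
        assert [pytest.approx(s.weight) for s in segs] == [10, 10, 7]


class TestBaseDistance:
    def test_identical_zero(self):
        s = TrackingSettings()
        a = _seg([(0, 0), (10, 0)], orientation=0.0)
        assert base_distance(a, a, s) == 0.0

    def test_eq1_composition(self):
        s = TrackingSettings()  # factor_length=4, factor_angle=1
        a = _seg([(0, 0), (5, 0)], orientation=0.0)
        b = _seg([(8, 0), (13, 0)], orientation=4.0)  # d_l=3, d_phi=4
        assert base_distance(a, b, s) == pytest.approx(4 * 9 + 16)

    def test_angle_wraparound(self):
        s = TrackingSettings(factor_length=0.0, factor_angle=1.0)
        a = _seg([(0, 0), (5, 0)], orientation=10.0)
        b = _seg([(0, 0), (5, 0)], orientation=170.0)
        assert base_distance(a, b, s) == pytest.approx(400.0)  # d_phi = 20


class TestSolveTransport:
    def test_single_pair_full_flow(self):
        s = TrackingSettings()
        a = _seg([(0, 0), (7, 0)], weight=7.0)
        b = _seg([(1, 0), (8, 0)], weight=7.0)
        plan = solve_transport([a], [b], s)
        assert plan.flows[0, 0] == pytest.approx(7.0)
        assert plan.flows[0, 1] == pytest.approx(0.0)  # dummies idle
        assert plan.flows[1, 0] == pytest.approx(0.0)

    def test_unbalanced_mass_to_dummy(self):
        s = TrackingSettings()
        a = _seg([(0, 0), (5, 0)], weight=5.0)
        b = _seg([(1, 0), (4, 0)], weight=3.0)
        plan = solve_transport([a], [b], s)
        assert plan.flows[0, 0] == pytest.approx(3.0)
        assert plan.flows[0, 1] == pytest.approx(2.0)  # excess to dummy consumer

    @pytest.mark.parametrize("seed", range(8))
    def test_objective_matches_dense_lp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P, C = random_instance(rng, 4, 5)
        s = TrackingSettings()
        plan = solve_transport(P, C, s)
        obj = dense_lp_oracle(plan.cost, plan.producer_weights, plan.consumer_weights)
        assert plan.objective == pytest.approx(obj, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_mass_conservation_and_locality(self, seed):
        rng = np.random.default_rng(100 + seed)
        P, C = random_instance(rng, 5, 4, spread=80.0)
        s = TrackingSettings()  # d_max=20, factors (4, 1)
        plan = solve_transport(P, C, s)
        # marginals hold for every true producer/consumer
        np.testing.assert_allclose(
            plan.flows.sum(axis=1), plan.producer_weights, atol=1e-7
        )
        np.testing.assert_allclose(
            plan.flows.sum(axis=0), plan.consumer_weights, atol=1e-7
        )
        # locality: no flow across pairs beyond the joining bounds
        from scipy.spatial.distance import cdist
        from filatrack.geometry import orientation_difference

        for j, p in enumerate(P):
            for k, c in enumerate(C):
                d_l = cdist(p.points, c.points).min()
                d_phi = orientation_difference(p.orientation, c.orientation)
                if d_l > s.max_dist / 2 or d_phi > s.max_dist:
                    assert plan.flows[j, k] <= 1e-7

    def test_nonpositive_weight_rejected(self):
        s = TrackingSettings()
        a = _seg([(0, 0), (5, 0)], weight=0.0)
        with pytest.raises(ValueError):
            solve_transport([a], [a], s)


class TestConsolidate:
    def test_identity_tracking_diagonal(self):
        s = TrackingSettings()
        f1 = Filament.from_points([(10, 10), (50, 10)], width=2)
        f2 = Filament.from_points([(10, 40), (60, 60)], width=2)
        f1.id, f2.id = 0, 1
        segs = [x for f in (f1, f2) for x in fragment_filament(f, s.fragment_length)]
        plan = solve_transport(segs, segs, s)
        M = consolidate(plan, segs, segs, 2, 2)
        assert M[0, 0] == pytest.approx(f1.length, rel=1e-6)
        assert M[1, 1] == pytest.approx(f2.length, rel=1e-6)
        assert M[0, 1] == pytest.approx(0.0, abs=1e-7)

    def test_block_sum_manual(self):
        s = TrackingSettings()
        P = [_seg([(0, 0), (10, 0)], weight=10, fid=0), _seg([(10, 0), (20, 0)], weight=10, fid=0)]
        C = [_seg([(0, 1), (10, 1)], weight=10, fid=0), _seg([(10, 1), (20, 1)], weight=10, fid=1)]
        plan = solve_transport(P, C, s)
        M = consolidate(plan, P, C, 1, 2)
        manual = np.zeros((1, 2))
        t = plan.true_flows()
        manual[0, 0] = t[0, 0] + t[1, 0]
        manual[0, 1] = t[0, 1] + t[1, 1]
        np.testing.assert_allclose(M, manual)

    def test_all_mass_to_dummy_zero_matrix(self):
        s = TrackingSettings()
        a = _seg([(0, 0), (10, 0)], weight=10, fid=0)
        b = _seg([(500, 500), (510, 500)], weight=10, fid=0)  # far away
        plan = solve_transport([a], [b], s)
        M = consolidate(plan, [a], [b], 1, 1)
        np.testing.assert_allclose(M, 0.0, atol=1e-7)


class TestLinkFilaments:
    def test_full_mass_links(self):
        s = TrackingSettings()
        M = np.array([[40.0, 0.0]])
        links = link_filaments(M, [40.0], [40.0, 12.0], s)
        assert links[0] == [0]

    def test_zero_mass_solitary(self):
        s = TrackingSettings()
        links = link_filaments(np.zeros((1, 2)), [40.0], [40.0, 40.0], s)
        assert links[0] == []

    def test_accumulation_follows_hand_trace(self):
        s = TrackingSettings(min_valid=0.3, min_matched=0.6, min_rel_size=0.25, min_abs_size=10)
        # filament a of length 40; successors with masses 18, 12, 5
        M = np.array([[18.0, 12.0, 5.0]])
        links = link_filaments(M, [40.0], [40.0, 30.0, 20.0], s)
        # hand trace: 18 < 24 -> add next; 18+12=30 >= 24 -> stop; 30 >= 12 valid
        assert links[0] == [0, 1]

    def test_min_abs_and_rel_size_prefilter(self):
        s = TrackingSettings(min_abs_size=10, min_rel_size=0.25)
        M = np.array([[30.0, 30.0]])
        # first successor too short absolutely, second relatively (len 9 < 0.25*40=10)
        links = link_filaments(M, [40.0], [8.0, 9.9], s)
        assert links[0] == []

    def test_below_min_valid_solitary(self):
        s = TrackingSettings(min_valid=0.3)
        M = np.array([[5.0]])
        links = link_filaments(M, [40.0], [40.0], s)
        assert links[0] == []  # 5 < 12


def _drift_frames(n_frames=10, step=3.0, extra_frame=None):
    specs = [
        syn.line_stroke((30, 40), (150, 60)),
        syn.arc_stroke((100, 140), 60, -2.0, -1.0),
        syn.line_stroke((40, 180), (160, 150)),
    ]
    frames = []
    for t in range(n_frames):
        fl = [
            Filament.from_points(syn.stroke_polyline(sp.translated(step * t, 0)), width=4)
            for sp in specs
        ]
        if extra_frame is not None and t == extra_frame:
            fl.append(
                Filament.from_points(
                    syn.stroke_polyline(syn.line_stroke((220, 200), (260, 230))), width=4
                )
            )
        frames.append(fl)
    return frames


class TestTrackStack:
    def test_static_stack_full_persistence(self):
        frames = _drift_frames(5, step=0.0)
        life = track_stack(frames, TrackingSettings())
        assert len(life) == 3
        assert all(d.persistence == 5 for d in life)

    def test_drift_within_dmax(self):
        frames = _drift_frames(10, step=3.0)
        life = track_stack(frames, TrackingSettings(max_dist=20.0))
        assert len(life) == 3
        assert all(d.persistence == 10 for d in life)

    def test_single_frame_filament_filterable(self):
        frames = _drift_frames(5, step=3.0, extra_frame=2)
        life = track_stack(frames, TrackingSettings())
        assert sorted(d.persistence for d in life) == [1, 5, 5, 5]
        filtered = track_stack(frames, TrackingSettings(), min_persistence=2)
        assert sorted(d.persistence for d in filtered) == [5, 5, 5]

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            track_stack(_drift_frames(1), TrackingSettings())

    def test_palindromic_stack_symmetry(self):
        fw = _drift_frames(4, step=4.0)
        frames = fw + fw[-2::-1]  # 1..n..1
        life = track_stack(frames, TrackingSettings())
        spans = sorted((d.birth, d.death) for d in life)
        n = len(frames)
        mirrored = sorted((n - 1 - d1, n - 1 - d0) for d0, d1 in spans)
        assert spans == mirrored

    def test_fragment_length_stability(self):
        # doubling fragment_length changes total matched mass by < 10%
        frames = _drift_frames(2, step=2.0)
        from filatrack.tracking import _pair_links

        masses = []
        for fl in (5.0, 10.0):
            s = TrackingSettings(fragment_length=fl)
            _, M = _pair_links(frames[0], frames[1], s)
            masses.append(M.sum())
        assert abs(masses[1] - masses[0]) / masses[0] < 0.10
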