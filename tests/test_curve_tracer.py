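import numpy as np
import pytest

from filatrack import synthetic as syn
from filatrack.curve_tracer import (
    Gatherer,
    TracerSettings,
    extend_gatherer,
    seed_direction_pair,
    trace_filaments,
    validate_filament,
)
from filatrack.filament import Filament
from filatrack.geometry import orientation_difference
from filatrack.preprocessing import binarize
from filatrack.sensing import OrientationField, compute_width_map


def _stripe_wm(shape=(60, 120), rows=(28, 33), cols=(5, 115)):
    mask = np.zeros(shape, dtype=bool)
    mask[rows[0] : rows[1], cols[0] : cols[1]] = True
    return compute_width_map(mask)


class TestSeedDirectionPair:
    def test_horizontal_stripe_center(self):
        wm = _stripe_wm()
        a, b, ma, mb = seed_direction_pair(wm, (60, 30), TracerSettings())
        assert (a, b) == (0.0, 180.0)
        assert ma > 1 and mb > 1

    def test_isolated_pixel_tie_rule(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20, 20] = True
        wm = compute_width_map(mask)
        a, b, ma, mb = seed_direction_pair(wm, (20, 20), TracerSettings())
        assert (a, b) == (0.0, 180.0)  # all means equal -> smallest pair

    def test_diagonal_stroke(self):
        img, _ = syn.render_strokes(
            [syn.line_stroke((20, 100), (100, 20), width=5)], shape=(120, 120)
        )
        wm = compute_width_map(binarize(img))
        s = TracerSettings()
        a, b, _, _ = seed_direction_pair(wm, (60, 60), s)
        assert orientation_difference(a, 45.0) <= s.increment


class TestExtendGatherer:
    def _gatherer(self, wm, start, direction):
        return Gatherer(
            chain=[start],
            widths=[wm.value_at(start)],
            vertex_idx=[0],
            direction=direction,
            score=wm.value_at(start),
        )

    def test_full_step_on_straight_stripe(self):
        wm = _stripe_wm()
        g = extend_gatherer(self._gatherer(wm, (40, 30), 0.0), wm, TracerSettings())
        assert g is not None
        assert g.direction == 0.0
        assert g.end == (40 + TracerSettings().l_str, 30)

    def test_trimmed_step_then_stop(self):
        # thick stripe ending 4 px after the gatherer tip: the l_str=10 step
        # is trimmed to the stripe end, the next call stops
        wm = _stripe_wm(shape=(60, 120), rows=(10, 31), cols=(5, 45))
        s = TracerSettings()
        g = extend_gatherer(self._gatherer(wm, (40, 20), 0.0), wm, s)
        assert g is not None
        assert g.end[0] <= 44  # trimmed to the stripe end, not l_str away
        assert extend_gatherer(g, wm, s) is None  # then STOP

    def test_stop_facing_background(self):
        wm = _stripe_wm()
        g0 = self._gatherer(wm, (114, 30), 0.0)
        assert extend_gatherer(g0, wm, TracerSettings()) is None
        assert g0.chain == [(114, 30)]  # unchanged


class TestTraceFilaments:
    def test_blank_mask(self):
        assert trace_filaments(np.zeros((64, 64), dtype=bool), TracerSettings()) == []

    def test_bezier_recovery(self):
        spec = syn.bezier_stroke((20, 140), (100, 30), (200, 150), width=4)
        img, truth = syn.render_strokes([spec], shape=(200, 220))
        fils = trace_filaments(binarize(img), TracerSettings(l_min=40, l_str=10, phi_diff=3.0))
        assert len(fils) == 1
        t = truth.iloc[0]
        assert fils[0].length == pytest.approx(t.length, rel=0.10)
        assert abs(fils[0].mean_width - t.width) <= 1.0

    def test_two_parallel_strokes(self):
        img, _ = syn.render_strokes(
            [
                syn.line_stroke((20, 40), (180, 40), width=4),
                syn.line_stroke((20, 60), (180, 60), width=4),
            ],
            shape=(100, 200),
        )
        fils = trace_filaments(binarize(img), TracerSettings())
        assert len(fils) == 2
        masks = [f.claimed_mask for f in fils]
        assert not (masks[0] & masks[1]).any()  # claims are disjoint

    def test_accepted_invariants(self):
        img, _ = syn.render_strokes(
            [
                syn.line_stroke((20, 40), (180, 70), width=4),
                syn.arc_stroke((100, 160), 60, -2.2, -0.9, width=4),
            ],
            shape=(200, 220),
        )
        s = TracerSettings(l_min=30, l_str=10, phi_diff=2.0)
        fils = trace_filaments(binarize(img), s)
        assert fils
        claimed_total = np.zeros(img.shape, dtype=bool)
        for f in fils:
            assert f.length >= s.l_min
            steps = np.linalg.norm(np.diff(f.points.astype(float), axis=0), axis=1)
            assert np.all(steps <= s.l_str + 1.0)  # rounding slack
            assert not (claimed_total & f.claimed_mask).any()
            claimed_total |= f.claimed_mask

    def test_rotation_equivariance(self):
        img, _ = syn.render_strokes(
            [syn.line_stroke((30, 60), (170, 100), width=4)], shape=(200, 210)
        )
        mask = binarize(img)
        s = TracerSettings()
        fils = trace_filaments(mask, s)
        fils_rot = trace_filaments(np.rot90(mask), s)
        assert len(fils) == len(fils_rot) == 1
        from filatrack.features import filament_descriptors

        a = filament_descriptors(fils[0]).angle
        b = filament_descriptors(fils_rot[0]).angle
        assert orientation_difference((a + 90.0) % 180.0, b) <= s.increment

    def test_straight_mode_consistency(self):
        # curve mode on straight strokes matches straight mode within 5%
        from filatrack.sensing import SensorSettings, scan_straight_filaments

        img, _ = syn.render_strokes(
            [
                syn.line_stroke((20, 50), (180, 50), width=4),
                syn.line_stroke((30, 120), (170, 160), width=4),
            ],
            shape=(200, 210),
        )
        mask = binarize(img)
        curved = trace_filaments(mask, TracerSettings(l_min=30))
        wm = compute_width_map(mask)
        straight, _ = scan_straight_filaments(wm, SensorSettings(minimal_length=30))
        assert len(curved) == len(straight) == 2
        for fc, fs in zip(
            sorted(curved, key=lambda f: -f.length),
            sorted(straight, key=lambda f: -f.length),
        ):
            assert fc.length == pytest.approx(fs.length, rel=0.05)

    @pytest.mark.parametrize(
        "radius,l_str,phi",
        [(30, 5, 4.0), (60, 10, 4.0), (120, 10, 2.0)],
    )
    def test_arc_curvature_recovery(self, radius, l_str, phi):
        from filatrack.features import filament_descriptors

        span = 3.0 if radius == 30 else 1.6
        spec = syn.arc_stroke((128, 128), radius, -span / 2 - 1.2, span / 2 - 1.2, width=5)
        img, _ = syn.render_strokes([spec], shape=(256, 256))
        fils = trace_filaments(
            binarize(img), TracerSettings(l_min=25, l_str=l_str, phi_diff=phi)
        )
        assert len(fils) == 1
        k = filament_descriptors(fils[0]).curvature
        assert k == pytest.approx(1.0 / radius, rel=0.20)


def _field_with_vertical(shape, x0, x1, y0, y1):
    of = OrientationField(shape)
    m = np.zeros(shape, dtype=bool)
    m[y0:y1, x0:x1] = True
    of.mark(m, 90.0)
    return of


class TestValidateFilament:
    def _horizontal(self, n=60, y=50):
        return Filament.from_points([(10, y), (10 + n, y)], width=3)

    def test_unset_field_accepts(self):
        s = TracerSettings()
        f = self._horizontal()
        res = validate_filament(f, OrientationField((100, 100)), s)
        assert res.kind == "accept"

    def test_interior_conflict_discards(self):
        s = TracerSettings()
        f = self._horizontal(n=60)
        # vertical marks over 40% of the chain, interior only
        of = _field_with_vertical((100, 100), 25, 50, 0, 100)
        res = validate_filament(f, of, s)
        assert res.kind == "discard"

    def test_low_conflict_accepts(self):
        s = TracerSettings()
        f = self._horizontal(n=60)
        of = _field_with_vertical((100, 100), 30, 42, 0, 100)  # ~20%
        assert validate_filament(f, of, s).kind == "accept"

    def test_exactly_thirty_percent_not_accepted(self):
        s = TracerSettings()
        # 20-pixel chain, exactly 6 conflicting pixels = 0.30
        f = Filament.from_points([(10, 50), (29, 50)], width=3)
        assert len(f.chain) == 20
        of = _field_with_vertical((100, 100), 14, 20, 0, 100)
        conflicts = 6 / 20
        assert conflicts == 0.30
        res = validate_filament(f, of, s)
        assert res.kind != "accept"  # strict "less than" rule

    def test_endpoint_conflict_shortens(self):
        s = TracerSettings(l_min=30)
        f = self._horizontal(n=80)
        # conflicts at the left end over ~40% of pixels
        of = _field_with_vertical((100, 120), 0, 45, 0, 100)
        res = validate_filament(f, of, s)
        assert res.kind == "shorten"
        assert res.filament.length >= s.l_min
        # the shortened filament is conflict-free
        res2 = validate_filament(res.filament, of, s)
        assert res2.kind == "accept"
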