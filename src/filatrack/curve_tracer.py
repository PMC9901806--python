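"""Curved-filament tracing by seeded bidirectional forward search.

Seeds are taken from the width map in decreasing diameter order.  From a
seed, all directions are probed at 3°·phi_diff increments over rays of
length 2·l_str and the opposite pair with the largest summed mean width
starts two gatherers.  Each gatherer advances in steps of at most l_str,
choosing among the previous direction and its two angular neighbours the
one with the highest directional mean width, trimming trailing pixels of
insufficient width, and stopping when no candidate direction has mean
width >= 1.  Joined gatherers become ranked candidates which are then
validated against the orientation field of previously accepted (longer)
filaments.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .filament import Filament
from .geometry import direction_vector, orientation_difference, stamp_disks
from .sensing import (
    OrientationField,
    WidthMap,
    compute_width_map,
    directional_mean_width,
    ray_points,
)

__all__ = [
    "TracerSettings",
    "Gatherer",
    "ValidationResult",
    "seed_direction_pair",
    "extend_gatherer",
    "validate_filament",
    "trace_filaments",
]

_MAX_CHAIN = 100_000  # safety bound against pathological loops


@dataclass
class TracerSettings:
    l_min: float = 30.0  # minimal accepted filament length, pixels
    l_str: int = 10  # straight-piece step length, pixels
    phi_diff: float = 1.0  # multiplier of the 3° probing increment
    alpha_tol: float = 20.0  # degrees; conflicting-orientation threshold
    conflict_fraction_limit: float = 0.30
    tolerance: float = 0.0  # width-map disk-miss tolerance

    def __post_init__(self):
        if not (self.l_min >= self.l_str >= 2):
            raise ValueError("need l_min >= l_str >= 2")
        if not (0.0 < self.alpha_tol < 90.0):
            raise ValueError("alpha_tol must be in (0, 90)")
        if not (0.0 < self.conflict_fraction_limit < 1.0):
            raise ValueError("conflict_fraction_limit must be in (0, 1)")
        if self.phi_diff <= 0:
            raise ValueError("phi_diff must be positive")

    @property
    def increment(self) -> float:
        """Effective probing increment in degrees."""
        return 3.0 * self.phi_diff


@dataclass
class Gatherer:
    """A growing curve candidate: accumulated points, width-sum score and
    the direction of the last step.

    ``pos`` is the sub-pixel endpoint the next step starts from; keeping
    it un-rounded prevents the trace from drifting off the stroke center
    one rounding error at a time.
    """

    chain: list  # [(x, y), ...], seed first
    widths: list
    vertex_idx: list
    direction: float  # degrees
    score: float = 0.0
    pos: tuple | None = None  # float endpoint; defaults to chain[-1]

    def __post_init__(self):
        if self.pos is None:
            self.pos = (float(self.chain[-1][0]), float(self.chain[-1][1]))

    @property
    def end(self):
        return self.chain[-1]


def seed_direction_pair(wm: WidthMap, p, s: TracerSettings):
    """Probe all directions from ``p``; return the opposite direction pair
    with the largest summed mean width over rays of length 2·l_str.

    Returns ``(angle_a, angle_b, mean_a, mean_b)``; ties resolve to the
    smallest angle pair.
    """
    inc = s.increment
    n = int(round(360.0 / inc))
    half = n // 2
    means = np.array(
        [directional_mean_width(wm, p, k * inc, 2 * s.l_str) for k in range(n)]
    )
    best_k, best_sum = 0, -1.0
    for k in range(half):
        tot = means[k] + means[k + half]
        if tot > best_sum + 1e-12:
            best_k, best_sum = k, tot
    a = best_k * inc
    return a, a + 180.0, float(means[best_k]), float(means[best_k + half])


def extend_gatherer(g: Gatherer, wm: WidthMap, s: TracerSettings) -> Gatherer | None:
    """One elongation step; returns the grown gatherer or None (STOP).

    The step direction is the best of {previous, ±one increment} by mean
    width over an l_str ray; trailing ray pixels with pointwise width < 1
    are trimmed.  STOP when no candidate direction reaches mean width 1.
    """
    inc = s.increment
    best_theta, best_mean = None, -1.0
    for dtheta in (0.0, -inc, inc):  # prefer straight-on at ties
        theta = g.direction + dtheta
        m = directional_mean_width(wm, g.pos, theta, s.l_str)
        if m > best_mean + 1e-12:
            best_theta, best_mean = theta, m
    if best_mean < 1.0:
        return None
    pts = ray_points(g.pos, best_theta, s.l_str)
    # snap each sample one pixel toward the width ridge, perpendicular to
    # the step: keeps the recorded chain on the stroke center instead of
    # hugging an edge where the width map is small
    perp = direction_vector(best_theta + 90.0)
    px, py = int(round(perp[0])), int(round(perp[1]))
    snapped = []
    for p in pts:
        cands = [(p[0], p[1]), (p[0] + px, p[1] + py), (p[0] - px, p[1] - py)]
        snapped.append(max(cands, key=lambda q: (wm.value_at(q), q == (p[0], p[1]))))
    pts = np.asarray(snapped, dtype=int)
    vals = np.array([wm.value_at(p) for p in pts])
    # trim trailing points with insufficient width
    suff = np.nonzero(vals >= 1.0)[0]
    if len(suff) == 0:
        return None
    t_last = int(suff[-1]) + 1  # step length actually taken
    pts = pts[:t_last]
    vals = vals[:t_last]
    chain = list(g.chain)
    widths = list(g.widths)
    added = 0
    for (x, y), v in zip(pts, vals):
        if (int(x), int(y)) != tuple(chain[-1]):
            chain.append((int(x), int(y)))
            widths.append(float(v))
            added += 1
    if added == 0 or len(chain) > _MAX_CHAIN:
        return None
    d = direction_vector(best_theta)
    ideal = (g.pos[0] + t_last * d[0], g.pos[1] + t_last * d[1])
    # keep the sub-pixel endpoint but concede the snap correction
    end = chain[-1]
    new_pos = (
        (ideal[0] + end[0]) / 2.0,
        (ideal[1] + end[1]) / 2.0,
    )
    return Gatherer(
        chain=chain,
        widths=widths,
        vertex_idx=list(g.vertex_idx) + [len(chain) - 1],
        direction=best_theta,
        score=g.score + float(np.sum(vals)),
        pos=new_pos,
    )


def _grow(wm: WidthMap, seed, direction: float, s: TracerSettings) -> Gatherer:
    g = Gatherer(
        chain=[tuple(int(v) for v in seed)],
        widths=[wm.value_at(seed)],
        vertex_idx=[0],
        direction=direction,
        score=wm.value_at(seed),
    )
    while True:
        nxt = extend_gatherer(g, wm, s)
        if nxt is None:
            return g
        g = nxt


def _join(ga: Gatherer, gb: Gatherer) -> Filament | None:
    """Fuse two gatherers grown in opposite directions from one seed."""
    na = len(ga.chain)
    chain = list(reversed(ga.chain)) + list(gb.chain[1:])
    if len(chain) < 2:
        return None
    widths = list(reversed(ga.widths)) + list(gb.widths[1:])
    vidx_a = sorted(na - 1 - i for i in ga.vertex_idx)
    vidx_b = [na - 1 + (i) for i in gb.vertex_idx[1:]]
    vidx = vidx_a + vidx_b
    if vidx[0] != 0:
        vidx = [0] + vidx
    if vidx[-1] != len(chain) - 1:
        vidx.append(len(chain) - 1)
    score = ga.score + gb.score - ga.widths[0]  # seed counted once
    return Filament(
        chain=np.asarray(chain),
        widths=np.asarray(widths),
        vertex_idx=np.asarray(sorted(set(vidx))),
        score=float(score),
    )


@dataclass
class ValidationResult:
    kind: str  # 'accept' | 'shorten' | 'discard'
    filament: Filament | None = None


def _conflicts(f: Filament, of: OrientationField, alpha_tol: float) -> np.ndarray:
    """Per-chain-pixel conflict flags against the orientation field."""
    marked = of.values_at(f.chain)
    local = f.pixel_orientations()
    out = np.zeros(len(f.chain), dtype=bool)
    has = ~np.isnan(marked)
    if has.any():
        diff = np.array(
            [orientation_difference(a, b) for a, b in zip(marked[has], local[has])]
        )
        out[has] = diff > alpha_tol
    return out


def validate_filament(
    f: Filament, of: OrientationField, s: TracerSettings
) -> ValidationResult:
    """Check a candidate against the orientation field.

    A pixel conflicts iff the field is set there and the undirected
    angular difference to the local piece orientation exceeds alpha_tol.
    Conflict fraction strictly below the limit => ACCEPT (and the field is
    marked).  Otherwise: conflicts at the chain endpoints => shorten from
    the conflicting ends inward (discard if the rest falls below l_min);
    conflict-free endpoints => DISCARD.
    """
    conf = _conflicts(f, of, s.alpha_tol)
    frac = conf.mean()
    if frac < s.conflict_fraction_limit:
        _mark_field(f, of)
        return ValidationResult("accept", f)
    if not (conf[0] or conf[-1]):
        return ValidationResult("discard")
    lo, hi = 0, len(conf) - 1
    while lo < hi and conf[lo]:
        lo += 1
    while hi > lo and conf[hi]:
        hi -= 1
    if hi - lo < 1:
        return ValidationResult("discard")
    nf = f.sub_filament(lo, hi)
    if nf.length < s.l_min:
        return ValidationResult("discard")
    return ValidationResult("shorten", nf)


def _mark_field(f: Filament, of: OrientationField) -> None:
    pieces = f.piece_orientations()
    for k in range(len(pieces)):
        lo, hi = f.vertex_idx[k], f.vertex_idx[k + 1]
        pix = stamp_disks(
            of.shape,
            f.chain[lo : hi + 1],
            np.maximum(f.widths[lo : hi + 1], 1).astype(int),
        )
        of.mark(pix, pieces[k])


def trace_filaments(mask: np.ndarray, s: TracerSettings) -> list:
    """Trace curved filaments on a binary mask.

    Seeds run in decreasing width-map diameter order; each uncovered seed
    grows a joined gatherer pair.  Candidates of length >= l_min enter a
    queue ranked by (length, score, first point) and are accepted against
    the orientation field, longest first; accepted filaments claim their
    pixels, shortened ones re-enter the queue at their new length.
    """
    mask = np.asarray(mask, dtype=bool)
    wm = compute_width_map(mask, s.tolerance)
    h, w = wm.shape
    ys, xs = np.nonzero(wm.diameters)
    if len(xs) == 0:
        return []
    order = np.lexsort((xs, ys, -wm.diameters[ys, xs]))
    covered = np.zeros((h, w), dtype=bool)
    candidates = []
    for i in order:
        x, y = int(xs[i]), int(ys[i])
        if covered[y, x]:
            continue
        a, b, _, _ = seed_direction_pair(wm, (x, y), s)
        ga = _grow(wm, (x, y), a, s)
        gb = _grow(wm, (x, y), b, s)
        f = _join(ga, gb)
        if f is None or f.length < s.l_min:
            continue
        candidates.append(f)
        covered |= f.coverage_mask((h, w))

    field = OrientationField((h, w))
    claimed = np.zeros((h, w), dtype=bool)
    accepted = []
    heap = []
    for n, f in enumerate(candidates):
        key = (-f.length, -f.score, int(f.chain[0][1]), int(f.chain[0][0]), n)
        heapq.heappush(heap, (key, f))
    counter = len(candidates)
    while heap:
        _, f = heapq.heappop(heap)
        # claimed pixels cannot be claimed again: a candidate must still
        # contribute at least l_min of unclaimed length (drops re-traces
        # of already-accepted strokes while crossings stay acceptable)
        on_claimed = claimed[f.chain[:, 1], f.chain[:, 0]].mean() if accepted else 0.0
        if f.length * (1.0 - on_claimed) < s.l_min:
            continue
        res = validate_filament(f, field, s)
        if res.kind == "accept":
            pix = f.coverage_mask((h, w))
            f.claimed_mask = pix & ~claimed  # earlier filaments keep their claim
            claimed |= pix
            f.id = len(accepted)
            accepted.append(f)
        elif res.kind == "shorten":
            nf = res.filament
            counter += 1
            key = (-nf.length, -nf.score, int(nf.chain[0][1]), int(nf.chain[0][0]), counter)
            heapq.heappush(heap, (key, nf))
    return accepted
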