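"""Frame-to-frame single-filament tracking via unbalanced optimal transport.

Filaments are cut into short polyline fragments whose weights are their
lengths in pixels.  Fragments of consecutive frames form producers and
consumers of a transportation problem; a dummy element on each side with
cost d_max^2 and the opposite side's total mass absorbs unmatched length,
so that only fragments at most d_max/2 pixels apart and at most d_max
degrees different in orientation can be joined (with the default cost
pre-factors 4 and 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from .geometry import orientation_difference, orientation_of

__all__ = [
    "Segment",
    "TrackingSettings",
    "TransportPlan",
    "DynamicFilament",
    "fragment_filament",
    "base_distance",
    "solve_transport",
    "consolidate",
    "link_filaments",
    "track_stack",
    "tracking_table",
]


@dataclass
class TrackingSettings:
    max_dist: float = 20.0  # mixed pixel/degree unit
    factor_angle: float = 1.0
    factor_length: float = 4.0
    fragment_length: float = 10.0  # pixels
    min_valid: float = 0.3  # MIN_VALID
    min_matched: float = 0.6  # MIN_MATCHED
    min_rel_size: float = 0.25  # MIN_REL_SIZE
    min_abs_size: float = 10.0  # MIN_ABS_SIZE, pixels

    def __post_init__(self):
        if self.max_dist <= 0:
            raise ValueError("max_dist must be positive")
        if self.fragment_length < 2:
            raise ValueError("fragment_length must be >= 2")
        for name in ("min_valid", "min_matched", "min_rel_size"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class Segment:
    filament_id: int
    points: np.ndarray  # (M, 2) float samples at ~1 px spacing
    weight: float  # piece length in pixels
    orientation: float  # degrees in [0, 180)


def _resample(points: np.ndarray, cum: np.ndarray, positions: np.ndarray) -> np.ndarray:
    xs = np.interp(positions, cum, points[:, 0])
    ys = np.interp(positions, cum, points[:, 1])
    return np.stack([xs, ys], axis=1)


def fragment_filament(f, fragment_length: float) -> list:
    """Cut a filament's polyline into consecutive arc-length slices.

    All pieces have length ``fragment_length`` except the last, which
    carries the remainder; a remainder of at most half a fragment is
    merged into the previous piece.  Segment weights sum to the filament
    length exactly.
    """
    if fragment_length < 2:
        raise ValueError("fragment_length must be >= 2")
    pts = np.asarray(f.points, dtype=float)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = float(cum[-1])
    if total <= 0:
        return []
    n_full = int(total // fragment_length)
    rem = total - n_full * fragment_length
    if n_full == 0:
        bounds = [0.0, total]
    elif rem <= fragment_length / 2.0 + 1e-12:
        bounds = [i * fragment_length for i in range(n_full)] + [total]
    else:
        bounds = [i * fragment_length for i in range(n_full + 1)] + [total]
    fid = f.id if getattr(f, "id", None) is not None else -1
    segs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        n_samples = max(int(np.ceil(hi - lo)) + 1, 2)
        sp = _resample(pts, cum, np.linspace(lo, hi, n_samples))
        d = sp[-1] - sp[0]
        if d[0] == 0 and d[1] == 0:
            ori = 0.0
        else:
            ori = orientation_of(d[0], d[1])
        segs.append(Segment(filament_id=fid, points=sp, weight=float(hi - lo), orientation=ori))
    return segs


def base_distance(p: Segment, c: Segment, s: TrackingSettings) -> float:
    """Cost between two segments: factor_length·d_l² + factor_angle·d_ϕ²
    with d_l the closest point-pair distance and d_ϕ the undirected
    orientation difference in degrees."""
    d_l = float(cdist(p.points, c.points).min())
    d_phi = orientation_difference(p.orientation, c.orientation)
    return s.factor_length * d_l**2 + s.factor_angle * d_phi**2


@dataclass
class TransportPlan:
    """Flow matrix over producers+dummy x consumers+dummy.

    The dummy row/column is the last index on each side.
    """

    flows: np.ndarray  # (n+1, m+1)
    cost: np.ndarray  # (n+1, m+1)
    producer_weights: np.ndarray  # (n+1,), dummy last
    consumer_weights: np.ndarray

    @property
    def objective(self) -> float:
        return float(np.sum(self.flows * self.cost))

    def true_flows(self) -> np.ndarray:
        return self.flows[:-1, :-1]


def transport_cost_matrix(producers, consumers, s: TrackingSettings) -> np.ndarray:
    n, m = len(producers), len(consumers)
    cost = np.zeros((n + 1, m + 1))
    for j, p in enumerate(producers):
        for k, c in enumerate(consumers):
            cost[j, k] = base_distance(p, c, s)
    cost[:n, m] = s.max_dist**2
    cost[n, :m] = s.max_dist**2
    cost[n, m] = 0.0
    return cost


def solve_transport(producers, consumers, s: TrackingSettings) -> TransportPlan:
    """Exact LP solution of the dummy-augmented transportation problem.

    True pairs whose base distance exceeds d_max^2 are excluded outright
    (flow forced to zero): rerouting both sides through the dummies costs
    2*d_max^2, so the dummy cost alone would only discourage joins beyond
    twice the intended bound.
    """
    n, m = len(producers), len(consumers)
    wp = np.array([p.weight for p in producers], dtype=float)
    wc = np.array([c.weight for c in consumers], dtype=float)
    if np.any(wp <= 0) or np.any(wc <= 0):
        raise ValueError("all weights must be positive")
    cost = transport_cost_matrix(producers, consumers, s)
    wP = np.concatenate([wp, [wc.sum()]])  # dummy producer absorbs consumers
    wC = np.concatenate([wc, [wp.sum()]])
    R, C = n + 1, m + 1
    # marginal constraints: rows then columns
    a_rows = sparse.kron(sparse.eye(R), np.ones((1, C)))
    a_cols = sparse.kron(np.ones((1, R)), sparse.eye(C))
    A_eq = sparse.vstack([a_rows, a_cols]).tocsr()
    b_eq = np.concatenate([wP, wC])
    limit = s.max_dist**2 + 1e-9
    forbidden = cost > limit
    forbidden[n, :] = False
    forbidden[:, m] = False
    bounds = [
        (0.0, 0.0) if forbidden[j, k] else (0.0, None)
        for j in range(R)
        for k in range(C)
    ]
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    flows = res.x.reshape(R, C)
    return TransportPlan(flows=flows, cost=cost, producer_weights=wP, consumer_weights=wC)


def consolidate(plan: TransportPlan, producers, consumers, n_a: int, n_b: int) -> np.ndarray:
    """Block-sum the segment-level plan into a filament correlation
    matrix M[a, b] (dummy flows excluded)."""
    M = np.zeros((n_a, n_b))
    t = plan.true_flows()
    for j, p in enumerate(producers):
        for k, c in enumerate(consumers):
            if t[j, k] > 0:
                M[p.filament_id, c.filament_id] += t[j, k]
    return M


def link_filaments(M: np.ndarray, lengths_a, lengths_b, s: TrackingSettings) -> dict:
    """Successor lists per filament of frame A.

    Candidates are pre-filtered to length >= MIN_ABS_SIZE and
    >= MIN_REL_SIZE of the current filament; successors accumulate in
    decreasing correlation order until MIN_MATCHED of the filament length
    is covered.  Below MIN_VALID total matched mass the filament is
    solitary (empty list).
    """
    links = {}
    for a in range(M.shape[0]):
        la = lengths_a[a]
        cands = [
            b
            for b in range(M.shape[1])
            if M[a, b] > 0
            and lengths_b[b] >= s.min_abs_size
            and lengths_b[b] >= s.min_rel_size * la
        ]
        cands.sort(key=lambda b: (-M[a, b], b))
        acc, mass = [], 0.0
        for b in cands:
            if mass >= s.min_matched * la:
                break
            acc.append(b)
            mass += M[a, b]
        links[a] = acc if mass >= s.min_valid * la else []
    return links


@dataclass
class DynamicFilament:
    """A filament lifeline: contiguous frame -> per-frame filament index."""

    id: int
    frames: dict = field(default_factory=dict)

    @property
    def birth(self) -> int:
        return min(self.frames)

    @property
    def death(self) -> int:
        return max(self.frames)

    @property
    def persistence(self) -> int:
        return self.death - self.birth + 1


def _pair_links(fil_a, fil_b, s: TrackingSettings):
    """Links and correlation matrix between two consecutive frames."""
    for i, f in enumerate(fil_a):
        f.id = i
    for i, f in enumerate(fil_b):
        f.id = i
    segs_a = [seg for f in fil_a for seg in fragment_filament(f, s.fragment_length)]
    segs_b = [seg for f in fil_b for seg in fragment_filament(f, s.fragment_length)]
    if not segs_a or not segs_b:
        return {a: [] for a in range(len(fil_a))}, np.zeros((len(fil_a), len(fil_b)))
    plan = solve_transport(segs_a, segs_b, s)
    M = consolidate(plan, segs_a, segs_b, len(fil_a), len(fil_b))
    lengths_a = [f.length for f in fil_a]
    lengths_b = [f.length for f in fil_b]
    return link_filaments(M, lengths_a, lengths_b, s), M


def track_stack(
    frames,
    s: TrackingSettings,
    min_persistence: int = 1,
    max_persistence: int | None = None,
) -> list:
    """Chain frame-to-frame links into DynamicFilament lifelines.

    The primary successor of a filament is the first (largest-mass) entry
    of its link list; when two filaments claim the same successor the one
    with the larger correlation wins (ties: smaller id).  Unmatched
    appearances start new lifelines; the persistence filter drops
    lifelines outside [min_persistence, max_persistence].
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    succ_maps = []
    for t in range(len(frames) - 1):
        links, M = _pair_links(frames[t], frames[t + 1], s)
        primary = {a: bs[0] for a, bs in links.items() if bs}
        by_b: dict = {}
        for a, b in primary.items():
            by_b.setdefault(b, []).append(a)
        resolved = {}
        for b, as_ in by_b.items():
            winner = min(as_, key=lambda a: (-M[a, b], a))
            resolved[winner] = b
        succ_maps.append(resolved)

    lifelines = []
    carrier = {}  # filament index in current frame -> lifeline
    for idx in range(len(frames[0])):
        dyn = DynamicFilament(id=len(lifelines), frames={0: idx})
        lifelines.append(dyn)
        carrier[idx] = dyn
    for t in range(1, len(frames)):
        nxt = {}
        succ = succ_maps[t - 1]
        for a, dyn in carrier.items():
            if a in succ:
                b = succ[a]
                dyn.frames[t] = b
                nxt[b] = dyn
        for idx in range(len(frames[t])):
            if idx not in nxt:
                dyn = DynamicFilament(id=len(lifelines), frames={t: idx})
                lifelines.append(dyn)
                nxt[idx] = dyn
        carrier = nxt

    out = []
    for dyn in lifelines:
        p = dyn.persistence
        if p < min_persistence:
            continue
        if max_persistence is not None and p > max_persistence:
            continue
        out.append(dyn)
    return out


def tracking_table(lifelines, frame_records, layout: str = "frame") -> pd.DataFrame:
    """CSV-ready tracking export, bundled by frame or by filament id.

    ``frame_records`` maps frame -> list of FilamentRecord aligned with
    the per-frame filament indices used during tracking.
    """
    rows = []
    for dyn in lifelines:
        for t in sorted(dyn.frames):
            rec = frame_records[t][dyn.frames[t]]
            row = {"lifeline": dyn.id, "frame": t, "birth": dyn.birth,
                   "death": dyn.death, "persistence": dyn.persistence}
            row.update(rec.as_dict())
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if layout == "frame":
        return df.sort_values(["frame", "lifeline"], kind="stable").reset_index(drop=True)
    if layout == "id":
        return df.sort_values(["lifeline", "frame"], kind="stable").reset_index(drop=True)
    raise ValueError("layout must be 'frame' or 'id'")
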