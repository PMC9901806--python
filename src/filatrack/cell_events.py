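"""Bounding-box area tracking and cell-event detection over a stack.

Connected foreground areas of consecutive frames are scored by the
fraction of their intersection over the smaller area (bounding boxes act
only as a search pre-filter).  Predecessor counting classifies Start,
Alive, Split and Fusion events into lifelines; a post-processing pass
rewrites Fusion followed by Split on the same lifeline into Touch /
DeTouch and reconnects the original lifelines across the contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "AreaRegion",
    "MatchingMap",
    "CellEvent",
    "DynamicArea",
    "detect_areas",
    "matching_score",
    "build_matching_map",
    "classify_events",
    "postprocess_lifelines",
    "events_table",
    "lifelines_table",
]

_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class AreaRegion:
    frame: int
    index: int  # index within its frame
    pixels: frozenset  # {(x, y), ...}
    bbox: tuple  # (x0, y0, x1, y1) inclusive
    area: int
    centroid: tuple

    @classmethod
    def from_pixels(cls, frame: int, index: int, xs, ys) -> "AreaRegion":
        pix = frozenset(zip(map(int, xs), map(int, ys)))
        return cls(
            frame=frame,
            index=index,
            pixels=pix,
            bbox=(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())),
            area=len(pix),
            centroid=(float(np.mean(xs)), float(np.mean(ys))),
        )


def detect_areas(mask: np.ndarray, min_area: int = 1, frame: int = 0) -> list:
    """8-connected components with area >= min_area, each with its tight
    axis-aligned bounding box."""
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    regions = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(lab == i)
        if len(xs) < min_area:
            continue
        regions.append(AreaRegion.from_pixels(frame, len(regions), xs, ys))
    return regions


def _boxes_intersect(a: AreaRegion, b: AreaRegion) -> bool:
    ax0, ay0, ax1, ay1 = a.bbox
    bx0, by0, bx1, by1 = b.bbox
    return ax0 <= bx1 and bx0 <= ax1 and ay0 <= by1 and by0 <= ay1


def matching_score(a: AreaRegion, b: AreaRegion) -> float:
    """|a ∩ b| / min(|a|, |b|), capped at 1."""
    inter = len(a.pixels & b.pixels)
    return min(inter / min(a.area, b.area), 1.0)


@dataclass
class MatchingMap:
    """Scores of box-intersecting area pairs of consecutive frames."""

    scores: dict = field(default_factory=dict)  # (frame_i, ia, ib) -> score

    def predecessors(self, frame: int, ib: int, tol: float) -> list:
        """(index, score) of frame-1 areas scoring strictly above tol."""
        out = [
            (ia, sc)
            for (fi, ia, b), sc in self.scores.items()
            if fi == frame - 1 and b == ib and sc > tol
        ]
        return sorted(out)

    def successors(self, frame: int, ia: int, tol: float) -> list:
        out = [
            (ib, sc)
            for (fi, a, ib), sc in self.scores.items()
            if fi == frame and a == ia and sc > tol
        ]
        return sorted(out)


def build_matching_map(frames_areas) -> MatchingMap:
    """Score every box-intersecting pair of consecutive frames."""
    if len(frames_areas) < 2:
        raise ValueError("need at least 2 frames")
    mm = MatchingMap()
    for i in range(len(frames_areas) - 1):
        for a in frames_areas[i]:
            for b in frames_areas[i + 1]:
                if _boxes_intersect(a, b):
                    mm.scores[(i, a.index, b.index)] = matching_score(a, b)
    return mm


@dataclass
class CellEvent:
    kind: str  # start | alive | split | fusion | touch | detouch | end
    frame: int
    lifelines: list  # participating lifeline ids

    def __post_init__(self):
        if self.kind in ("split", "fusion") and len(self.lifelines) < 2:
            raise ValueError(f"{self.kind} event needs >= 2 lifelines")


@dataclass
class DynamicArea:
    id: int
    frames: dict = field(default_factory=dict)  # frame -> area index
    closed_by: str | None = None  # 'split' | 'fusion' if interrupted

    @property
    def birth(self) -> int:
        return min(self.frames)

    @property
    def death(self) -> int:
        return max(self.frames)

    @property
    def lifespan(self) -> int:
        return self.death - self.birth + 1


def classify_events(frames_areas, mmap: MatchingMap, intersect_tolerance: float = 0.2):
    """Group areas by predecessor count into lifelines and events.

    No predecessor above tolerance: Start.  Exactly one predecessor whose
    lifeline has a single successor: Alive (lifeline extended).  One
    predecessor with several successors: Split (predecessor closed, each
    child a new lifeline).  Several predecessors: Fusion (predecessors
    closed, fused area opens a new lifeline).
    """
    if not (0.0 <= intersect_tolerance < 1.0):
        raise ValueError("intersect_tolerance must be in [0, 1)")
    lifelines: list[DynamicArea] = []
    events: list[CellEvent] = []

    def open_lifeline(frame, aidx) -> DynamicArea:
        dyn = DynamicArea(id=len(lifelines), frames={frame: aidx})
        lifelines.append(dyn)
        return dyn

    owner = {}
    for a in frames_areas[0]:
        dyn = open_lifeline(0, a.index)
        events.append(CellEvent("start", 0, [dyn.id]))
        owner[a.index] = dyn
    for i in range(1, len(frames_areas)):
        preds = {
            b.index: mmap.predecessors(i, b.index, intersect_tolerance)
            for b in frames_areas[i]
        }
        succ_count = {}
        for b, ps in preds.items():
            for ia, _ in ps:
                succ_count[ia] = succ_count.get(ia, 0) + 1
        split_children: dict = {}
        nxt = {}
        for b in sorted(preds):
            ps = preds[b]
            if len(ps) == 0:
                dyn = open_lifeline(i, b)
                events.append(CellEvent("start", i, [dyn.id]))
            elif len(ps) > 1:
                plids = [owner[ia].id for ia, _ in ps]
                for ia, _ in ps:
                    owner[ia].closed_by = "fusion"
                dyn = open_lifeline(i, b)
                events.append(CellEvent("fusion", i, sorted(set(plids)) + [dyn.id]))
            else:
                ia = ps[0][0]
                if succ_count.get(ia, 0) > 1:
                    owner[ia].closed_by = "split"
                    dyn = open_lifeline(i, b)
                    split_children.setdefault(ia, []).append(dyn.id)
                else:
                    dyn = owner[ia]
                    dyn.frames[i] = b
                    events.append(CellEvent("alive", i, [dyn.id]))
            nxt[b] = dyn
        for ia in sorted(split_children):
            events.append(CellEvent("split", i, [owner[ia].id] + split_children[ia]))
        owner = nxt
    return lifelines, events


def _score_regions(ra: AreaRegion, rb: AreaRegion) -> float:
    return matching_score(ra, rb)


def postprocess_lifelines(lifelines, events, frames_areas):
    """Rewrite Fusion-then-Split into Touch/DeTouch, reconnect lifelines,
    and finalize end events.

    A fused lifeline later interrupted by a Split is treated as cells in
    contact: the fusion becomes a Touch, the split a DeTouch, the merged
    frames are carried by the predecessor with the best matching score to
    the merged area, and each post-split lifeline is appended to the
    predecessor it matches best, so touching does not interrupt lifelines.
    Afterwards every lifeline without a successor gets an End event.
    """
    by_id = {ll.id: ll for ll in lifelines}
    alias: dict[int, int] = {}

    def resolve(lid: int) -> int:
        while lid in alias:
            lid = alias[lid]
        return lid

    def region(frame: int, aidx: int) -> AreaRegion:
        return frames_areas[frame][aidx]

    events = list(events)
    for ev in [e for e in events if e.kind == "fusion"]:
        fused_id = resolve(ev.lifelines[-1])
        fused = by_id[fused_id]
        split_ev = next(
            (
                e
                for e in events
                if e.kind == "split" and resolve(e.lifelines[0]) == fused_id
            ),
            None,
        )
        if split_ev is None:
            continue  # end-of-stack merge (or never separates): fusion stands
        pred_ids = [resolve(l) for l in ev.lifelines[:-1]]
        child_ids = [resolve(l) for l in split_ev.lifelines[1:]]
        k = ev.frame
        m = split_ev.frame
        merged_first = region(k, fused.frames[k])

        def last_region(lid):
            ll = by_id[lid]
            fr = max(f for f in ll.frames if f < k)
            return region(fr, ll.frames[fr])

        # best-matching predecessor absorbs the merged frames
        best_pred = max(
            pred_ids,
            key=lambda lid: (
                _score_regions(last_region(lid), merged_first),
                last_region(lid).area,
                -lid,
            ),
        )
        for fr, aidx in fused.frames.items():
            by_id[best_pred].frames[fr] = aidx
        alias[fused_id] = best_pred
        # reconnect post-split lifelines to predecessors by best score
        pairs = []
        for lid in pred_ids:
            for cid in child_ids:
                child = by_id[cid]
                child_first = region(m, child.frames[m])
                sc = _score_regions(last_region(lid), child_first)
                pairs.append((sc, last_region(lid).area, -lid, lid, cid))
        pairs.sort(key=lambda t: (-t[0], -t[1], t[2], t[4]))
        used_p, used_c = set(), set()
        for sc, _, _, lid, cid in pairs:
            if lid in used_p or cid in used_c:
                continue
            used_p.add(lid)
            used_c.add(cid)
            child = by_id[cid]
            for fr, aidx in child.frames.items():
                by_id[lid].frames[fr] = aidx
            alias[cid] = lid
            by_id[lid].closed_by = child.closed_by
        ev.kind = "touch"
        ev.lifelines = sorted(set(pred_ids))
        split_ev.kind = "detouch"
        split_ev.lifelines = sorted(set(resolve(c) for c in child_ids))

    # apply aliases and drop absorbed lifelines
    final_events = []
    for e in events:
        lids = sorted(set(resolve(l) for l in e.lifelines))
        final_events.append(CellEvent(e.kind, e.frame, lids))
    final_lifelines = [ll for ll in lifelines if ll.id not in alias]

    # successors: lifelines still closed by a surviving fusion or split
    has_successor = set()
    for e in final_events:
        if e.kind == "fusion":
            has_successor.update(e.lifelines[:-1])
        elif e.kind == "split":
            has_successor.add(e.lifelines[0])
    for ll in final_lifelines:
        if ll.id not in has_successor:
            final_events.append(CellEvent("end", ll.death, [ll.id]))
    final_events.sort(key=lambda e: (e.frame, e.kind, e.lifelines))
    return final_lifelines, final_events


def events_table(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"kind": e.kind, "frame": e.frame, "lifelines": ";".join(map(str, e.lifelines))}
            for e in events
        ],
        columns=["kind", "frame", "lifelines"],
    )


def lifelines_table(lifelines) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lifeline": ll.id,
                "birth": ll.birth,
                "death": ll.death,
                "lifespan": ll.lifespan,
            }
            for ll in lifelines
        ],
        columns=["lifeline", "birth", "death", "lifespan"],
    )
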