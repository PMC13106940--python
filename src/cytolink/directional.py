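"""Directional heuristic tracker: bounded-radius linking plus forward
(mitosis) and backward (fusion) event detection.

Linking solves, frame by frame, a minimum-total-cost bipartite assignment
between open tracks and the next frame's detections; links farther than
``search_range`` are forbidden, and a track unmatched for more than
``memory`` frames is closed (a later object then starts a new track).  The
linking cost is the Euclidean distance in a feature space of (row, col)
plus optionally weighted morphological descriptors; the default puts all
weight on position.

Event detection inspects track endpoints.  A candidate parent P with
daughters D1, D2 (for fusion, the "parent" is the merged cell and the
"children" the source cells) is accepted iff all three criteria hold:

* distance:   ||pos_Di - pos_P|| < alpha_dist * diameter_P   for i = 1, 2
* area:       beta_min < (A_D1 + A_D2) / A_P < beta_max
* similarity: min(A_D1, A_D2) / max(A_D1, A_D2) > gamma_sim
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .ctc_io import Detection, Lineage, Track

__all__ = [
    "LinkParams",
    "EventThresholds",
    "Event",
    "link_detections",
    "validate_event",
    "detect_events",
    "assemble_lineage",
]

_FEATURES = (
    "area",
    "equivalent_diameter",
    "perimeter",
    "eccentricity",
    "solidity",
    "orient_sin2",
    "orient_cos2",
)
_FORBIDDEN = 1e12


@dataclass(frozen=True)
class LinkParams:
    search_range: float = 50.0
    memory: int = 0
    feature_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.search_range <= 0:
            raise ValueError("search_range must be positive")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        for name in self.feature_weights:
            if name not in _FEATURES:
                raise ValueError(f"unknown feature {name!r}")


@dataclass(frozen=True)
class EventThresholds:
    alpha_dist: float = 1.5
    beta_min: float = 0.8
    beta_max: float = 1.2
    gamma_sim: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha_dist <= 0:
            raise ValueError("alpha_dist must be positive")
        if not 0 < self.beta_min < self.beta_max:
            raise ValueError("need 0 < beta_min < beta_max")
        if not 0 < self.gamma_sim < 1:
            raise ValueError("gamma_sim must lie in (0, 1)")


@dataclass(frozen=True)
class Event:
    """A detected split or merge on the raw track list.

    ``frame`` is the last frame of the ending side.  A raw track produced by
    one-to-one linking usually follows the parent *into* one daughter (or a
    source into the merged cell); when that happens the anchor track's own
    index appears on the child (mitosis) or parent (fusion) side, meaning
    the track must be cut at ``frame`` during lineage assembly.
    """

    kind: str  # "mitosis" | "fusion"
    frame: int
    parent_tracks: tuple[int, ...]  # indices into the raw track list
    child_tracks: tuple[int, ...]


def _link_cost(track_last: Detection, det: Detection, params: LinkParams) -> float:
    spatial2 = (track_last.centroid[0] - det.centroid[0]) ** 2 + (
        track_last.centroid[1] - det.centroid[1]
    ) ** 2
    if math.sqrt(spatial2) > params.search_range:
        return _FORBIDDEN
    extra = 0.0
    for name, w in params.feature_weights.items():
        if w:
            extra += w * (getattr(track_last, name) - getattr(det, name)) ** 2
    return math.sqrt(spatial2 + extra)


def link_detections(
    detections: list[list[Detection]], params: LinkParams | None = None
) -> list[list[Detection]]:
    """Assemble raw tracks from per-frame detection lists.

    Returns tracks as detection lists ordered by frame; every detection
    belongs to exactly one track.
    """
    params = params or LinkParams()
    tracks: list[list[Detection]] = []
    open_tracks: list[int] = []  # indices into `tracks`
    last_seen: dict[int, int] = {}

    for t, dets in enumerate(detections):
        if open_tracks and dets:
            cost = np.array(
                [
                    [_link_cost(tracks[ti][-1], d, params) for d in dets]
                    for ti in open_tracks
                ]
            )
            rows, cols = linear_sum_assignment(cost)
            matched_tracks: set[int] = set()
            matched_dets: set[int] = set()
            for r, c in zip(rows, cols):
                if cost[r, c] < _FORBIDDEN / 2:
                    ti = open_tracks[r]
                    tracks[ti].append(dets[c])
                    last_seen[ti] = t
                    matched_tracks.add(ti)
                    matched_dets.add(c)
        else:
            matched_dets = set()

        for c, d in enumerate(dets):
            if c not in matched_dets:
                tracks.append([d])
                last_seen[len(tracks) - 1] = t

        open_tracks = [
            ti for ti, seen in sorted(last_seen.items()) if t - seen <= params.memory
        ]
    return tracks


def validate_event(
    parent: Detection,
    child1: Detection,
    child2: Detection,
    thresholds: EventThresholds | None = None,
) -> bool:
    """Apply the three event criteria (direction-agnostic)."""
    th = thresholds or EventThresholds()
    if parent.area <= 0:
        raise ValueError("parent area must be positive")
    limit = th.alpha_dist * parent.equivalent_diameter
    if parent.distance_to(child1) >= limit or parent.distance_to(child2) >= limit:
        return False
    ratio = (child1.area + child2.area) / parent.area
    if not (th.beta_min < ratio < th.beta_max):
        return False
    lo, hi = sorted((child1.area, child2.area))
    return lo / hi > th.gamma_sim


def _det_at(track: list[Detection], frame: int) -> Detection | None:
    for d in track:
        if d.frame == frame:
            return d
    return None


def detect_events(
    tracks: list[list[Detection]],
    direction: str,
    thresholds: EventThresholds | None = None,
) -> list[Event]:
    """Detect mitosis (forward) or fusion (backward) events.

    Forward mode anchors on a candidate parent present at frame t: either a
    track that ends at t (both daughters are then tracks starting at t+1) or
    a track that continues into t+1 — one-to-one linking follows the parent
    into one daughter, so the continuation itself is the first daughter and
    a newly starting track the second; the anchor is later cut at t.
    Backward mode is the mirror: the merged cell at t+1 is anchored and the
    sources are tracks ending at t (or the anchor's own pre-segment).

    Each newly starting (forward) / ending (backward) track is consumed by
    at most one event; among valid candidate pairs the lowest combined
    centroid distance wins, ties broken by the lowest label pair.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    th = thresholds or EventThresholds()

    ends: dict[int, list[int]] = {}
    starts: dict[int, list[int]] = {}
    for ti, tr in enumerate(tracks):
        ends.setdefault(tr[-1].frame, []).append(ti)
        starts.setdefault(tr[0].frame, []).append(ti)
    all_frames = sorted({d.frame for tr in tracks for d in tr})

    events: list[Event] = []
    consumed_new: set[int] = set()  # new/ending tracks used as event children
    anchor_used: set[tuple[int, int]] = set()  # (track, frame) splits taken

    for t in all_frames:
        if direction == "forward":
            fresh = [ti for ti in starts.get(t + 1, []) if ti not in consumed_new]
        else:
            fresh = [ti for ti in ends.get(t, []) if ti not in consumed_new]
        if not fresh:
            continue
        # pure endpoint anchors first, then continuing (split) anchors
        if direction == "forward":
            pure = [ti for ti in ends.get(t, []) if ti not in consumed_new]
            spanning = [
                ti
                for ti, tr in enumerate(tracks)
                if _det_at(tr, t) is not None
                and _det_at(tr, t + 1) is not None
                and (ti, t) not in anchor_used
            ]
        else:
            pure = [ti for ti in starts.get(t + 1, []) if ti not in consumed_new]
            spanning = [
                ti
                for ti, tr in enumerate(tracks)
                if _det_at(tr, t) is not None
                and _det_at(tr, t + 1) is not None
                and (ti, t) not in anchor_used
            ]
        for anchor, is_split in [(ti, False) for ti in sorted(pure)] + [
            (ti, True) for ti in sorted(spanning)
        ]:
            if anchor in consumed_new or (is_split and (anchor, t) in anchor_used):
                continue
            if direction == "forward":
                pivot = _det_at(tracks[anchor], t)
            else:
                pivot = _det_at(tracks[anchor], t + 1)
            if pivot is None:
                continue
            # candidate partners: fresh tracks, plus the anchor's own
            # continuation when the anchor spans the boundary
            cont_det = None
            if is_split:
                cont_det = (
                    _det_at(tracks[anchor], t + 1)
                    if direction == "forward"
                    else _det_at(tracks[anchor], t)
                )
            best = None
            available = [ti for ti in fresh if ti not in consumed_new and ti != anchor]
            if is_split and cont_det is not None:
                pairs = [(anchor, ti) for ti in available]
            else:
                pairs = [
                    (available[i], available[j])
                    for i in range(len(available))
                    for j in range(i + 1, len(available))
                ]
            for c1, c2 in pairs:
                d1 = (
                    cont_det
                    if c1 == anchor
                    else (
                        tracks[c1][0] if direction == "forward" else tracks[c1][-1]
                    )
                )
                d2 = tracks[c2][0] if direction == "forward" else tracks[c2][-1]
                if d1 is None:
                    continue
                if not validate_event(pivot, d1, d2, th):
                    continue
                key = (
                    pivot.distance_to(d1) + pivot.distance_to(d2),
                    min(d1.label, d2.label),
                    max(d1.label, d2.label),
                )
                if best is None or key < best[0]:
                    best = (key, c1, c2)
            if best is not None:
                _, c1, c2 = best
                for c in (c1, c2):
                    if c != anchor:
                        consumed_new.add(c)
                if is_split:
                    anchor_used.add((anchor, t))
                else:
                    consumed_new.add(anchor)
                if direction == "forward":
                    events.append(
                        Event("mitosis", t, (anchor,), tuple(sorted((c1, c2))))
                    )
                else:
                    events.append(
                        Event("fusion", t, tuple(sorted((c1, c2))), (anchor,))
                    )
    return events


def assemble_lineage(
    tracks: list[list[Detection]], events: list[Event]
) -> Lineage:
    """Cut raw tracks at event boundaries, install parent/child links and
    number the resulting tracks.

    A raw track whose own index appears on the child side of a mitosis (or
    the parent side of a fusion) is cut after the event frame; the leading
    piece is the parent (or source) and the trailing piece the daughter (or
    merged cell).  Track ids are assigned 1..N in order of (first frame,
    first label), so a parent's id always precedes its children's.
    """
    for ev in events:
        if ev.kind not in ("mitosis", "fusion"):
            raise ValueError(f"unknown event kind {ev.kind!r}")

    cuts: dict[int, set[int]] = {ti: set() for ti in range(len(tracks))}
    for ev in events:
        if ev.kind == "mitosis":
            (p,) = ev.parent_tracks
            if p in ev.child_tracks:
                cuts[p].add(ev.frame)
        else:
            (c,) = ev.child_tracks
            if c in ev.parent_tracks:
                cuts[c].add(ev.frame)

    # split raw tracks into segments at the cut frames
    segments: list[tuple[int, tuple[Detection, ...]]] = []
    seg_of: dict[tuple[int, int], int] = {}  # (raw index, frame) -> segment
    for ti, dets in enumerate(tracks):
        current: list[Detection] = []
        for d in dets:
            current.append(d)
            if d.frame in cuts[ti]:
                segments.append((ti, tuple(current)))
                current = []
        if current:
            segments.append((ti, tuple(current)))
    for si, (_ti, dets) in enumerate(segments):
        for d in dets:
            seg_of[(_ti, d.frame)] = si

    def segment_at(ti: int, frame: int) -> int:
        key = (ti, frame)
        if key not in seg_of:
            raise ValueError(
                f"event references frame {frame} outside track {ti}"
            )
        return seg_of[key]

    parents_of: dict[int, tuple[int, ...]] = {}
    used_out: set[int] = set()
    for ev in events:
        if ev.kind == "mitosis":
            (p,) = ev.parent_tracks
            parent_seg = segment_at(p, ev.frame)
            child_segs = []
            for c in ev.child_tracks:
                frame = ev.frame + 1 if c == p else tracks[c][0].frame
                child_segs.append(segment_at(c, frame))
            if parent_seg in used_out:
                raise ValueError(f"conflicting events at end of track {p}")
            used_out.add(parent_seg)
            for cs in child_segs:
                if cs in parents_of:
                    raise ValueError("conflicting events at a track start")
                parents_of[cs] = (parent_seg,)
        else:
            (c,) = ev.child_tracks
            merged_seg = segment_at(c, ev.frame + 1)
            source_segs = []
            for p in ev.parent_tracks:
                frame = ev.frame if p == c else tracks[p][-1].frame
                source_segs.append(segment_at(p, frame))
            for ss in source_segs:
                if ss in used_out:
                    raise ValueError("conflicting events at a track end")
                used_out.add(ss)
            if merged_seg in parents_of:
                raise ValueError("conflicting events at a track start")
            parents_of[merged_seg] = tuple(source_segs)

    order = sorted(
        range(len(segments)),
        key=lambda si: (segments[si][1][0].frame, segments[si][1][0].label),
    )
    seg_id = {si: i + 1 for i, si in enumerate(order)}

    out: dict[int, Track] = {}
    for si, (_ti, dets) in enumerate(segments):
        tid = seg_id[si]
        parent_ids = tuple(sorted(seg_id[ps] for ps in parents_of.get(si, ())))
        out[tid] = Track(
            track_id=tid,
            frame_begin=dets[0].frame,
            frame_end=dets[-1].frame,
            parents=parent_ids,
            detections=dets,
        )
    return Lineage(tracks=out)
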