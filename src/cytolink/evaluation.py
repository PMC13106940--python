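"""AOGM-based tracking accuracy (TRA) for CTC-layout lineage graphs.

TRA compares the acyclic directed graph of a tracking result with the
reference graph: nodes are segmented markers per frame, edges connect a
marker to its successor in the same track or to the first marker of a child
track.  A reference marker is matched to the result marker covering more
than half of its pixels.  The score is

    TRA = 1 - min(AOGM, AOGM_0) / AOGM_0

where AOGM is the weighted sum of graph operations needed to turn the
result graph into the reference graph and AOGM_0 the cost of building the
reference from scratch.  Standard operation weights are used: node split
5, false negative 10, false positive 1, redundant edge 1, missing edge 1.5,
wrong edge semantics 1.

Fusion products carry two parent edges when the two-parent sidecar
information is available on both sides, so a correctly recovered fusion
contributes no penalty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ctc_io import (
    LabelStack,
    Lineage,
    read_ctc_tracks,
    read_label_stack,
    lineage_from_records,
)

__all__ = ["AOGMBreakdown", "tra_score", "tra_score_from_dirs", "build_graph"]

W_NS, W_FN, W_FP, W_ED, W_EA, W_EC = 5.0, 10.0, 1.0, 1.0, 1.5, 1.0


@dataclass(frozen=True)
class AOGMBreakdown:
    false_negatives: int
    node_splits: int
    false_positives: int
    redundant_edges: int
    missing_edges: int
    wrong_semantics: int

    @property
    def aogm(self) -> float:
        return (
            W_FN * self.false_negatives
            + W_NS * self.node_splits
            + W_FP * self.false_positives
            + W_ED * self.redundant_edges
            + W_EA * self.missing_edges
            + W_EC * self.wrong_semantics
        )


def build_graph(
    lineage: Lineage, stack: LabelStack
) -> tuple[set[tuple[int, int]], dict[tuple[tuple[int, int], tuple[int, int]], str]]:
    """Nodes (frame, label) and typed edges ('track' or 'parent') of a
    lineage over its mask stack.  Mask pixel values are assumed to equal
    track ids (the CTC result/GT convention)."""
    present: list[set[int]] = [
        set(np.unique(frame)) - {0} for frame in stack.frames
    ]
    nodes: set[tuple[int, int]] = set()
    edges: dict[tuple[tuple[int, int], tuple[int, int]], str] = {}
    for tid, tr in lineage.tracks.items():
        marker_frames = [
            t for t in range(tr.frame_begin, tr.frame_end + 1) if tid in present[t]
        ]
        for t in marker_frames:
            nodes.add((t, tid))
        for a, b in zip(marker_frames, marker_frames[1:]):
            edges[((a, tid), (b, tid))] = "track"
    for tid, tr in lineage.tracks.items():
        for p in tr.parents:
            ptr = lineage.tracks[p]
            u, v = (ptr.frame_end, p), (tr.frame_begin, tid)
            if u in nodes and v in nodes:
                edges[(u, v)] = "parent"
    return nodes, edges


def _match_markers(
    gt_stack: LabelStack, res_stack: LabelStack
) -> tuple[dict[tuple[int, int], tuple[int, int]], dict[tuple[int, int], int]]:
    """Per-frame marker matching: gt node -> res node iff the result marker
    covers > 50% of the reference marker's pixels.  Also returns, per result
    node, the number of reference markers matched to it."""
    match: dict[tuple[int, int], tuple[int, int]] = {}
    res_load: dict[tuple[int, int], int] = {}
    for t, (g, r) in enumerate(zip(gt_stack.frames, res_stack.frames)):
        g = g.ravel()
        r = r.ravel()
        sel = g > 0
        if not sel.any():
            continue
        pairs = np.stack([g[sel], r[sel]], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        gt_sizes: dict[int, int] = {}
        for (gl, _rl), c in zip(uniq, counts):
            gt_sizes[int(gl)] = gt_sizes.get(int(gl), 0) + int(c)
        for (gl, rl), c in zip(uniq, counts):
            gl, rl = int(gl), int(rl)
            if rl > 0 and c > 0.5 * gt_sizes[gl]:
                match[(t, gl)] = (t, rl)
                res_load[(t, rl)] = res_load.get((t, rl), 0) + 1
    return match, res_load


def tra_breakdown(
    gt_lineage: Lineage,
    gt_stack: LabelStack,
    res_lineage: Lineage,
    res_stack: LabelStack,
) -> AOGMBreakdown:
    if gt_stack.n_frames != res_stack.n_frames:
        raise ValueError("stacks cover different frame counts")
    gt_nodes, gt_edges = build_graph(gt_lineage, gt_stack)
    res_nodes, res_edges = build_graph(res_lineage, res_stack)
    match, res_load = _match_markers(gt_stack, res_stack)

    fn = sum(1 for u in gt_nodes if u not in match)
    fp = sum(1 for v in res_nodes if v not in res_load)
    ns = sum(load - 1 for load in res_load.values() if load > 1)

    missing = wrong = 0
    images: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for (u, v), semantics in gt_edges.items():
        mu, mv = match.get(u), match.get(v)
        if mu is None or mv is None or mu == mv:
            missing += 1
            continue
        if (mu, mv) in res_edges:
            images.add((mu, mv))
            if res_edges[(mu, mv)] != semantics:
                wrong += 1
        else:
            missing += 1
    redundant = sum(1 for e in res_edges if e not in images)

    return AOGMBreakdown(
        false_negatives=fn,
        node_splits=ns,
        false_positives=fp,
        redundant_edges=redundant,
        missing_edges=missing,
        wrong_semantics=wrong,
    )


def tra_score(
    gt_lineage: Lineage,
    gt_stack: LabelStack,
    res_lineage: Lineage,
    res_stack: LabelStack,
) -> float:
    b = tra_breakdown(gt_lineage, gt_stack, res_lineage, res_stack)
    gt_nodes, gt_edges = build_graph(gt_lineage, gt_stack)
    aogm0 = W_FN * len(gt_nodes) + W_EA * len(gt_edges)
    if aogm0 == 0:
        raise ValueError("empty reference graph")
    return 1.0 - min(b.aogm, aogm0) / aogm0


def tra_score_from_dirs(gt_directory: str | Path, res_directory: str | Path) -> float:
    """Score a CTC result directory against a CTC GT directory.

    The GT directory may be the sequence folder containing ``TRA/`` or the
    ``TRA`` folder itself; the result directory holds ``res_track.txt`` plus
    relabeled masks.
    """
    gt_dir = Path(gt_directory)
    if (gt_dir / "TRA").is_dir():
        gt_dir = gt_dir / "TRA"
    res_dir = Path(res_directory)
    gt_lineage = lineage_from_records(read_ctc_tracks(gt_dir / "man_track.txt"))
    res_lineage = lineage_from_records(read_ctc_tracks(res_dir / "res_track.txt"))
    return tra_score(
        gt_lineage,
        read_label_stack(gt_dir),
        res_lineage,
        read_label_stack(res_dir),
    )
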