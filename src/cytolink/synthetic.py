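"""Synthetic time-lapse benchmark generator with scheduled mitoses and fusions.

Cells are rendered as non-overlapping filled disks on a dark background and
move as a bounded random walk: a fixed base velocity along a persistent
per-cell heading plus isotropic Gaussian perturbations, reflected at the
field boundary.  Divisions are scheduled by sampling each parent's lifespan
from a configurable interval; each division replaces the parent disk with
two daughters of half the area placed antipodally about the parent centroid,
so that midpoint alignment, area conservation and daughter similarity hold
by construction.  Fusion pairs are pre-designated and steered toward each
other so that the merge triggers when their centroid distance falls below
the proximity threshold; the merged disk carries the summed area.

The generator emits the label stack (pixel value = ground-truth track id), a
CTC-compliant ground-truth lineage and an event log.  Because every event is
scheduled, the ground truth satisfies an exact conservation law:

    total tracks = n_initial_cells + 2 * n_mitosis + n_fusion

and cells never enter or leave the field (no appearance/disappearance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as _disk

from .ctc_io import (
    LabelStack,
    Lineage,
    Track,
    records_from_lineage,
    write_lineage_sidecar,
    write_mask_stack,
    write_track_file,
)

__all__ = ["SynthConfig", "SynthResult", "generate_sequence", "write_ground_truth"]

_SEPARATION = 1.0  # extra clearance (px) between disk rims
_NOISE_CLIP = 3.0  # Gaussian step clipped at this many sigma


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic sequence.

    Defaults reproduce the benchmark construction used throughout this
    package: a 1024x1024 px field, 12 px cell radius, 3 px/frame base speed
    with 1 px/frame Gaussian perturbation, and division lifespans of 40-120
    frames (2-3 generations within a 200-frame sequence).
    """

    n_initial_cells: int = 16
    n_frames: int = 200
    n_mitosis: int = 0
    n_fusion: int = 0
    field_size: tuple[int, int] = (1024, 1024)
    cell_radius: float = 12.0
    base_speed: float = 3.0
    noise_sigma: float = 1.0
    lifespan_interval: tuple[int, int] = (40, 120)
    fusion_proximity: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_initial_cells < 1:
            raise ValueError("n_initial_cells must be >= 1")
        if self.cell_radius < 1:
            raise ValueError("cell_radius must be >= 1")
        if self.lifespan_interval[0] < 1:
            raise ValueError("lifespan minimum must be >= 1")
        if self.lifespan_interval[0] > self.lifespan_interval[1]:
            raise ValueError("lifespan interval reversed")
        if self.n_mitosis < 0 or self.n_fusion < 0:
            raise ValueError("event counts must be non-negative")
        if (self.n_mitosis or self.n_fusion) and self.n_frames < 4:
            raise ValueError("scheduled events need n_frames >= 4")
        if self.n_initial_cells < 2 * self.n_fusion:
            raise ValueError(
                "each fusion consumes two designated initial cells; need "
                "n_initial_cells >= 2 * n_fusion"
            )
        if self.base_speed < 0 or self.noise_sigma < 0:
            raise ValueError("speeds must be non-negative")


@dataclass
class SynthResult:
    stack: LabelStack
    gt_lineage: Lineage
    event_log: list[tuple[int, str, tuple[int, ...]]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# lineage planning (topology + event times; no geometry)


@dataclass
class _Plan:
    birth: dict[int, int]
    end: dict[int, int]
    parents: dict[int, tuple[int, ...]]
    mitoses: list[tuple[int, int, int, int]]  # (frame, parent, d1, d2)
    fusions: list[tuple[int, int, int, int]]  # (frame, p1, p2, child)


def _plan_lineage(cfg: SynthConfig, rng: np.random.Generator) -> _Plan:
    birth: dict[int, int] = {}
    end: dict[int, int] = {}
    parents: dict[int, tuple[int, ...]] = {}
    next_id = 1
    for _ in range(cfg.n_initial_cells):
        birth[next_id], end[next_id], parents[next_id] = 0, cfg.n_frames - 1, ()
        next_id += 1

    lo, hi = cfg.lifespan_interval
    consumed: set[int] = set()  # tracks that end in a scheduled event

    # fusions first: each consumes a designated pair of initial cells, which
    # the simulator places within closing range and steers together
    fusions: list[tuple[int, int, int, int]] = []
    free_initial = list(range(1, cfg.n_initial_cells + 1))
    for _ in range(cfg.n_fusion):
        f = int(rng.integers(2, cfg.n_frames - 1))
        i, j = rng.choice(len(free_initial), size=2, replace=False)
        p1, p2 = sorted((free_initial[int(i)], free_initial[int(j)]))
        free_initial = [t for t in free_initial if t not in (p1, p2)]
        end[p1] = end[p2] = f
        consumed.update((p1, p2))
        child = next_id
        birth[child], end[child], parents[child] = f + 1, cfg.n_frames - 1, (p1, p2)
        next_id += 1
        fusions.append((f, p1, p2, child))

    mitoses: list[tuple[int, int, int, int]] = []
    for _ in range(cfg.n_mitosis):
        eligible = sorted(
            t for t in birth if t not in consumed and birth[t] <= cfg.n_frames - 3
        )
        if not eligible:
            raise ValueError("mitosis schedule infeasible for this configuration")
        parent = eligible[int(rng.integers(len(eligible)))]
        d = birth[parent] + int(rng.integers(lo, hi + 1))
        d = min(max(d, birth[parent] + 1, 2), cfg.n_frames - 2)
        end[parent] = d
        consumed.add(parent)
        daughters = (next_id, next_id + 1)
        for dt in daughters:
            birth[dt], end[dt], parents[dt] = d + 1, cfg.n_frames - 1, (parent,)
        next_id += 2
        mitoses.append((d, parent, *daughters))

    return _Plan(birth=birth, end=end, parents=parents, mitoses=mitoses, fusions=fusions)


# ---------------------------------------------------------------------------
# geometry simulation


def _radii(plan: _Plan, cfg: SynthConfig) -> dict[int, float]:
    radius: dict[int, float] = {}
    for tid in sorted(plan.birth, key=lambda t: (plan.birth[t], t)):
        ps = plan.parents[tid]
        if not ps:
            radius[tid] = cfg.cell_radius
        elif len(ps) == 1:
            radius[tid] = radius[ps[0]] / math.sqrt(2.0)
        else:
            radius[tid] = math.hypot(radius[ps[0]], radius[ps[1]])
    return radius


def _reflect(pos: np.ndarray, heading: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    for ax in range(2):
        if pos[ax] < lo[ax]:
            pos[ax] = 2 * lo[ax] - pos[ax]
            heading[ax] = -heading[ax]
        elif pos[ax] > hi[ax]:
            pos[ax] = 2 * hi[ax] - pos[ax]
            heading[ax] = -heading[ax]
    np.clip(pos, lo, hi, out=pos)
    return pos, heading


def _clear(
    cand: np.ndarray,
    r: float,
    others: dict[int, tuple[np.ndarray, float]],
    skip: set[int],
) -> bool:
    for oid, (opos, orad) in others.items():
        if oid in skip:
            continue
        if float(np.hypot(*(cand - opos))) <= r + orad + _SEPARATION:
            return False
    return True


def generate_sequence(config: SynthConfig) -> SynthResult:
    """Generate one synthetic sequence; bit-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    plan = _plan_lineage(config, rng)
    radius = _radii(plan, config)
    H, W = config.field_size

    def bounds(r: float) -> tuple[np.ndarray, np.ndarray]:
        m = r + 1.0
        return np.array([m, m]), np.array([H - 1 - m, W - 1 - m])

    # persistent headings (unit vectors), drawn in track-id order
    heading: dict[int, np.ndarray] = {}
    for tid in sorted(plan.birth):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        heading[tid] = np.array([math.sin(ang), math.cos(ang)])

    mito_by_frame: dict[int, list[tuple[int, int, int]]] = {}
    for d, p, d1, d2 in plan.mitoses:
        mito_by_frame.setdefault(d, []).append((p, d1, d2))
    fus_by_frame: dict[int, list[tuple[int, int, int]]] = {}
    for f, p1, p2, c in plan.fusions:
        fus_by_frame.setdefault(f, []).append((p1, p2, c))
    fusion_of = {}
    for f, p1, p2, _c in plan.fusions:
        fusion_of[p1] = (p2, f)
        fusion_of[p2] = (p1, f)

    # initial placement by rejection sampling; each designated fusion pair
    # starts within a distance its members can close by their fusion frame
    pos: dict[int, np.ndarray] = {}
    initial = sorted(t for t in plan.birth if plan.birth[t] == 0)
    paired_with: dict[int, int] = {}
    for _f, p1, p2, _c in plan.fusions:
        paired_with[p2] = p1
    for tid in initial:
        lo, hi = bounds(radius[tid])
        placed = {o: (pos[o], radius[o]) for o in pos}
        if tid in paired_with and paired_with[tid] in pos:
            mate = paired_with[tid]
            f = fusion_of[tid][1]
            min_d = radius[tid] + radius[mate] + 2 * _SEPARATION
            max_d = max(
                min_d + 2.0,
                min(
                    config.fusion_proximity + 1.2 * config.base_speed * (f - 1),
                    0.45 * min(H, W),
                ),
            )
            for _try in range(4000):
                ang = rng.uniform(0.0, 2.0 * math.pi)
                d0 = rng.uniform(min_d, max_d)
                cand = pos[mate] + d0 * np.array([math.sin(ang), math.cos(ang)])
                if np.all(cand >= lo) and np.all(cand <= hi) and _clear(
                    cand, radius[tid], placed, set()
                ):
                    pos[tid] = cand
                    break
            else:
                raise ValueError("field too crowded to place a fusion pair")
            continue
        for _try in range(4000):
            cand = rng.uniform(lo, hi)
            if _clear(cand, radius[tid], placed, set()):
                pos[tid] = cand
                break
        else:
            raise ValueError("field too crowded to place initial cells")

    frames: list[np.ndarray] = []
    event_log: list[tuple[int, str, tuple[int, ...]]] = []
    alive = set(initial)

    def render() -> None:
        frame = np.zeros((H, W), dtype=np.uint16)
        for tid in sorted(alive):
            rr, cc = _disk(tuple(pos[tid]), radius[tid], shape=(H, W))
            frame[rr, cc] = tid
        frames.append(frame)

    render()  # frame 0

    for t in range(1, config.n_frames):
        # events scheduled at the t-1 -> t boundary
        mitos = mito_by_frame.get(t - 1, [])
        fuss = fus_by_frame.get(t - 1, [])

        # a fusion pair reaching its final frame is placed tangent, at a
        # centroid distance below the proximity trigger
        survivors = sorted(tid for tid in alive)
        merged_now: set[int] = set()
        for p1, p2, _child in fus_by_frame.get(t, []):
            r1, r2 = radius[p1], radius[p2]
            gap = min(config.fusion_proximity * 0.99, r1 + r2 + _SEPARATION)
            mid = (pos[p1] + pos[p2]) / 2.0
            axis = pos[p2] - pos[p1]
            norm = float(np.hypot(*axis))
            axis = axis / norm if norm > 0 else np.array([0.0, 1.0])
            pos[p1] = mid - axis * gap / 2.0
            pos[p2] = mid + axis * gap / 2.0
            for p in (p1, p2):
                lo, hi = bounds(radius[p])
                np.clip(pos[p], lo, hi, out=pos[p])
            merged_now.update((p1, p2))

        # move survivors: base velocity along heading + clipped Gaussian noise
        for tid in survivors:
            if tid in merged_now:
                continue
            direction = heading[tid]
            if tid in fusion_of and fusion_of[tid][0] in pos:
                # steer designated fusion partners together until they sit
                # just outside the proximity trigger, then hold
                partner, _f = fusion_of[tid]
                gap_vec = pos[partner] - pos[tid]
                dist = float(np.hypot(*gap_vec))
                holding = (
                    config.fusion_proximity + 2.0 * config.base_speed + 2.0
                )
                if dist > holding:
                    direction = gap_vec / max(dist, 1e-9)
                    heading[tid] = direction
            noise = rng.normal(0.0, config.noise_sigma, size=2)
            nn = float(np.hypot(*noise))
            limit = _NOISE_CLIP * config.noise_sigma
            if nn > limit > 0:
                noise *= limit / nn
            step = direction * config.base_speed + noise
            lo, hi = bounds(radius[tid])
            others = {
                o: (pos[o], radius[o]) for o in alive if o != tid
            }
            for scale in (1.0, 0.6, 0.3, 0.0):
                cand, hd = _reflect(
                    pos[tid] + scale * step, heading[tid].copy(), lo, hi
                )
                if _clear(cand, radius[tid], others, set()):
                    pos[tid], heading[tid] = cand, hd
                    break

        # apply divisions: parent disk replaced by two antipodal daughters
        for parent, d1, d2 in mitos:
            ppos = pos.pop(parent)
            alive.discard(parent)
            rd = radius[d1]
            others = {o: (pos[o], radius[o]) for o in alive}
            best_axis, best_clearance = None, -math.inf
            offset = rd + _SEPARATION / 2.0
            for _try in range(24):
                ang = rng.uniform(0.0, 2.0 * math.pi)
                axis = np.array([math.sin(ang), math.cos(ang)])
                c1, c2 = ppos - axis * offset, ppos + axis * offset
                lo, hi = bounds(rd)
                if np.any(c1 < lo) or np.any(c1 > hi) or np.any(c2 < lo) or np.any(c2 > hi):
                    continue
                if others:
                    clearance = min(
                        float(np.hypot(*(cc - opos))) - rd - orad
                        for cc in (c1, c2)
                        for opos, orad in others.values()
                    )
                else:
                    clearance = math.inf
                if clearance > best_clearance:
                    best_clearance, best_axis = clearance, axis
                if clearance > _SEPARATION:
                    break
            if best_axis is None:
                best_axis = np.array([0.0, 1.0])
            pos[d1] = ppos - best_axis * offset
            pos[d2] = ppos + best_axis * offset
            alive.update((d1, d2))
            event_log.append((t - 1, "mitosis", (parent, d1, d2)))

        # apply fusions: merged disk of summed area at the pair midpoint
        for p1, p2, child in fuss:
            mid = (pos.pop(p1) + pos.pop(p2)) / 2.0
            alive.difference_update((p1, p2))
            lo, hi = bounds(radius[child])
            np.clip(mid, lo, hi, out=mid)
            pos[child] = mid
            alive.add(child)
            event_log.append((t - 1, "fusion", (p1, p2, child)))

        render()

    tracks = {
        tid: Track(
            track_id=tid,
            frame_begin=plan.birth[tid],
            frame_end=plan.end[tid],
            parents=plan.parents[tid],
        )
        for tid in sorted(plan.birth)
    }
    lineage = Lineage(tracks=tracks)
    event_log.sort(key=lambda e: (e[0], e[1], e[2]))
    return SynthResult(
        stack=LabelStack(frames=frames), gt_lineage=lineage, event_log=event_log
    )


def write_ground_truth(result: SynthResult, out_directory: str | Path) -> Path:
    """Write the ground truth in CTC GT layout: ``TRA/man_trackNNN.tif``,
    ``TRA/man_track.txt`` and the two-parent ``lineage.json`` sidecar."""
    out = Path(out_directory) / "TRA"
    write_mask_stack(result.stack.frames, out, prefix="man_track")
    write_track_file(records_from_lineage(result.gt_lineage), out / "man_track.txt")
    events = [
        {"frame": f, "kind": kind, "participants": list(parts)}
        for f, kind, parts in result.event_log
    ]
    write_lineage_sidecar(result.gt_lineage, out / "lineage.json", events=events)
    return out
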