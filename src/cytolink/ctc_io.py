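"""Cell Tracking Challenge (CTC) I/O and per-region feature extraction.

The CTC layout stores a time-lapse sequence as one 16-bit label TIFF per
frame (``mask000.tif``, ``mask001.tif``, ... — background 0, each cell
instance a positive integer) plus a whitespace-separated track file with one
line ``L B E P`` per track: label, begin frame, end frame, parent label
(0 = none).  The four-column format cannot express a track with two parents
(a fusion product), so alongside every track file this package writes a
``lineage.json`` sidecar that records the full parent set per track; the
track file itself carries the lower-numbered parent so that standard CTC
tools still see a consistent single-parent graph.

Coordinates are (row, col), 0-based; frame indices are 0-based and match the
zero-padded frame number in the file name.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from skimage.measure import regionprops

__all__ = [
    "LabelStack",
    "Detection",
    "Track",
    "Lineage",
    "TrackRecord",
    "read_label_stack",
    "extract_detections",
    "write_ctc_result",
    "read_ctc_tracks",
    "write_mask_stack",
    "write_track_file",
    "write_lineage_sidecar",
    "lineage_from_records",
    "records_from_lineage",
]

_FRAME_RE = re.compile(r"^\D*?(\d+)\.tiff?$", re.IGNORECASE)


@dataclass
class LabelStack:
    """Ordered stack of 2D integer label images sharing one (H, W) shape."""

    frames: list[np.ndarray]
    frame_index_origin: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("label stack must contain at least one frame")
        shape = self.frames[0].shape
        for t, frame in enumerate(self.frames):
            if frame.ndim != 2:
                raise ValueError(f"frame {t} is not a 2D image")
            if frame.shape != shape:
                raise ValueError(
                    f"inconsistent image dimensions: frame {t} has shape "
                    f"{frame.shape}, expected {shape}"
                )
            if not np.issubdtype(frame.dtype, np.integer):
                raise ValueError(f"frame {t} is not an integer label image")
            if frame.min() < 0:
                raise ValueError(f"frame {t} contains negative labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class Detection:
    """One segmented cell instance in one frame.

    The orientation of the region's major axis theta is encoded as
    (sin 2*theta, cos 2*theta) so that the descriptor is invariant under the
    pi-ambiguity of an axis direction.  Degenerate regions (single pixel, or
    zero-length major axis) use the convention (0, 1) with eccentricity 0.
    """

    frame: int
    label: int
    centroid: tuple[float, float]  # (row, col)
    area: float
    equivalent_diameter: float
    perimeter: float
    eccentricity: float
    solidity: float
    orient_sin2: float
    orient_cos2: float

    def distance_to(self, other: "Detection") -> float:
        return math.hypot(
            self.centroid[0] - other.centroid[0],
            self.centroid[1] - other.centroid[1],
        )


@dataclass(frozen=True)
class TrackRecord:
    """One line of a CTC track file, plus the sidecar's second parent."""

    track_id: int
    frame_begin: int
    frame_end: int
    parent_id: int = 0
    second_parent_id: int = 0

    def __post_init__(self) -> None:
        if self.track_id <= 0:
            raise ValueError("track_id must be positive")
        if self.frame_begin > self.frame_end:
            raise ValueError(
                f"track {self.track_id}: begin {self.frame_begin} after "
                f"end {self.frame_end}"
            )
        if self.parent_id == self.track_id:
            raise ValueError(f"track {self.track_id} is its own parent")
        if self.second_parent_id and not self.parent_id:
            raise ValueError(
                f"track {self.track_id}: second parent without first parent"
            )


@dataclass
class Track:
    """A single-cell trajectory with 0, 1 (mitosis daughter) or 2 (fusion
    product) parent tracks."""

    track_id: int
    frame_begin: int
    frame_end: int
    parents: tuple[int, ...] = ()
    detections: tuple[Detection, ...] | None = None

    @property
    def length(self) -> int:
        return self.frame_end - self.frame_begin + 1


@dataclass
class Lineage:
    """A set of tracks with parent links; the tracker's primary output."""

    tracks: dict[int, Track] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, tr in self.tracks.items():
            if tid != tr.track_id:
                raise ValueError("lineage key does not match track id")
            for p in tr.parents:
                if p not in self.tracks:
                    raise ValueError(f"track {tid} references unknown parent {p}")

    def children_of(self, track_id: int) -> list[int]:
        return sorted(
            t.track_id for t in self.tracks.values() if track_id in t.parents
        )

    def mitosis_parents(self) -> list[int]:
        """Tracks that end by dividing into exactly two single-parent daughters."""
        kids: dict[int, list[int]] = {}
        for tr in self.tracks.values():
            if len(tr.parents) == 1:
                kids.setdefault(tr.parents[0], []).append(tr.track_id)
        return sorted(p for p, c in kids.items() if len(c) == 2)

    def fusion_products(self) -> list[int]:
        return sorted(t.track_id for t in self.tracks.values() if len(t.parents) == 2)

    @property
    def n_mitosis(self) -> int:
        return len(self.mitosis_parents())

    @property
    def n_fusion(self) -> int:
        return len(self.fusion_products())

    def frame_range(self) -> tuple[int, int]:
        begins = [t.frame_begin for t in self.tracks.values()]
        ends = [t.frame_end for t in self.tracks.values()]
        return min(begins), max(ends)


# ---------------------------------------------------------------------------
# reading


def read_label_stack(mask_directory: str | Path) -> LabelStack:
    """Read a CTC-layout directory of per-frame label TIFFs.

    Files are matched by a trailing zero-padded frame number (``mask000.tif``,
    ``man_track017.tif``, ``t012.tif``...).  Frame numbers must start at 0 and
    be consecutive; a gap raises ``ValueError``.
    """
    directory = Path(mask_directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"mask directory not found: {directory}")
    numbered: dict[int, Path] = {}
    for path in sorted(directory.iterdir()):
        m = _FRAME_RE.match(path.name)
        if m is None:
            continue
        num = int(m.group(1))
        if num in numbered:
            raise ValueError(f"duplicate frame number {num} in {directory}")
        numbered[num] = path
    if not numbered:
        raise ValueError(f"no mask files found in {directory}")
    if min(numbered) != 0:
        raise ValueError(f"frame numbering must start at 0 in {directory}")
    frames = []
    for t in range(max(numbered) + 1):
        if t not in numbered:
            raise ValueError(f"missing frame {t} in {directory}")
        frames.append(np.asarray(tifffile.imread(numbered[t])))
    return LabelStack(frames=frames)


def extract_detections(stack: LabelStack) -> list[list[Detection]]:
    """One :class:`Detection` per positive label per frame.

    Output ordering is deterministic: frames in order, labels ascending
    within each frame.  Feature values come from ``skimage.measure
    .regionprops`` on the labeled image.
    """
    per_frame: list[list[Detection]] = []
    for t, frame in enumerate(stack.frames):
        dets = []
        for rp in regionprops(frame):
            theta = rp.orientation
            if rp.axis_major_length == 0 or not np.isfinite(theta):
                sin2, cos2 = 0.0, 1.0
                ecc = 0.0
            else:
                sin2, cos2 = math.sin(2 * theta), math.cos(2 * theta)
                ecc = float(rp.eccentricity)
            dets.append(
                Detection(
                    frame=t,
                    label=int(rp.label),
                    centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                    area=float(rp.area),
                    equivalent_diameter=float(rp.equivalent_diameter_area),
                    perimeter=float(rp.perimeter),
                    eccentricity=ecc,
                    solidity=float(rp.solidity),
                    orient_sin2=float(sin2),
                    orient_cos2=float(cos2),
                )
            )
        dets.sort(key=lambda d: d.label)
        per_frame.append(dets)
    return per_frame


def read_ctc_tracks(track_file: str | Path) -> list[TrackRecord]:
    """Parse a CTC ``man_track.txt`` / ``res_track.txt`` file.

    If a ``lineage.json`` sidecar sits next to the file, its parent sets
    populate ``second_parent_id`` for fusion products.
    """
    path = Path(track_file)
    records: list[TrackRecord] = []
    raw: list[tuple[int, int, int, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            vals = tuple(int(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer field") from exc
        raw.append(vals)  # type: ignore[arg-type]

    second_parent: dict[int, int] = {}
    sidecar = path.parent / "lineage.json"
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        for entry in data.get("tracks", []):
            parents = sorted(int(p) for p in entry.get("parents", []))
            if len(parents) == 2:
                second_parent[int(entry["id"])] = parents[1]

    known = {}
    for tid, begin, end, parent in raw:
        known[tid] = (begin, end)
    for tid, begin, end, parent in raw:
        if parent:
            if parent not in known:
                raise ValueError(f"track {tid} references unknown parent {parent}")
            if begin < known[parent][1] + 1:
                raise ValueError(
                    f"track {tid} starts at frame {begin} before parent "
                    f"{parent} ends at {known[parent][1]}"
                )
        records.append(
            TrackRecord(
                track_id=tid,
                frame_begin=begin,
                frame_end=end,
                parent_id=parent,
                second_parent_id=second_parent.get(tid, 0),
            )
        )
    return records


def lineage_from_records(records: Iterable[TrackRecord]) -> Lineage:
    tracks = {}
    for r in records:
        parents: tuple[int, ...]
        if r.second_parent_id:
            parents = tuple(sorted((r.parent_id, r.second_parent_id)))
        elif r.parent_id:
            parents = (r.parent_id,)
        else:
            parents = ()
        tracks[r.track_id] = Track(
            track_id=r.track_id,
            frame_begin=r.frame_begin,
            frame_end=r.frame_end,
            parents=parents,
        )
    return Lineage(tracks=tracks)


def records_from_lineage(lineage: Lineage) -> list[TrackRecord]:
    records = []
    for tid in sorted(lineage.tracks):
        tr = lineage.tracks[tid]
        parents = sorted(tr.parents)
        records.append(
            TrackRecord(
                track_id=tid,
                frame_begin=tr.frame_begin,
                frame_end=tr.frame_end,
                parent_id=parents[0] if parents else 0,
                second_parent_id=parents[1] if len(parents) == 2 else 0,
            )
        )
    return records


# ---------------------------------------------------------------------------
# writing


def _frame_name(prefix: str, t: int, width: int) -> str:
    return f"{prefix}{t:0{width}d}.tif"


def write_mask_stack(
    frames: Sequence[np.ndarray], out_directory: Path, prefix: str = "mask"
) -> None:
    out_directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(len(frames) - 1)))
    for t, frame in enumerate(frames):
        tifffile.imwrite(
            out_directory / _frame_name(prefix, t, width),
            frame.astype(np.uint16),
        )


def write_track_file(records: Iterable[TrackRecord], path: Path) -> None:
    lines = [
        f"{r.track_id} {r.frame_begin} {r.frame_end} {r.parent_id}"
        for r in sorted(records, key=lambda r: r.track_id)
    ]
    path.write_text("\n".join(lines) + "\n")


def write_lineage_sidecar(
    lineage: Lineage,
    path: Path,
    events: list[dict] | None = None,
) -> None:
    data = {
        "tracks": [
            {
                "id": tid,
                "begin": lineage.tracks[tid].frame_begin,
                "end": lineage.tracks[tid].frame_end,
                "parents": sorted(lineage.tracks[tid].parents),
            }
            for tid in sorted(lineage.tracks)
        ],
    }
    if events is not None:
        data["events"] = events
    path.write_text(json.dumps(data, indent=1) + "\n")


def write_ctc_result(
    lineage: Lineage,
    stack: LabelStack,
    out_directory: str | Path,
    prefix: str = "mask",
    track_filename: str = "res_track.txt",
    events: list[dict] | None = None,
) -> Path:
    """Write a tracking result in CTC layout.

    Mask pixel values are rewritten to track ids so the result directory is
    self-describing; ``res_track.txt`` holds one ``L B E P`` line per track
    (lower-numbered parent for fusion products) and ``lineage.json`` the full
    parent sets.  The output round-trips through :func:`read_ctc_tracks`.
    """
    out = Path(out_directory)
    claimed: dict[tuple[int, int], int] = {}
    for tid in sorted(lineage.tracks):
        tr = lineage.tracks[tid]
        if tr.detections is None:
            raise ValueError(
                f"track {tid} carries no detections; cannot relabel masks"
            )
        if tr.frame_begin > tr.frame_end:
            raise ValueError(f"track {tid} has an empty frame span")
        for det in tr.detections:
            key = (det.frame, det.label)
            if key in claimed:
                raise ValueError(
                    f"detection frame={det.frame} label={det.label} claimed by "
                    f"both track {claimed[key]} and track {tid}"
                )
            claimed[key] = tid

    relabeled = []
    for t, frame in enumerate(stack.frames):
        lut = np.zeros(int(frame.max()) + 1, dtype=np.uint16)
        for (ft, label), tid in claimed.items():
            if ft == t:
                lut[label] = tid
        relabeled.append(lut[frame])

    write_mask_stack(relabeled, out, prefix=prefix)
    write_track_file(records_from_lineage(lineage), out / track_filename)
    write_lineage_sidecar(lineage, out / "lineage.json", events=events)
    return out
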