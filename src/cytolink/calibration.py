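"""Lineage statistics and Bayesian calibration of the ILP cost weights.

Calibration searches the weight space (wt, wm, wf, wa, wd, dmax) for the
configuration whose reconstructed lineage best matches macroscopic targets
an experimentalist can state without ground-truth trajectories: cell counts
in the first frame, total tracks, expected mitosis and fusion counts, and
so on.  The objective is the normalized squared deviation

    sum over targeted fields of ((predicted - target) / max(|target|, 1))^2

(the max(., 1) denominator guards zero-valued targets such as "no fusions
expected").  The search is sequential model-based optimization: a Gaussian-
process surrogate (Matern 5/2) is fitted to the evaluations made so far and
the next configuration maximizes expected improvement over a random
candidate pool.  Fully deterministic for a fixed seed.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .ctc_io import Detection, LabelStack, Lineage, extract_detections
from .ilp import CostWeights, track as ilp_track

__all__ = [
    "LineageStats",
    "CalibrationTargets",
    "lineage_summary",
    "calibration_objective",
    "calibrate",
    "DEFAULT_BOUNDS",
]

#: search-space bounds per weight, spanning the regimes seen in practice
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "wt": (0.1, 3.0),
    "wm": (0.5, 20.0),
    "wf": (1.0, 30.0),
    "wa": (5.0, 40.0),
    "wd": (5.0, 40.0),
    "dmax": (20.0, 80.0),
}
_DIMS = ("wt", "wm", "wf", "wa", "wd", "dmax")


@dataclass(frozen=True)
class LineageStats:
    first_frame_cells: int
    last_frame_cells: int
    total_tracks: int
    mitosis_events: int
    fusion_events: int
    mean_track_length: float
    median_track_length: float
    lifecycle_min: int
    lifecycle_max: int
    lifecycle_mean: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class CalibrationTargets:
    """Targets for any subset of :class:`LineageStats` fields."""

    targets: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    n_calls: int = 30
    n_initial: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("at least one target must be set")
        valid = {f.name for f in dc_fields(LineageStats)}
        for name in self.targets:
            if name not in valid:
                raise ValueError(f"unknown lineage statistic {name!r}")
        for name, (lo, hi) in self.bounds.items():
            if name not in _DIMS:
                raise ValueError(f"unknown weight dimension {name!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}")
        if self.n_calls < self.n_initial:
            raise ValueError("n_calls must be >= n_initial")


def lineage_summary(lineage: Lineage) -> LineageStats:
    """Macroscopic statistics of a lineage.

    Event counts come from the parent-link topology: a track with exactly
    two single-parent children divided; a track with two parents is a fusion
    product.  Track length (equals the life-cycle span) is
    ``frame_end - frame_begin + 1``.
    """
    first, last = lineage.frame_range()
    lengths = [t.length for t in lineage.tracks.values()]
    return LineageStats(
        first_frame_cells=sum(
            1
            for t in lineage.tracks.values()
            if t.frame_begin <= first <= t.frame_end
        ),
        last_frame_cells=sum(
            1 for t in lineage.tracks.values() if t.frame_begin <= last <= t.frame_end
        ),
        total_tracks=len(lineage.tracks),
        mitosis_events=lineage.n_mitosis,
        fusion_events=lineage.n_fusion,
        mean_track_length=float(np.mean(lengths)),
        median_track_length=float(statistics.median(lengths)),
        lifecycle_min=int(min(lengths)),
        lifecycle_max=int(max(lengths)),
        lifecycle_mean=float(np.mean(lengths)),
    )


def calibration_objective(stats: LineageStats, targets: CalibrationTargets) -> float:
    values = stats.as_dict()
    total = 0.0
    for name, expect in targets.targets.items():
        total += ((values[name] - expect) / max(abs(expect), 1.0)) ** 2
    return total


def _weights_from_vector(x: np.ndarray) -> CostWeights:
    vals = dict(zip(_DIMS, (float(v) for v in x)))
    vals["dmax"] = float(round(vals["dmax"]))
    return CostWeights(**vals)


def _expected_improvement(
    gp: GaussianProcessRegressor, X: np.ndarray, y_best: float
) -> np.ndarray:
    mu, sd = gp.predict(X, return_std=True)
    sd = np.maximum(sd, 1e-12)
    z = (y_best - mu) / sd
    return (y_best - mu) * norm.cdf(z) + sd * norm.pdf(z)


def calibrate(
    stack: LabelStack | list[list[Detection]],
    targets: CalibrationTargets,
) -> tuple[CostWeights, list[tuple[CostWeights, float]]]:
    """Calibrate ILP weights against biological targets.

    Returns the best evaluated configuration and the full evaluation trace
    (length ``n_calls``).  Consumes only the mask stack and the declared
    targets — never ground-truth annotations.
    """
    detections = (
        extract_detections(stack) if isinstance(stack, LabelStack) else stack
    )
    rng = np.random.default_rng(targets.seed)
    lo = np.array([targets.bounds.get(d, DEFAULT_BOUNDS[d])[0] for d in _DIMS])
    hi = np.array([targets.bounds.get(d, DEFAULT_BOUNDS[d])[1] for d in _DIMS])

    def evaluate(x: np.ndarray) -> tuple[CostWeights, float]:
        weights = _weights_from_vector(x)
        lineage = ilp_track(detections, weights)
        return weights, calibration_objective(lineage_summary(lineage), targets)

    X: list[np.ndarray] = []
    trace: list[tuple[CostWeights, float]] = []
    for _ in range(targets.n_initial):
        x = rng.uniform(lo, hi)
        X.append(x)
        trace.append(evaluate(x))

    kernel = ConstantKernel(1.0) * Matern(
        length_scale=np.ones(len(_DIMS)), nu=2.5
    ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e-1))
    for _ in range(targets.n_calls - targets.n_initial):
        y = np.array([v for _, v in trace])
        # normalize inputs to the unit box for stable length scales
        Xn = (np.array(X) - lo) / (hi - lo)
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=0, alpha=1e-10
        )
        with warnings.catch_warnings():
            # a flat (fully matched) objective pushes length scales to their
            # bounds; harmless for the acquisition step
            warnings.simplefilter("ignore")
            gp.fit(Xn, y)
        pool = rng.uniform(0.0, 1.0, size=(1024, len(_DIMS)))
        ei = _expected_improvement(gp, pool, float(y.min()))
        x = lo + pool[int(np.argmax(ei))] * (hi - lo)
        X.append(x)
        trace.append(evaluate(x))

    best_idx = int(np.argmin([v for _, v in trace]))
    return trace[best_idx][0], trace
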