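"""Composite biologically motivated tracking scores and lineage reports.

Two composite scores summarize lineage-reconstruction quality from
established Cell Tracking Challenge component metrics (all in [0, 1]):

    BIO    = 0.25 * (CT + BC + TF + CCA)
    OP_CLB = 0.5 * (LNK + BIO)

where CT is the complete-tracks fraction, BC branching correctness, TF the
track fraction, CCA cell-cycle accuracy and LNK linking accuracy.  This
module composes and reports; the component metrics themselves are defined
by the CTC evaluation protocol (see :mod:`cytolink.evaluation` for the
AOGM-based TRA score computed in this package).

Reported values are rounded half-up to 3 decimals.  The rounding is done in
decimal arithmetic on the inputs so that values whose exact decimal mean
ends in ...5 (e.g. 0.5 * (0.997 + 0.930) = 0.9635) round up as a human
would round them, instead of following the binary-float representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .calibration import LineageStats, lineage_summary
from .ctc_io import Lineage

__all__ = ["MetricBundle", "bio_score", "op_clb_score", "stats_report"]


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _dec(x: float) -> Decimal:
    return Decimal(repr(float(x)))


def _round3(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def bio_score(ct: float, bc: float, tf: float, cca: float) -> float:
    """BIO = 0.25 * (CT + BC + TF + CCA), rounded half-up to 3 decimals."""
    for name, v in (("ct", ct), ("bc", bc), ("tf", tf), ("cca", cca)):
        _check_unit(name, v)
    return _round3(
        (_dec(ct) + _dec(bc) + _dec(tf) + _dec(cca)) * Decimal("0.25")
    )


def op_clb_score(lnk: float, bio: float) -> float:
    """OP_CLB = 0.5 * (LNK + BIO), rounded half-up to 3 decimals."""
    _check_unit("lnk", lnk)
    _check_unit("bio", bio)
    return _round3((_dec(lnk) + _dec(bio)) * Decimal("0.5"))


@dataclass(frozen=True)
class MetricBundle:
    """Component metrics plus the derived composites."""

    ct: float
    bc: float
    tf: float
    cca: float
    lnk: float

    @property
    def bio(self) -> float:
        return bio_score(self.ct, self.bc, self.tf, self.cca)

    @property
    def op_clb(self) -> float:
        return op_clb_score(self.lnk, self.bio)


def stats_report(result: Lineage, reference: Lineage) -> pd.DataFrame:
    """Side-by-side lineage statistics with absolute deviations.

    Both lineages must cover the same frame range; rows are the
    :class:`~cytolink.calibration.LineageStats` fields.
    """
    if result.frame_range() != reference.frame_range():
        raise ValueError(
            f"frame-range mismatch: result {result.frame_range()} vs "
            f"reference {reference.frame_range()}"
        )
    res = lineage_summary(result).as_dict()
    ref = lineage_summary(reference).as_dict()
    rows = {
        name: {
            "reference": ref[name],
            "result": res[name],
            "abs_deviation": abs(res[name] - ref[name]),
        }
        for name in LineageStats.__dataclass_fields__
    }
    return pd.DataFrame.from_dict(rows, orient="index")
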