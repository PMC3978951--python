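"""Standardized dissimilarity score (SDS).

The panel's internal distance matrix yields reference statistics: the
average over columns of the per-column median and interquartile range
(diagonal excluded).  A test sample's median distance to all panel members
is then standardized as

    SDS = (median(d(test, members)) - ref_median) / ref_iqr.

An SDS near 0 means the sample is as close to the panel as the members are
to each other; growing SDS indicates accumulating genotyping errors.
Quantiles use the linear-interpolation (type-7) convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix, distances_to_members
from .reference_panel import ReferencePanel
from .types import VariantSet


@dataclass(frozen=True)
class ReferenceStats:
    """Column-averaged median and IQR of the panel's internal distances."""

    ref_median: float
    ref_iqr: float

    def __post_init__(self) -> None:
        if self.ref_iqr <= 0:
            raise ValueError("reference IQR must be positive")


@dataclass(frozen=True)
class SDSResult:
    """A test sample's raw and standardized distance to the panel."""

    sample_id: str
    raw_median: float
    raw_mean: float
    sds: float
    ref_median: float
    ref_iqr: float

    def to_dict(self) -> dict:
        return {
            "sample": self.sample_id,
            "raw_median": self.raw_median,
            "raw_mean": self.raw_mean,
            "ref_median": self.ref_median,
            "ref_iqr": self.ref_iqr,
            "sds": self.sds,
        }


def reference_stats(panel_D: DistanceMatrix) -> ReferenceStats:
    """Average per-column median and IQR of a panel distance matrix.

    The diagonal (self-distance 0) is excluded from each column.  Raises on
    fewer than 4 members (IQR unstable) or a degenerate zero IQR.
    """
    m = len(panel_D)
    if m < 4:
        raise ValueError(f"reference statistics need >= 4 members, got {m}")
    values = panel_D.values
    off = ~np.eye(m, dtype=bool)
    cols = values.T[off.T].reshape(m, m - 1)  # column i without its diagonal
    medians = np.median(cols, axis=1)
    q1 = np.quantile(cols, 0.25, axis=1)
    q3 = np.quantile(cols, 0.75, axis=1)
    iqr = float(np.mean(q3 - q1))
    if iqr <= 0:
        raise ValueError("degenerate panel: zero interquartile range of distances")
    return ReferenceStats(float(np.mean(medians)), iqr)


def standardize(raw_median: float, stats: ReferenceStats) -> float:
    return (raw_median - stats.ref_median) / stats.ref_iqr


def sds(
    test: VariantSet,
    panel: ReferencePanel,
    stats: ReferenceStats,
    weighted: bool = True,
) -> SDSResult:
    """SDS of a test sample against a reference panel."""
    if panel.member_sets is None or not panel.member_sets:
        raise ValueError("panel has no member variant sets")
    d = distances_to_members(test, panel, weighted=weighted)
    raw_median = float(np.median(d))
    return SDSResult(
        sample_id=test.sample_id,
        raw_median=raw_median,
        raw_mean=float(np.mean(d)),
        sds=standardize(raw_median, stats),
        ref_median=stats.ref_median,
        ref_iqr=stats.ref_iqr,
    )
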