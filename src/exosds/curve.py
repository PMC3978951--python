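"""SDS-versus-error-rate reference curve and its inversion.

For each error rate p on a log-spaced grid, panel members are perturbed by
simulated genotyping errors and their SDS against the unperturbed panel is
recorded; the per-p median and 5%/95% quantiles form the reference curve.
A test sample's SDS is then inverted through the curve (monotone piecewise
linear interpolation in log10 p) to estimate its genotyping error rate;
the quantile curves give the uncertainty band, and SDS values outside the
curve's range are censored at the grid boundary, never silently.

The curve is near-flat while errors are rarer than the genuine
inter-individual differences in the panel and rises steeply beyond that —
a phase-transition-like shape that sets the method's detection limit.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .distance import pair_sums
from .errors import ErrorModel, error_to_accuracy, AccuracyValue
from .reference_panel import ReferencePanel
from .sds import ReferenceStats, reference_stats, standardize
from .distance import DistanceMatrix, distances_to_members
from .errors import inject_errors

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: half-decade grid spanning the error range of interest
DEFAULT_GRID: tuple[float, ...] = (1e-6, 3.16e-6, 1e-5, 3.16e-5, 1e-4, 3.16e-4, 1e-3)


@dataclass
class ReferenceCurve:
    """Median and 5%/95% quantile SDS at each simulated error rate."""

    grid: np.ndarray
    sds_median: np.ndarray
    sds_q05: np.ndarray
    sds_q95: np.ndarray
    n_replicates: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.sds_median = np.asarray(self.sds_median, dtype=np.float64)
        self.sds_q05 = np.asarray(self.sds_q05, dtype=np.float64)
        self.sds_q95 = np.asarray(self.sds_q95, dtype=np.float64)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("error-rate grid must be strictly increasing")
        if np.any(self.sds_q05 > self.sds_median) or np.any(self.sds_median > self.sds_q95):
            raise ValueError("quantile curves must bracket the median curve")

    def to_json(self, path: PathLike) -> None:
        payload = {
            "metadata": {**self.metadata, "n_replicates": self.n_replicates},
            "points": [
                {
                    "p": float(p),
                    "sds_median": float(m),
                    "sds_q05": float(lo),
                    "sds_q95": float(hi),
                }
                for p, m, lo, hi in zip(
                    self.grid, self.sds_median, self.sds_q05, self.sds_q95
                )
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: PathLike) -> "ReferenceCurve":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        pts = payload["points"]
        meta = dict(payload.get("metadata", {}))
        n_rep = meta.pop("n_replicates", 0)
        return cls(
            grid=np.array([q["p"] for q in pts]),
            sds_median=np.array([q["sds_median"] for q in pts]),
            sds_q05=np.array([q["sds_q05"] for q in pts]),
            sds_q95=np.array([q["sds_q95"] for q in pts]),
            n_replicates=n_rep,
            metadata=meta,
        )


@dataclass(frozen=True)
class ErrorEstimate:
    """Estimated genotyping error rate with its uncertainty band."""

    p_hat: float
    p_lo: float
    p_hi: float
    accuracy: AccuracyValue
    censored: bool
    sds_value: float

    def to_dict(self) -> dict:
        return {
            "sds": self.sds_value,
            "p_hat": self.p_hat,
            "p_lo": self.p_lo,
            "p_hi": self.p_hi,
            "accuracy_pct": self.accuracy.value,
            "censored": self.censored,
        }


def _isotonic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return IsotonicRegression(increasing=True).fit_transform(x, y)


def build_curve(
    panel: ReferencePanel,
    grid: Sequence[float] = DEFAULT_GRID,
    n_replicates: int = 30,
    mode: str = "approx",
    seed: int = 0,
    stats: Optional[ReferenceStats] = None,
    weighted: bool = True,
) -> ReferenceCurve:
    """Simulate the SDS distribution over an error-rate grid.

    For each grid point and replicate, one panel member is perturbed at
    that error rate — explicitly (``mode="explicit"``) or through the
    binomial approximation on the normalizing constant (``mode="approx"``)
    — and its SDS against the unperturbed panel is computed.  Median
    curves are made monotone by isotonic regression before storage.
    """
    if panel.member_sets is None:
        raise ValueError("building a curve requires panel member sets")
    grid = np.asarray(sorted(grid), dtype=np.float64)
    if grid.size == 0:
        raise ValueError("error-rate grid is empty")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per grid point")
    if n_replicates < 10:
        logger.warning("n_replicates=%d is low; quantiles will be noisy", n_replicates)
    if mode not in ("approx", "explicit"):
        raise ValueError(f"unknown simulation mode {mode!r}")

    members = panel.member_sets
    n = len(members)
    region_size = panel.region.total_size
    A, C = pair_sums(members, panel, weighted=weighted)
    D = 1.0 - np.divide(A, C, out=np.ones_like(A), where=C > 0)
    np.fill_diagonal(D, 0.0)
    panel_D = DistanceMatrix([vs.sample_id for vs in members], D)
    if stats is None:
        stats = reference_stats(panel_D)

    rng = np.random.default_rng(seed)
    w_err = ErrorModel(p=grid[0], N=region_size).resolved_weight(n)
    medians = np.empty(grid.size)
    q05 = np.empty(grid.size)
    q95 = np.empty(grid.size)
    for gi, p in enumerate(grid):
        scores = np.empty(n_replicates)
        for r in range(n_replicates):
            m = r % n
            if mode == "approx":
                # one binomial draw per simulated sample, shared across pairs
                x_draw = rng.binomial(region_size, p)
                d_vec = 1.0 - A[m] / (C[m] + w_err * x_draw)
            else:
                model = ErrorModel(p=p, N=region_size)
                perturbed = inject_errors(members[m], model, rng=rng)
                d_vec = distances_to_members(perturbed, panel, weighted=weighted)
            scores[r] = standardize(float(np.median(d_vec)), stats)
        medians[gi] = np.median(scores)
        q05[gi] = np.quantile(scores, 0.05)
        q95[gi] = np.quantile(scores, 0.95)

    order = np.arange(grid.size, dtype=np.float64)  # grid order; robust to p=0
    smoothed = _isotonic(order, medians)
    if not np.allclose(smoothed, medians):
        logger.info("median curve had monotonicity violations; isotonic-smoothed")
    medians = smoothed
    q05 = np.minimum(_isotonic(order, q05), medians)
    q95 = np.maximum(_isotonic(order, q95), medians)
    return ReferenceCurve(
        grid=grid,
        sds_median=medians,
        sds_q05=q05,
        sds_q95=q95,
        n_replicates=n_replicates,
        metadata={
            "panel": panel.population,
            "n_members": n,
            "N": region_size,
            "mode": mode,
            "seed": seed,
            "ref_median": stats.ref_median,
            "ref_iqr": stats.ref_iqr,
            "quantile_convention": "type-7",
        },
    )


def _invert_monotone(sds_value: float, curve_y: np.ndarray, log_p: np.ndarray) -> float:
    """Interpolate log10(p) at sds_value on a non-decreasing SDS curve."""
    # break exact ties so np.interp sees strictly increasing abscissae
    y = curve_y + np.arange(curve_y.size) * 1e-12
    return float(np.interp(sds_value, y, log_p))


def estimate_error(sds_value: float, curve: ReferenceCurve) -> ErrorEstimate:
    """Invert the reference curve at an observed SDS.

    Below the curve's range the estimate is censored at the smallest grid
    error rate (an upper bound); above it, at the largest.  The 95% and 5%
    quantile curves yield the lower and upper bounds of the band.
    """
    if not np.all(np.diff(curve.sds_median) >= 0):
        raise ValueError("reference curve medians are not monotone")
    if curve.grid[0] <= 0:
        raise ValueError("error-rate inversion needs a strictly positive grid")
    log_p = np.log10(curve.grid)
    lo_grid, hi_grid = float(curve.grid[0]), float(curve.grid[-1])
    if sds_value < curve.sds_median[0]:
        return ErrorEstimate(
            p_hat=lo_grid, p_lo=0.0, p_hi=lo_grid,
            accuracy=error_to_accuracy(lo_grid), censored=True, sds_value=sds_value,
        )
    if sds_value > curve.sds_median[-1]:
        return ErrorEstimate(
            p_hat=hi_grid, p_lo=hi_grid, p_hi=hi_grid,
            accuracy=error_to_accuracy(hi_grid), censored=True, sds_value=sds_value,
        )
    p_hat = 10.0 ** _invert_monotone(sds_value, curve.sds_median, log_p)
    # higher-quantile curve reaches a given SDS at a smaller error rate
    if sds_value < curve.sds_q95[0]:
        p_lo = 0.0
    else:
        p_lo = 10.0 ** _invert_monotone(sds_value, curve.sds_q95, log_p)
    if sds_value > curve.sds_q05[-1]:
        p_hi = hi_grid
    else:
        p_hi = 10.0 ** _invert_monotone(sds_value, curve.sds_q05, log_p)
    p_lo = min(p_lo, p_hat)
    p_hi = max(p_hi, p_hat)
    return ErrorEstimate(
        p_hat=p_hat, p_lo=p_lo, p_hi=p_hi,
        accuracy=error_to_accuracy(p_hat), censored=False, sds_value=sds_value,
    )
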