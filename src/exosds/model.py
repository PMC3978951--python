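"""Model/Results front door for the accuracy-estimation workflow.

:class:`GenotypeAccuracyModel` is built from a reference panel (with member
variant sets); :meth:`fit` computes the panel's internal distance matrix,
the standardization statistics and the simulated SDS-versus-error-rate
reference curve, returning a :class:`GenotypeAccuracyResults` that scores
test samples, embeds them next to the panel, and prints a summary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .curve import (
    DEFAULT_GRID,
    ErrorEstimate,
    ReferenceCurve,
    build_curve,
    estimate_error,
)
from .distance import DistanceMatrix, distance_matrix
from .nmds import Embedding, nmds
from .reference_panel import ReferencePanel, build_panel
from .sds import ReferenceStats, SDSResult, reference_stats, sds
from .types import VariantSet


@dataclass(frozen=True)
class SampleScore:
    """Everything the method reports about one test sample."""

    sds: SDSResult
    estimate: ErrorEstimate

    def to_dict(self) -> dict:
        return {**self.sds.to_dict(), **self.estimate.to_dict()}


class GenotypeAccuracyModel:
    """Exome genotyping-accuracy model calibrated on a reference panel.

    Parameters
    ----------
    panel
        Reference panel with member variant sets (the high-quality
        population the test samples are compared to).
    weighted
        Use genotype-frequency weights (default); ``False`` gives the
        Hamming-style unweighted variant.
    grid, n_replicates, mode
        Error-rate grid and per-point replicate count for the simulated
        reference curve; ``mode`` chooses the binomial approximation
        ("approx") or explicit error injection ("explicit").
    """

    def __init__(
        self,
        panel: ReferencePanel,
        weighted: bool = True,
        grid: Sequence[float] = DEFAULT_GRID,
        n_replicates: int = 30,
        mode: str = "approx",
    ):
        if panel.member_sets is None:
            raise ValueError("the model needs a panel with member variant sets")
        self.panel = panel
        self.weighted = weighted
        self.grid = tuple(grid)
        self.n_replicates = n_replicates
        self.mode = mode

    @classmethod
    def from_variant_sets(
        cls, members: Sequence[VariantSet], population: str = "reference", **kwargs
    ) -> "GenotypeAccuracyModel":
        return cls(build_panel(members, population), **kwargs)

    def fit(self, seed: int = 0) -> "GenotypeAccuracyResults":
        panel_D = distance_matrix(self.panel.member_sets, self.panel, weighted=self.weighted)
        stats = reference_stats(panel_D)
        curve = build_curve(
            self.panel,
            grid=self.grid,
            n_replicates=self.n_replicates,
            mode=self.mode,
            seed=seed,
            stats=stats,
            weighted=self.weighted,
        )
        return GenotypeAccuracyResults(self, panel_D, stats, curve, seed)


class GenotypeAccuracyResults:
    """Fitted calibration: panel distances, SDS statistics, reference curve."""

    def __init__(
        self,
        model: GenotypeAccuracyModel,
        panel_D: DistanceMatrix,
        stats: ReferenceStats,
        curve: ReferenceCurve,
        seed: int,
    ):
        self.model = model
        self.panel_D = panel_D
        self.ref_stats = stats
        self.curve = curve
        self.seed = seed

    def score(self, test: VariantSet) -> SampleScore:
        """SDS and genotyping-error estimate for one test sample."""
        result = sds(test, self.model.panel, self.ref_stats, weighted=self.model.weighted)
        return SampleScore(result, estimate_error(result.sds, self.curve))

    def embed(self, tests: Sequence[VariantSet] = (), seed: int = 0) -> Embedding:
        """Joint NMDS embedding of the panel members and any test samples."""
        sets = list(self.model.panel.member_sets) + list(tests)
        D = distance_matrix(sets, self.model.panel, weighted=self.model.weighted)
        return nmds(D, dims=2, seed=seed)

    def summary(self) -> str:
        panel = self.model.panel
        lines = [
            "Genotype accuracy calibration",
            "=" * 45,
            f"panel population      : {panel.population}",
            f"panel members (n)     : {panel.n}",
            f"variant sites         : {len(panel.sites)}",
            f"target region (bp)    : {panel.region.total_size}",
            f"metric                : {'frequency-weighted' if self.model.weighted else 'Hamming'}",
            f"reference median      : {self.ref_stats.ref_median:.6f}",
            f"reference IQR         : {self.ref_stats.ref_iqr:.6f}",
            f"curve mode            : {self.curve.metadata.get('mode')}"
            f" ({self.curve.n_replicates} replicates/point)",
            "",
            "  error rate    SDS median     5%        95%",
        ]
        for p, m, lo, hi in zip(
            self.curve.grid, self.curve.sds_median, self.curve.sds_q05, self.curve.sds_q95
        ):
            lines.append(f"  {p:10.2e}  {m:10.3f} {lo:9.3f} {hi:9.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<GenotypeAccuracyResults: n={self.model.panel.n}, "
            f"ref_median={self.ref_stats.ref_median:.4f}, "
            f"ref_iqr={self.ref_stats.ref_iqr:.4f}>"
        )
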