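"""Genotyping-error simulation and the accuracy definition.

Two simulation routes are provided.  *Explicit injection* perturbs a
variant set at K ~ Binomial(region_size, p) uniformly drawn positions with
false positives, false negatives and genotype swaps.  The *binomial
approximation* exploits the fact that most target positions have low
variability in the panel, so each error behaves as a disagreement at a
constrained site: the agreement sum is unchanged and the normalizing
constant grows by (per-error weight) x X with X ~ Binomial(N, p).

Genotyping accuracy is the percentage of the target region correctly
genotyped: 100 * (1 - p).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .distance import PairwiseDistance
from .types import BASES, GenomicSite, GenotypeCall, VariantSet

logger = logging.getLogger(__name__)

#: total size of the consensus exome target, in bp
EXOME_SIZE = 28_000_000


@dataclass
class ErrorModel:
    """Parameters of the genotyping-error process.

    p
        Per-position genotyping error probability.
    N
        Number of binomial trials for the approximation route; defaults to
        the consensus exome size and should be overridden with the actual
        target-region size when working at smaller scales.
    per_error_weight
        Weight each simulated error adds to the normalizing constant.
        ``None`` (default) resolves to the exact weight of an unseen
        genotype against a hom-ref panel background, 2(n+1)/(n+2), which
        tends to 2 for large panels; pass 2.0 to fix the large-panel value.
    mix
        Probabilities of (false positive, false negative, genotype swap)
        at each drawn error position.
    """

    p: float
    N: int = EXOME_SIZE
    per_error_weight: Optional[float] = None
    seed: int = 0
    mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError(f"error probability must lie in [0, 1], got {self.p}")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not np.isclose(sum(self.mix), 1.0):
            raise ValueError("error-type mix must sum to 1")

    def resolved_weight(self, n_ref: Optional[int] = None) -> float:
        if self.per_error_weight is not None:
            return self.per_error_weight
        if n_ref is None:
            return 2.0
        return 2.0 * (n_ref + 1) / (n_ref + 2)


@dataclass(frozen=True)
class AccuracyValue:
    """Genotyping accuracy as a percentage of the target region."""

    value: float

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 100:
            raise ValueError(f"accuracy percentage out of range: {self.value}")


def error_to_accuracy(p: float) -> AccuracyValue:
    """Accuracy = percentage of the target correctly genotyped = 100(1-p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"error rate must lie in [0, 1], got {p}")
    return AccuracyValue(100.0 * (1.0 - p))


def expected_errors(p: float, window_bp: int) -> float:
    """Expected number of genotyping errors in a window of ``window_bp``."""
    if window_bp < 1:
        raise ValueError("window must be >= 1 bp")
    if not 0 <= p <= 1:
        raise ValueError(f"error rate must lie in [0, 1], got {p}")
    return p * window_bp


def _random_fp_call(
    chrom: str, pos: int, rng: np.random.Generator, ref: Optional[str] = None
) -> GenotypeCall:
    """A spurious heterozygous call at a hom-ref position."""
    if ref is None:
        ref = BASES[rng.integers(4)]
    alt = BASES[(BASES.index(ref) + 1 + rng.integers(3)) % 4]
    site = GenomicSite(chrom, pos, ref)
    return GenotypeCall(site, (ref, alt))


def inject_errors(
    x: VariantSet, model: ErrorModel, rng: Optional[np.random.Generator] = None
) -> VariantSet:
    """Explicitly perturb a variant set at random target positions.

    Draws K ~ Binomial(region_size, p) distinct positions uniformly over
    the target region; at each, one error type is drawn from ``model.mix``:
    false positive (spurious het at a hom-ref position), false negative
    (an existing call deleted), or genotype swap (het <-> hom-alt).  Error
    types that do not apply at the drawn position fall back to the
    applicable one.  The tally of applied error types is recorded in the
    output's ``metadata['error_tally']``.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    region = x.region
    k = int(rng.binomial(region.total_size, model.p))
    out = x.copy()
    tally = {"n_fp": 0, "n_fn": 0, "n_swap": 0}
    if k == 0:
        out.metadata["error_tally"] = tally
        return out
    offsets = rng.choice(region.total_size, size=k, replace=False)
    kinds = rng.choice(3, size=k, p=model.mix)
    for offset, kind in zip(offsets, kinds):
        chrom, pos = region.position_at(int(offset))
        existing = out.calls.get((chrom, pos))
        if existing is None:
            # only a false positive is possible at an uncalled position
            out.add(_random_fp_call(chrom, pos, rng))
            tally["n_fp"] += 1
            continue
        if kind == 0:
            kind = 2  # position already called: perturb the genotype instead
        if kind == 1:
            out.drop(chrom, pos)
            tally["n_fn"] += 1
            continue
        site = existing.site
        ref = site.ref_allele
        a, b = existing.alleles
        if a == b:  # hom-alt -> ref het
            new = GenotypeCall(site, (ref, a))
        elif ref in (a, b):  # ref het -> hom-alt
            alt = b if a == ref else a
            new = GenotypeCall(site, (alt, alt))
        else:  # non-ref het -> one of its hom-alts
            alt = (a, b)[rng.integers(2)]
            new = GenotypeCall(site, (alt, alt))
        out.calls[site.key] = new
        tally["n_swap"] += 1
    out.metadata["error_tally"] = tally
    return out


def approx_error_distance(
    clean_pair: PairwiseDistance,
    model: ErrorModel,
    n_ref: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    x_draw: Optional[int] = None,
) -> PairwiseDistance:
    """Binomial approximation of the distance after simulated errors.

    The agreement sum A = (1-d)C is left unchanged; the normalizing
    constant grows by w*X with X ~ Binomial(N, p).  ``x_draw`` allows the
    caller to share one X across all pairings of a simulated sample.
    """
    if x_draw is None:
        if rng is None:
            rng = np.random.default_rng(model.seed)
        x_draw = int(rng.binomial(model.N, model.p))
    w = model.resolved_weight(n_ref)
    agreement = (1.0 - clean_pair.value) * clean_pair.c_norm
    c_new = clean_pair.c_norm + w * x_draw
    if c_new <= 0:
        return clean_pair
    return PairwiseDistance(1.0 - agreement / c_new, clean_pair.union_size, c_new)
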