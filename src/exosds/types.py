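"""Core data model: genomic sites, diploid genotype calls, variant sets, target regions.

A *variant set* is the collection of positions where a sample's called
genotype differs from the reference sequence.  Positions absent from the
call map are implicitly homozygous reference; this convention is what makes
the weighted distance sensitive to false-negative calls.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

BASES = ("A", "C", "G", "T")

#: all unordered diploid genotypes over {A,C,G,T}, in canonical order
GENOTYPE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (a, b) for i, a in enumerate(BASES) for b in BASES[i:]
)
PAIR_CODE: dict[tuple[str, str], int] = {p: i for i, p in enumerate(GENOTYPE_PAIRS)}
#: genotype code of the homozygous-reference genotype for each reference base
HOMREF_CODE: dict[str, int] = {b: PAIR_CODE[(b, b)] for b in BASES}

_TRANSITIONS = {frozenset(("A", "G")), frozenset(("C", "T"))}


def is_transition(ref: str, alt: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    return frozenset((ref, alt)) in _TRANSITIONS


@dataclass(frozen=True, slots=True)
class GenomicSite:
    """A single genomic position (1-based) with its reference base."""

    chrom: str
    pos: int
    ref_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in BASES:
            raise ValueError(f"reference allele must be one of {BASES}, got {self.ref_allele!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """An unordered diploid genotype at a site; A/G and G/A compare equal."""

    site: GenomicSite
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a not in BASES or b not in BASES:
            raise ValueError(f"alleles must be single uppercase bases, got {self.alleles!r}")
        if a > b:  # canonicalize: lexicographic order
            object.__setattr__(self, "alleles", (b, a))

    @property
    def is_hom_ref(self) -> bool:
        r = self.site.ref_allele
        return self.alleles == (r, r)

    @property
    def is_het(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    @property
    def code(self) -> int:
        """Integer genotype code (0..9), shared with the vectorized engine."""
        return PAIR_CODE[self.alleles]

    def gt_string(self) -> str:
        return f"{self.alleles[0]}/{self.alleles[1]}"


def hom_ref_call(site: GenomicSite) -> GenotypeCall:
    return GenotypeCall(site, (site.ref_allele, site.ref_allele))


class TargetRegion:
    """A set of genomic intervals (0-based, half-open) defining the target.

    Intervals are merged and sorted on construction.  ``total_size`` is the
    number of base pairs covered; ``position_at`` maps a linear 0-based
    offset into the region onto a (chrom, 1-based position) pair, which the
    error simulator uses to draw uniform positions.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(intervals, key=lambda t: (t[0], t[1], t[2])):
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], end))
            else:
                merged.append((chrom, start, end))
        if not merged:
            raise ValueError("target region is empty")
        self.intervals: list[tuple[str, int, int]] = merged
        self.total_size: int = sum(e - s for _, s, e in merged)
        # per-chromosome sorted interval bounds, for membership tests
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, s, e in merged:
            self._starts.setdefault(chrom, []).append(s)
            self._ends.setdefault(chrom, []).append(e)
        # cumulative sizes, for offset -> position mapping
        self._cum: list[int] = []
        acc = 0
        for _, s, e in merged:
            acc += e - s
            self._cum.append(acc)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        i = bisect.bisect_right(starts, pos - 1) - 1
        return i >= 0 and pos - 1 < self._ends[chrom][i]

    def position_at(self, offset: int) -> tuple[str, int]:
        """Map linear offset in [0, total_size) to (chrom, 1-based pos)."""
        if not 0 <= offset < self.total_size:
            raise IndexError(f"offset {offset} outside region of size {self.total_size}")
        i = bisect.bisect_right(self._cum, offset)
        chrom, start, _ = self.intervals[i]
        prev = self._cum[i - 1] if i else 0
        return chrom, start + (offset - prev) + 1

    @property
    def chroms(self) -> list[str]:
        seen: list[str] = []
        for chrom, _, _ in self.intervals:
            if chrom not in seen:
                seen.append(chrom)
        return seen

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetRegion) and self.intervals == other.intervals

    def __hash__(self) -> int:
        return hash(tuple(self.intervals))

    def __repr__(self) -> str:
        return f"TargetRegion({len(self.intervals)} intervals, {self.total_size} bp)"


class VariantSet:
    """One sample's non-reference genotype calls over a target region."""

    def __init__(
        self,
        sample_id: str,
        region: TargetRegion,
        calls: Optional[dict[tuple[str, int], GenotypeCall]] = None,
        metadata: Optional[dict] = None,
        validate: bool = True,
    ):
        self.sample_id = sample_id
        self.region = region
        self.calls: dict[tuple[str, int], GenotypeCall] = dict(calls or {})
        self.metadata: dict = metadata or {}
        if validate:
            for (chrom, pos), call in self.calls.items():
                self._check(chrom, pos, call)

    def _check(self, chrom: str, pos: int, call: GenotypeCall) -> None:
        if (chrom, pos) != call.site.key:
            raise ValueError(f"call keyed at {chrom}:{pos} but sited at {call.site.key}")
        if call.is_hom_ref:
            raise ValueError(f"hom-ref genotype at {chrom}:{pos} does not belong in a variant set")
        if not self.region.contains(chrom, pos):
            raise ValueError(f"call at {chrom}:{pos} lies outside the target region")

    def add(self, call: GenotypeCall) -> None:
        self._check(*call.site.key, call)
        self.calls[call.site.key] = call

    def drop(self, chrom: str, pos: int) -> None:
        del self.calls[(chrom, pos)]

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    def copy(self, sample_id: Optional[str] = None) -> "VariantSet":
        return VariantSet(
            sample_id or self.sample_id,
            self.region,
            dict(self.calls),
            dict(self.metadata),
            validate=False,
        )

    def __iter__(self) -> Iterator[GenotypeCall]:
        return iter(self.calls.values())

    def __repr__(self) -> str:
        return f"VariantSet({self.sample_id!r}, {self.n_calls} calls)"
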