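"""Reference panels: per-site genotype counts and frequencies.

The genotype frequency of genotype *g* at a site is its count among the *n*
panel individuals divided by *n*; individuals with no call at a site count
toward the implicit homozygous-reference genotype.  A genotype never
observed in the panel is assigned the pseudo-frequency 1/(n+1), which caps
the weight any single disagreement can carry at n+1.  The same floor is
applied to the hom-ref genotype at sites where every panel member carries a
variant, so weights stay finite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    BASES,
    GENOTYPE_PAIRS,
    HOMREF_CODE,
    PAIR_CODE,
    GenomicSite,
    GenotypeCall,
    TargetRegion,
    VariantSet,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]
N_CODES = len(GENOTYPE_PAIRS)


@dataclass
class PanelSite:
    """Genotype tally at one panel site; hom-ref counts are implicit."""

    ref_allele: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def explicit_total(self) -> int:
        return sum(self.counts.values())


class ReferencePanel:
    """Per-site genotype counts for a population of n diploid individuals."""

    def __init__(
        self,
        n: int,
        population: str,
        sites: dict[tuple[str, int], PanelSite],
        region: TargetRegion,
        member_sets: Optional[list[VariantSet]] = None,
    ):
        if n < 1:
            raise ValueError("reference panel needs at least one individual")
        self.n = n
        self.population = population
        self.sites = sites
        self.region = region
        self.member_sets = member_sets
        #: populated by the synthetic generator: {pop: (sites, alts, freqs)}
        self.sim_freqs: Optional[dict] = None
        self.metadata: dict = {}
        self._index: Optional["PanelIndex"] = None

    @property
    def unseen_frequency(self) -> float:
        return 1.0 / (self.n + 1)

    @property
    def member_ids(self) -> Optional[list[str]]:
        if self.member_sets is None:
            return None
        return [vs.sample_id for vs in self.member_sets]

    @property
    def index(self) -> "PanelIndex":
        if self._index is None:
            self._index = PanelIndex(self)
        return self._index

    def __repr__(self) -> str:
        return (
            f"ReferencePanel({self.population!r}, n={self.n}, "
            f"{len(self.sites)} variant sites)"
        )


def build_panel(variant_sets: Sequence[VariantSet], population: str) -> ReferencePanel:
    """Tally per-site genotype counts over a list of member variant sets."""
    if not variant_sets:
        raise ValueError("cannot build a panel from zero variant sets")
    region = variant_sets[0].region
    for vs in variant_sets[1:]:
        if vs.region != region:
            raise ValueError("all panel members must share one target region")
    sites: dict[tuple[str, int], PanelSite] = {}
    for vs in variant_sets:
        for key, call in vs.calls.items():
            entry = sites.get(key)
            if entry is None:
                entry = sites[key] = PanelSite(call.site.ref_allele)
            entry.counts[call.alleles] = entry.counts.get(call.alleles, 0) + 1
    return ReferencePanel(
        len(variant_sets), population, sites, region, member_sets=list(variant_sets)
    )


def genotype_frequency(
    panel: ReferencePanel, site: GenomicSite, g: GenotypeCall
) -> float:
    """Frequency of genotype ``g`` at ``site`` under the panel's counts.

    Returns count/n for observed genotypes, the implicit hom-ref remainder
    for the reference genotype, and 1/(n+1) for genotypes never seen in the
    panel.  At sites the panel does not list, hom-ref has frequency 1.
    """
    if not panel.region.contains(site.chrom, site.pos):
        raise ValueError(f"site {site.chrom}:{site.pos} outside the panel region")
    n = panel.n
    entry = panel.sites.get(site.key)
    is_hom_ref = g.alleles == (site.ref_allele, site.ref_allele)
    if entry is None:
        return 1.0 if is_hom_ref else panel.unseen_frequency
    if is_hom_ref:
        remainder = n - entry.explicit_total
        return remainder / n if remainder >= 1 else panel.unseen_frequency
    count = entry.counts.get(g.alleles, 0)
    return count / n if count >= 1 else panel.unseen_frequency


class PanelIndex:
    """Vectorized view of a panel: site order, per-genotype frequency tables.

    Besides the floored full-panel frequency table (count/n, unseen
    genotypes at 1/(n+1)), the index exposes *raw* (unfloored) frequency
    tables used by the exchangeable weighting mode, in which each compared
    sample's own genotype copy — and, at agreement sites, the partner's
    copy — is removed from the counts before flooring.  That makes a panel
    member's weights the same function of the *other* individuals'
    genotypes as an external sample's.
    """

    def __init__(self, panel: ReferencePanel):
        self.panel = panel
        self.positions: list[tuple[str, int]] = sorted(panel.sites)
        self.pos_index: dict[tuple[str, int], int] = {
            k: i for i, k in enumerate(self.positions)
        }
        n = panel.n
        n_sites = len(self.positions)
        self.homref_codes = np.empty(n_sites, dtype=np.int8)
        # per-site genotype counts; the hom-ref column holds the implicit
        # remainder n - sum(explicit counts)
        counts = np.zeros((n_sites, N_CODES), dtype=np.int64)
        for i, key in enumerate(self.positions):
            entry = panel.sites[key]
            hr = HOMREF_CODE[entry.ref_allele]
            self.homref_codes[i] = hr
            counts[i, hr] = n - entry.explicit_total
            for alleles, count in entry.counts.items():
                counts[i, PAIR_CODE[alleles]] = count
        self.freq_full = np.where(counts >= 1, counts / n, panel.unseen_frequency)
        self.raw_full = counts / n
        self.raw_loo = (counts - 1) / n  # the encoded member's own copy removed
        self._member_matrix: dict[bool, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def unseen(self) -> float:
        return self.panel.unseen_frequency

    def is_member(self, vs: VariantSet) -> bool:
        ids = self.panel.member_ids
        return ids is not None and vs.sample_id in ids

    def encode(
        self, vs: VariantSet, loo: bool = False, raw: bool = False
    ) -> tuple[np.ndarray, np.ndarray, list]:
        """Encode a variant set over the panel site universe.

        Returns (codes, freqs, extras): genotype codes and their panel
        frequencies at every panel site (hom-ref where uncalled), plus the
        list of calls at positions the panel does not list.  With ``raw``
        the frequencies are unfloored counts/n (own copy removed when
        ``loo``); otherwise the floored full-panel frequencies.
        """
        loo = bool(loo and self.panel.n >= 2)
        if raw:
            table = self.raw_loo if loo else self.raw_full
        else:
            table = self.freq_full
        codes = self.homref_codes.copy()
        freqs = table[np.arange(len(self.positions)), self.homref_codes].copy()
        extras = []
        for key, call in vs.calls.items():
            i = self.pos_index.get(key)
            if i is None:
                extras.append(call)
            else:
                code = call.code
                codes[i] = code
                freqs[i] = table[i, code]
        return codes, freqs, extras

    def member_matrix(self, loo: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(codes, raw freqs) of shape (n_members, n_sites) for panel members."""
        loo = bool(loo and self.panel.n >= 2)
        if loo not in self._member_matrix:
            if self.panel.member_sets is None:
                raise ValueError("panel has no member variant sets")
            rows = [self.encode(vs, loo=loo, raw=True) for vs in self.panel.member_sets]
            for _, _, extras in rows:
                if extras:  # members define the panel sites, so this is a bug
                    raise ValueError("panel member carries a call at a non-panel site")
            codes = np.stack([r[0] for r in rows])
            freqs = np.stack([r[1] for r in rows])
            self._member_matrix[loo] = (codes, freqs)
        return self._member_matrix[loo]


def write_panel_tsv(panel: ReferencePanel, path: PathLike) -> None:
    """Serialize panel genotype counts as a TSV (CHROM POS REF GT COUNT N)."""
    rows = []
    for (chrom, pos) in sorted(panel.sites):
        entry = panel.sites[(chrom, pos)]
        for alleles in sorted(entry.counts):
            rows.append(
                (chrom, pos, entry.ref_allele, f"{alleles[0]}/{alleles[1]}",
                 entry.counts[alleles], panel.n)
            )
    df = pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "GT", "COUNT", "N"])
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(
    path: PathLike, region: TargetRegion, population: str = "panel"
) -> ReferencePanel:
    """Load a panel from its TSV serialization (no member sets)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    required = {"CHROM", "POS", "REF", "GT", "COUNT", "N"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel TSV missing columns {required - set(df.columns)}")
    if df.empty:
        raise ValueError("panel TSV contains no sites")
    n_values = df["N"].unique()
    if len(n_values) != 1:
        raise ValueError("panel TSV mixes different panel sizes N")
    sites: dict[tuple[str, int], PanelSite] = {}
    for row in df.itertuples(index=False):
        key = (row.CHROM, int(row.POS))
        entry = sites.get(key)
        if entry is None:
            entry = sites[key] = PanelSite(row.REF)
        a, b = row.GT.split("/")
        entry.counts[tuple(sorted((a, b)))] = int(row.COUNT)
    return ReferencePanel(int(n_values[0]), population, sites, region)


def assign_cluster(test: VariantSet, panels: Sequence[ReferencePanel]) -> str:
    """Assign a test sample to the population with smallest median distance.

    Requires panels built from member variant sets.  Ties are broken
    lexicographically on the population label (with a warning).
    """
    from .distance import distances_to_members  # local import: avoid cycle

    usable = [p for p in panels if p.member_sets]
    if not usable:
        raise ValueError("no panel provides member variant sets")
    scores: list[tuple[float, str]] = []
    for panel in usable:
        d = distances_to_members(test, panel)
        scores.append((float(np.median(d)), panel.population))
    scores.sort(key=lambda t: (t[0], t[1]))
    if len(scores) > 1 and np.isclose(scores[0][0], scores[1][0]):
        logger.warning(
            "test sample %s equidistant to clusters %s and %s; choosing %s",
            test.sample_id, scores[0][1], scores[1][1], scores[0][1],
        )
    return scores[0][1]
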