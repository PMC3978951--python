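"""Conventional variant-set QC statistics.

These are the community-standard indicators the weighted-distance score is
meant to complement: the transition/transversion ratio (~3:1 expected for
coding exons), the fraction of calls already catalogued in dbSNP-style
databases, the variance of the heterozygous allele fraction (sensitive to
amplification artifacts), flanking GC content (GC-biased coverage dropout
raises the false-negative rate), and allele-frequency concordance between
two sample groups of the same ancestry.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from cyvcf2 import VCF
from pyfaidx import Fasta

from .types import GenomicSite, TargetRegion, VariantSet, is_transition

PathLike = Union[str, Path]


@dataclass(frozen=True)
class QcReport:
    titv: Optional[float]
    dbsnp_fraction: Optional[float]
    het_af_variance: Optional[float]
    n_variants: int

    def to_dict(self) -> dict:
        return {
            "titv": self.titv,
            "dbsnp_fraction": self.dbsnp_fraction,
            "het_af_variance": self.het_af_variance,
            "n_variants": self.n_variants,
        }


def titv_ratio(x: VariantSet) -> float:
    """Transitions (A<->G, C<->T) over transversions among called alts."""
    if x.n_calls == 0:
        raise ValueError("empty variant set")
    ti = tv = 0
    for call in x:
        ref = call.site.ref_allele
        for alt in set(call.alleles):
            if alt == ref:
                continue
            if is_transition(ref, alt):
                ti += 1
            else:
                tv += 1
    if tv == 0:
        raise ValueError(f"no transversions among {ti} transitions; ratio undefined")
    return ti / tv


def dbsnp_fraction(x: VariantSet, known: set[tuple[str, int]]) -> float:
    """Fraction of called sites present in a known-sites catalogue."""
    if x.n_calls == 0:
        raise ValueError("empty variant set")
    if not known:
        raise ValueError("known-sites set is empty")
    hits = sum(1 for key in x.calls if key in known)
    return hits / x.n_calls


def het_af_variance(vcf_path: PathLike, region: TargetRegion, ddof: int = 1) -> float:
    """Variance of the alternate-read fraction at heterozygous SNV calls.

    Requires the AD (allele depth) FORMAT field; calls with zero total
    depth are skipped.
    """
    vcf = VCF(str(vcf_path))
    fractions: list[float] = []
    saw_ad = False
    for rec in vcf:
        if len(rec.REF) != 1 or not region.contains(rec.CHROM, rec.POS):
            continue
        gt = rec.genotypes[0]
        if len(gt) != 3:
            continue
        a1, a2 = gt[0], gt[1]
        if a1 < 0 or a2 < 0 or a1 == a2:  # want called heterozygotes
            continue
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            continue
        saw_ad = True
        depths = np.asarray(ad[0], dtype=np.float64)
        depths[depths < 0] = 0  # missing entries encode as negative
        total = depths.sum()
        if total <= 0:
            continue
        alt_idx = max(a1, a2)
        if alt_idx >= depths.size:
            continue
        fractions.append(float(depths[alt_idx] / total))
    if not saw_ad:
        raise ValueError(f"{vcf_path}: no AD field on heterozygous records")
    if len(fractions) < 2:
        raise ValueError(f"{vcf_path}: fewer than 2 usable heterozygous calls")
    return float(np.var(fractions, ddof=ddof))


def flanking_gc(
    sites: Sequence[GenomicSite], fasta: PathLike, flank_bp: int = 100
) -> list[float]:
    """GC fraction of the +/- ``flank_bp`` window around each site.

    The variant base itself is excluded; N bases are excluded from the
    denominator.  Raises if a window runs past the contig bounds.
    """
    fa = Fasta(str(fasta))
    out: list[float] = []
    for site in sites:
        if site.chrom not in fa:
            raise ValueError(f"contig {site.chrom} not in {fasta}")
        contig_len = len(fa[site.chrom])
        start = site.pos - 1 - flank_bp
        end = site.pos + flank_bp
        if start < 0 or end > contig_len:
            raise ValueError(
                f"flanking window of {site.chrom}:{site.pos} exceeds contig bounds"
            )
        seq = str(fa[site.chrom][start:end]).upper()
        window = seq[:flank_bp] + seq[flank_bp + 1 :]  # drop the site base
        gc = sum(1 for b in window if b in "GC")
        acgt = sum(1 for b in window if b in "ACGT")
        if acgt == 0:
            raise ValueError(f"window of {site.chrom}:{site.pos} is all N")
        out.append(gc / acgt)
    return out


def _group_allele_freqs(
    group: Sequence[VariantSet],
) -> tuple[dict[tuple[str, int], float], dict[tuple[str, int], int]]:
    """Variant-allele frequency and carrier count per site over a group."""
    m = len(group)
    counts: dict[tuple[str, int], int] = {}
    carriers: dict[tuple[str, int], int] = {}
    for vs in group:
        for key, call in vs.calls.items():
            ref = call.site.ref_allele
            counts[key] = counts.get(key, 0) + sum(1 for a in call.alleles if a != ref)
            carriers[key] = carriers.get(key, 0) + 1
    return {key: c / (2 * m) for key, c in counts.items()}, carriers


@dataclass(frozen=True)
class ConcordancePoint:
    site: tuple[str, int]
    freq_a: float
    freq_b: float
    carriers_a: int
    carriers_b: int
    sd_bound: float
    outlier: bool


def af_concordance(
    group_a: Sequence[VariantSet],
    group_b: Sequence[VariantSet],
    n_sd: float = 2.0,
) -> list[ConcordancePoint]:
    """Per-site allele-frequency pairs between two same-ancestry groups.

    The binomial envelope for each site uses the pooled frequency p-hat:
    SD = sqrt(p(1-p)/(2 m_a) + p(1-p)/(2 m_b)); a pair further than
    ``n_sd`` standard deviations off the diagonal is flagged as an
    outlier.  Under-called common variants in group_b surface as outliers
    below the diagonal.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    m_a, m_b = len(group_a), len(group_b)
    fa, ca = _group_allele_freqs(group_a)
    fb, cb = _group_allele_freqs(group_b)
    points: list[ConcordancePoint] = []
    for key in sorted(set(fa) | set(fb)):
        pa = fa.get(key, 0.0)
        pb = fb.get(key, 0.0)
        pooled = (pa * 2 * m_a + pb * 2 * m_b) / (2 * m_a + 2 * m_b)
        sd = float(np.sqrt(pooled * (1 - pooled) * (1 / (2 * m_a) + 1 / (2 * m_b))))
        outlier = abs(pa - pb) > n_sd * sd if sd > 0 else pa != pb
        points.append(
            ConcordancePoint(key, pa, pb, ca.get(key, 0), cb.get(key, 0), n_sd * sd, outlier)
        )
    return points


def dropout_candidates(
    points: Iterable[ConcordancePoint],
    m_a: int,
    ref_carrier_min: float = 0.5,
    test_carriers_max: int = 1,
) -> list[ConcordancePoint]:
    """Sites common in the reference group but nearly absent in the test
    group — the default false-negative outlier filter (carried by more
    than half the reference individuals, by at most one test sample)."""
    return [
        pt
        for pt in points
        if pt.carriers_a > ref_carrier_min * m_a and pt.carriers_b <= test_carriers_max
    ]


def qc_report(
    x: VariantSet,
    known: Optional[set[tuple[str, int]]] = None,
    vcf_path: Optional[PathLike] = None,
) -> QcReport:
    """Bundle the per-sample scalar QC metrics that are computable from
    the available inputs; metrics lacking inputs are reported as None."""
    try:
        titv = titv_ratio(x)
    except ValueError:
        titv = None
    dbsnp = None
    if known:
        try:
            dbsnp = dbsnp_fraction(x, known)
        except ValueError:
            dbsnp = None
    het_var = None
    if vcf_path is not None:
        try:
            het_var = het_af_variance(vcf_path, x.region)
        except ValueError:
            het_var = None
    return QcReport(titv, dbsnp, het_var, x.n_calls)
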