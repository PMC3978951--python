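"""Reading and writing variant call sets, target regions and known-site lists.

VCF parsing goes through :mod:`cyvcf2`.  Only biallelic-style SNV genotypes
are retained: multiallelic SNV records are resolved through the sample's GT
(a 1/2 call over ALT C,T becomes the genotype C/T), indels and symbolic
alleles are dropped, and no-call genotypes are treated as homozygous
reference (i.e. absent from the call map).  Coordinates are 1-based
internally; the BED boundary is the only place 0-based half-open intervals
appear.
"""
from __future__ import annotations

import gzip
import io
import logging
from collections import Counter
from pathlib import Path
from typing import Optional, Union

from cyvcf2 import VCF

from .types import BASES, GenomicSite, GenotypeCall, TargetRegion, VariantSet

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _open_text(path: PathLike):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_target_region(bed_path: PathLike) -> TargetRegion:
    """Read a BED3+ file into a merged, sorted :class:`TargetRegion`."""
    intervals: list[tuple[str, int, int]] = []
    with _open_text(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected at least 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{bed_path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    if not intervals:
        raise ValueError(f"{bed_path}: no intervals found")
    return TargetRegion(intervals)


def read_variant_set(
    vcf_path: PathLike,
    region: TargetRegion,
    sample: Optional[str] = None,
    keep_filtered: bool = False,
) -> VariantSet:
    """Load one sample's SNV calls from a VCF, restricted to ``region``.

    Records failing FILTER (anything other than PASS or '.'), indels,
    symbolic alleles, hom-ref and no-call genotypes, and non-diploid
    genotypes are dropped; drop counts are logged.
    """
    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    if sample is None:
        if len(samples) > 1:
            raise ValueError(
                f"{vcf_path} contains {len(samples)} samples; a sample name is required"
            )
        sample_id = samples[0] if samples else Path(str(vcf_path)).stem
        sidx = 0
    else:
        if sample not in samples:
            raise ValueError(f"sample {sample!r} not found in {vcf_path}")
        sample_id = sample
        sidx = samples.index(sample)

    dropped: Counter = Counter()
    vs = VariantSet(sample_id, region)
    for rec in vcf:
        if not keep_filtered and rec.FILTER is not None:  # None <=> PASS or '.'
            dropped["filter"] += 1
            continue
        ref = rec.REF.upper()
        if len(ref) != 1 or ref not in BASES:
            dropped["non_snv"] += 1
            continue
        try:
            gt = rec.genotypes[sidx]
        except (IndexError, TypeError):
            dropped["malformed_gt"] += 1
            logger.warning("malformed genotype at %s:%d; record rejected", rec.CHROM, rec.POS)
            continue
        if len(gt) != 3:  # [allele1, allele2, phased] for diploid calls
            dropped["ploidy"] += 1
            logger.warning("non-diploid genotype at %s:%d; record rejected", rec.CHROM, rec.POS)
            continue
        a1, a2 = gt[0], gt[1]
        if a1 < 0 or a2 < 0:  # ./. or half-called -> hom-ref convention
            dropped["no_call"] += 1
            continue
        if a1 == 0 and a2 == 0:
            dropped["hom_ref"] += 1
            continue
        alleles = []
        ok = True
        for ai in (a1, a2):
            allele = ref if ai == 0 else (rec.ALT[ai - 1].upper() if ai - 1 < len(rec.ALT) else "")
            if len(allele) != 1 or allele not in BASES:
                ok = False
                break
            alleles.append(allele)
        if not ok:
            dropped["non_snv"] += 1
            continue
        if not region.contains(rec.CHROM, rec.POS):
            dropped["outside_region"] += 1
            continue
        site = GenomicSite(rec.CHROM, rec.POS, ref)
        if site.key in vs.calls:
            dropped["duplicate_site"] += 1
            continue
        vs.add(GenotypeCall(site, (alleles[0], alleles[1])))
    if dropped:
        logger.info(
            "%s: kept %d calls, dropped %s", vcf_path, vs.n_calls, dict(dropped)
        )
    vs.metadata["dropped"] = dict(dropped)
    return vs


def write_variant_set(vs: VariantSet, path: PathLike) -> None:
    """Write a variant set as a minimal single-sample VCF v4.2."""
    chrom_order = {c: i for i, c in enumerate(vs.region.chroms)}
    keys = sorted(vs.calls, key=lambda k: (chrom_order.get(k[0], len(chrom_order)), k[1]))
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chrom_max: dict[str, int] = {}
        for chrom, _, end in vs.region.intervals:
            chrom_max[chrom] = max(chrom_max.get(chrom, 0), end)
        for chrom in vs.region.chroms:
            fh.write(f"##contig=<ID={chrom},length={chrom_max[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + vs.sample_id + "\n"
        )
        for key in keys:
            call = vs.calls[key]
            ref = call.site.ref_allele
            alts = sorted({a for a in call.alleles if a != ref})
            allele_index = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
            gt = "/".join(str(allele_index[a]) for a in call.alleles)
            fh.write(
                f"{call.site.chrom}\t{call.site.pos}\t.\t{ref}\t{','.join(alts)}"
                f"\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_known_sites(path: PathLike) -> set[tuple[str, int]]:
    """Read a known-sites list (dbSNP-style) from a VCF or a CHROM/POS TSV."""
    spath = str(path)
    stem = spath[:-3] if spath.endswith(".gz") else spath
    if stem.endswith((".vcf", ".bcf")):
        return {(rec.CHROM, rec.POS) for rec in VCF(spath)}
    sites: set[tuple[str, int]] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].upper() == "CHROM":
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected CHROM<TAB>POS")
            try:
                sites.add((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer position {fields[1]!r}") from exc
    return sites
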