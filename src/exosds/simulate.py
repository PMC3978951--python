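"""Synthetic reference panels and test samples.

The generator emulates the statistical structure the method relies on: a
target region, variant sites placed uniformly over it, an ancestral allele
frequency drawn from a rare-variant-dominated spectrum (density
proportional to 1/x, truncated to [1/(2n), 0.5], by default),
population-specific frequencies via the Balding-Nichols model when a
divergence parameter F > 0 is given, and Hardy-Weinberg genotypes per
individual.  Everything is deterministic under the spec's seed.

Default scale — 100 individuals, a 1 Mb region, 5,000 variant sites — is a
proportional scale-down of a consensus exome (28 Mb, ~15,000 variants per
sample) at which the full pipeline runs in seconds.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ErrorModel, inject_errors
from .reference_panel import ReferencePanel, build_panel, write_panel_tsv
from .types import BASES, GenomicSite, GenotypeCall, TargetRegion, VariantSet
from .variant_io import write_variant_set

PathLike = Union[str, Path]


@dataclass
class PanelSpec:
    """Specification of a synthetic reference panel.

    ``af_spectrum`` is one of ``"neutral_1_over_x"`` (density ~ 1/x on
    [1/(2n), 0.5]), ``("beta", a, b)`` or ``("uniform", lo, hi)``.
    ``populations`` lists (label, F) pairs; F is the Balding-Nichols
    divergence from the shared ancestral frequency.
    """

    n_individuals: int = 100
    region_size: int = 1_000_000
    n_variant_sites: int = 5_000
    af_spectrum: Union[str, tuple] = "neutral_1_over_x"
    populations: Sequence[tuple[str, float]] = (("POP1", 0.0),)
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variant_sites > self.region_size:
            raise ValueError("more variant sites than base pairs in the region")
        if self.n_individuals < 1 or self.n_variant_sites < 1:
            raise ValueError("need at least one individual and one site")
        for label, f_div in self.populations:
            if not 0 <= f_div < 1:
                raise ValueError(f"divergence F for {label} must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "region_size": self.region_size,
            "n_variant_sites": self.n_variant_sites,
            "af_spectrum": list(self.af_spectrum)
            if isinstance(self.af_spectrum, tuple)
            else self.af_spectrum,
            "populations": [list(p) for p in self.populations],
            "chrom": self.chrom,
            "seed": self.seed,
        }


def _draw_ancestral_freqs(spec: PanelSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.n_variant_sites
    spectrum = spec.af_spectrum
    if spectrum == "neutral_1_over_x":
        lo = 1.0 / (2 * spec.n_individuals)
        hi = 0.5
        u = rng.random(s)
        return lo * (hi / lo) ** u  # inverse CDF of density ~ 1/x on [lo, hi]
    if isinstance(spectrum, tuple) and spectrum[0] == "beta":
        _, a, b = spectrum
        return np.clip(rng.beta(a, b, size=s), 1e-6, 1 - 1e-6)
    if isinstance(spectrum, tuple) and spectrum[0] == "uniform":
        _, lo, hi = spectrum
        if lo == hi:
            return np.full(s, float(lo))
        return rng.uniform(lo, hi, size=s)
    raise ValueError(f"unknown allele-frequency spectrum {spectrum!r}")


def _hwe_individual(
    sample_id: str,
    sites: Sequence[GenomicSite],
    alts: Sequence[str],
    freqs: np.ndarray,
    region: TargetRegion,
    rng: np.random.Generator,
) -> VariantSet:
    dosages = rng.binomial(2, freqs)
    calls = {}
    for site, alt, dos in zip(sites, alts, dosages):
        if dos == 0:
            continue
        alleles = (site.ref_allele, alt) if dos == 1 else (alt, alt)
        calls[site.key] = GenotypeCall(site, alleles)
    return VariantSet(sample_id, region, calls, validate=False)


def simulate_panel(spec: PanelSpec) -> tuple[ReferencePanel, list[VariantSet]]:
    """Generate a reference panel and its member variant sets.

    The returned panel records the per-population allele frequencies it
    was generated from (``panel.sim_freqs``) so matched test samples can
    be drawn later.
    """
    rng = np.random.default_rng(spec.seed)
    region = TargetRegion([(spec.chrom, 0, spec.region_size)])
    positions = np.sort(rng.choice(spec.region_size, spec.n_variant_sites, replace=False))
    refs = rng.integers(4, size=spec.n_variant_sites)
    alt_shift = 1 + rng.integers(3, size=spec.n_variant_sites)
    sites = [
        GenomicSite(spec.chrom, int(p) + 1, BASES[r]) for p, r in zip(positions, refs)
    ]
    alts = [BASES[(r + s) % 4] for r, s in zip(refs, alt_shift)]
    ancestral = _draw_ancestral_freqs(spec, rng)

    members: list[VariantSet] = []
    sim_freqs: dict[str, tuple] = {}
    n_pops = len(spec.populations)
    base = spec.n_individuals // n_pops
    sizes = [base + (1 if i < spec.n_individuals % n_pops else 0) for i in range(n_pops)]
    for (label, f_div), size in zip(spec.populations, sizes):
        if f_div > 0:
            a = ancestral * (1 - f_div) / f_div
            b = (1 - ancestral) * (1 - f_div) / f_div
            pop_freqs = np.clip(rng.beta(a, b), 0.0, 1.0)
        else:
            pop_freqs = ancestral
        sim_freqs[label] = (sites, alts, pop_freqs)
        for i in range(size):
            members.append(
                _hwe_individual(f"{label}_{i:04d}", sites, alts, pop_freqs, region, rng)
            )
    panel = build_panel(members, "+".join(label for label, _ in spec.populations))
    panel.sim_freqs = sim_freqs
    panel.metadata = {"spec": spec.to_dict()}
    return panel, members


def simulate_test_sample(
    panel: ReferencePanel,
    p_error: float,
    seed: int,
    population: Optional[str] = None,
    sample_id: Optional[str] = None,
) -> VariantSet:
    """Draw a fresh Hardy-Weinberg individual from a simulated panel's
    frequencies, then inject genotyping errors at rate ``p_error``."""
    if panel.sim_freqs is None:
        raise ValueError(
            "panel lacks generated allele frequencies; only panels from "
            "simulate_panel can seed matched test samples"
        )
    if population is None:
        population = next(iter(panel.sim_freqs))
    if population not in panel.sim_freqs:
        raise ValueError(f"unknown population {population!r}")
    rng = np.random.default_rng(seed)
    sites, alts, freqs = panel.sim_freqs[population]
    vs = _hwe_individual(
        sample_id or f"test_{population}_s{seed}", sites, alts, freqs, panel.region, rng
    )
    if p_error > 0:
        vs = inject_errors(vs, ErrorModel(p=p_error, N=panel.region.total_size), rng=rng)
    else:
        vs.metadata["error_tally"] = {"n_fp": 0, "n_fn": 0, "n_swap": 0}
    return vs


def write_fixture_bundle(
    panel: ReferencePanel,
    members: Sequence[VariantSet],
    out_dir: PathLike,
) -> dict[str, str]:
    """Write per-individual VCFs, the region BED, the panel TSV and a
    provenance JSON; returns the map of written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    bed = out / "target_region.bed"
    with open(bed, "w", encoding="utf-8") as fh:
        for chrom, start, end in panel.region.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    paths["bed"] = str(bed)
    tsv = out / "panel.tsv"
    write_panel_tsv(panel, tsv)
    paths["panel_tsv"] = str(tsv)
    vcf_dir = out / "members"
    vcf_dir.mkdir(exist_ok=True)
    for vs in members:
        vcf_path = vcf_dir / f"{vs.sample_id}.vcf"
        write_variant_set(vs, vcf_path)
        paths[vs.sample_id] = str(vcf_path)
    prov = out / "provenance.json"
    with open(prov, "w", encoding="utf-8") as fh:
        json.dump(getattr(panel, "metadata", {}), fh, indent=2)
    paths["provenance"] = str(prov)
    return paths
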