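"""Shared fixtures: hand-built panels and the default synthetic panel."""
from __future__ import annotations

import pytest

from exosds.model import GenotypeAccuracyModel
from exosds.reference_panel import PanelSite, ReferencePanel
from exosds.simulate import PanelSpec, simulate_panel
from exosds.types import GenomicSite, GenotypeCall, TargetRegion, VariantSet

#: seed fixing the default synthetic study conditions across the suite
PANEL_SEED = 42


def make_call(chrom: str, pos: int, ref: str, a: str, b: str) -> GenotypeCall:
    return GenotypeCall(GenomicSite(chrom, pos, ref), (a, b))


def make_set(sample_id, region, calls):
    """calls: iterable of (chrom, pos, ref, allele1, allele2)."""
    vs = VariantSet(sample_id, region)
    for chrom, pos, ref, a, b in calls:
        vs.add(make_call(chrom, pos, ref, a, b))
    return vs


@pytest.fixture
def tiny_region():
    return TargetRegion([("chr1", 0, 10_000)])


@pytest.fixture
def hand_panel(tiny_region):
    """n=10 panel with known counts at two sites.

    chr1:100 (ref A): C/T seen in 5 of 10 -> f(C/T)=0.5
    chr1:200 (ref C): T/T in 1, C/T in 3  -> f(T/T)=0.1, f(C/T)=0.3
    """
    sites = {
        ("chr1", 100): PanelSite("A", {("C", "T"): 5}),
        ("chr1", 200): PanelSite("C", {("T", "T"): 1, ("C", "T"): 3}),
    }
    return ReferencePanel(10, "hand", sites, tiny_region)


@pytest.fixture(scope="session")
def default_panel():
    """The default synthetic study conditions: n=100 members, 1 Mb region,
    5,000 variant sites, allele-frequency spectrum ~ 1/x."""
    panel, members = simulate_panel(PanelSpec(seed=PANEL_SEED))
    return panel, members


@pytest.fixture(scope="session")
def fitted_results(default_panel):
    """Fitted calibration (distances, reference stats, curve) shared by the
    slower end-to-end tests."""
    panel, _ = default_panel
    return GenotypeAccuracyModel(panel, mode="approx").fit(seed=1)


@pytest.fixture(scope="session")
def small_panel():
    """A quicker panel for tests that rebuild distance matrices repeatedly."""
    spec = PanelSpec(
        n_individuals=40, region_size=200_000, n_variant_sites=1_000, seed=7
    )
    panel, members = simulate_panel(spec)
    return panel, members
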