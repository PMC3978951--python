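"""Weighted distance: formula arithmetic, metric properties, oracle equality."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exosds.distance import (
    DistanceMatrix,
    _raw_frequency,
    distance_matrix,
    distances_to_members,
    indicator,
    pairwise_distance,
    weight,
)
from exosds.reference_panel import PanelSite, ReferencePanel, build_panel, genotype_frequency
from exosds.simulate import PanelSpec, simulate_panel, simulate_test_sample
from exosds.types import GenomicSite, TargetRegion, hom_ref_call

from conftest import make_call, make_set


class TestIndicator:
    def test_order_invariance(self):
        assert indicator(make_call("chr1", 5, "A", "A", "G"),
                         make_call("chr1", 5, "A", "G", "A")) == 1

    def test_disagreement(self):
        assert indicator(make_call("chr1", 5, "C", "C", "C"),
                         make_call("chr1", 5, "C", "C", "T")) == 0

    def test_homref_vs_homref(self):
        assert indicator(None, None) == 1

    def test_homref_vs_call(self):
        assert indicator(None, make_call("chr1", 5, "C", "C", "T")) == 0
        site = GenomicSite("chr1", 5, "C")
        assert indicator(None, hom_ref_call(site)) == 1

    def test_different_sites_rejected(self):
        with pytest.raises(ValueError, match="different sites"):
            indicator(make_call("chr1", 5, "A", "A", "G"),
                      make_call("chr1", 6, "A", "A", "G"))


class TestWeight:
    @pytest.mark.parametrize(
        "fi, fj, expected",
        [(1.0, 1.0, 1.0), (1 / 1001, 1 / 1001, 1001.0), (0.999, 0.001, 2.0)],
    )
    def test_values(self, fi, fj, expected):
        assert weight(fi, fj) == pytest.approx(expected)

    @pytest.mark.parametrize("fi", [0.0, -0.1, 1.5])
    def test_invalid_frequency_rejected(self, fi):
        with pytest.raises(ValueError):
            weight(fi, 0.5)

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=2000),
        fi=st.floats(min_value=1e-4, max_value=1.0),
        fj=st.floats(min_value=1e-4, max_value=1.0),
    )
    def test_bounded_by_panel_size(self, n, fi, fj):
        lo = 1 / (n + 1)
        fi = max(fi, lo)
        fj = max(fj, lo)
        assert 1.0 - 1e-9 <= weight(fi, fj) <= (n + 1) * (1 + 1e-9)


class TestPairwiseDistance:
    def test_identical_sets_give_zero(self, hand_panel, tiny_region):
        x = make_set("x", tiny_region, [("chr1", 100, "A", "C", "T")])
        y = make_set("y", tiny_region, [("chr1", 100, "A", "C", "T")])
        assert pairwise_distance(x, y, hand_panel).value == 0.0

    def test_total_disagreement_gives_one(self, hand_panel, tiny_region):
        x = make_set("x", tiny_region, [("chr1", 100, "A", "C", "T")])
        y = make_set("y", tiny_region, [("chr1", 200, "C", "T", "T")])
        assert pairwise_distance(x, y, hand_panel).value == 1.0

    def test_hand_worked_example(self, hand_panel, tiny_region):
        """Two sites: agreement with W=2 at one, disagreement with W=5 at
        the other -> d = 1 - 2/7."""
        x = make_set("x", tiny_region,
                     [("chr1", 100, "A", "C", "T"), ("chr1", 200, "C", "T", "T")])
        y = make_set("y", tiny_region,
                     [("chr1", 100, "A", "C", "T"), ("chr1", 200, "C", "C", "T")])
        result = pairwise_distance(x, y, hand_panel)
        assert result.value == pytest.approx(1 - 2 / 7)
        assert result.union_size == 2
        assert result.c_norm == pytest.approx(7.0)

    def test_empty_union_is_zero(self, hand_panel, tiny_region):
        x = make_set("x", tiny_region, [])
        y = make_set("y", tiny_region, [])
        result = pairwise_distance(x, y, hand_panel)
        assert result.value == 0.0 and result.union_size == 0

    def test_region_mismatch_rejected(self, hand_panel, tiny_region):
        other = TargetRegion([("chr1", 0, 500)])
        x = make_set("x", tiny_region, [])
        y = make_set("y", other, [])
        with pytest.raises(ValueError):
            pairwise_distance(x, y, hand_panel)

    def test_hamming_mode_ignores_frequencies(self, hand_panel, tiny_region):
        x = make_set("x", tiny_region,
                     [("chr1", 100, "A", "C", "T"), ("chr1", 200, "C", "T", "T")])
        y = make_set("y", tiny_region,
                     [("chr1", 100, "A", "C", "T"), ("chr1", 200, "C", "C", "T")])
        assert pairwise_distance(x, y, hand_panel, weighted=False).value == pytest.approx(0.5)


@pytest.fixture(scope="module")
def sample_pool(small_panel):
    panel, members = small_panel
    tests = [simulate_test_sample(panel, 1e-4, seed=50 + i) for i in range(4)]
    return panel, members[:4] + tests


class TestMetricProperties:
    def test_symmetry_identity_range(self, sample_pool):
        panel, sets = sample_pool
        for i, x in enumerate(sets):
            assert pairwise_distance(x, x.copy("clone"), panel).value == pytest.approx(0.0)
            for y in sets[i + 1:]:
                d_xy = pairwise_distance(x, y, panel)
                d_yx = pairwise_distance(y, x, panel)
                assert d_xy.value == pytest.approx(d_yx.value, abs=1e-12)
                assert 0.0 <= d_xy.value <= 1.0

    def test_matrix_matches_scalar_oracle(self, sample_pool):
        """Vectorized matrix equals per-pair scalar recomputation exactly."""
        panel, sets = sample_pool
        D = distance_matrix(sets, panel)
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                expected = pairwise_distance(sets[i], sets[j], panel).value
                assert D.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_distances_to_members_matches_scalar(self, small_panel):
        panel, members = small_panel
        test = simulate_test_sample(panel, 1e-3, seed=77)
        d = distances_to_members(test, panel)
        for j in [0, 7, 19]:
            expected = pairwise_distance(test, members[j], panel).value
            assert d[j] == pytest.approx(expected, abs=1e-10)

    def test_error_sensitivity_monotone(self, small_panel):
        """Mean distance to the panel rises with the injected error rate."""
        panel, _ = small_panel
        means = []
        for p in [0.0, 1e-4, 1e-3]:
            vals = [
                np.mean(distances_to_members(simulate_test_sample(panel, p, seed=300 + s), panel))
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_triangle_inequality_reported(self, sample_pool):
        """The weighting makes the triangle inequality non-guaranteed; on
        synthetic data violations, if any, stay marginal."""
        panel, sets = sample_pool
        D = distance_matrix(sets, panel).values
        m = len(sets)
        worst = 0.0
        for i in range(m):
            for j in range(m):
                for k in range(m):
                    if len({i, j, k}) == 3:
                        worst = max(worst, D[i, j] - (D[i, k] + D[k, j]))
        assert worst <= 0.05


class TestDistanceMatrix:
    def test_identical_sets_zero_matrix(self, hand_panel, tiny_region):
        sets = [make_set(f"s{i}", tiny_region, [("chr1", 100, "A", "C", "T")]) for i in range(3)]
        D = distance_matrix(sets, hand_panel)
        assert np.allclose(D.values, 0.0)

    def test_duplicate_ids_rejected(self, hand_panel, tiny_region):
        sets = [make_set("same", tiny_region, []), make_set("same", tiny_region, [])]
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix(sets, hand_panel)

    def test_tsv_round_trip(self, small_panel, tmp_path):
        panel, members = small_panel
        D = distance_matrix(members[:5], panel)
        path = tmp_path / "d.tsv"
        D.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.labels == D.labels
        assert np.allclose(back.values, D.values, atol=1e-6)


class TestLeaveOneOut:
    def test_member_weights_match_external_framing(self):
        """A member of an (n+1)-panel and the same individual treated as an
        external probe of the n-panel get near-identical distances."""
        panel_all, members = simulate_panel(
            PanelSpec(n_individuals=41, region_size=200_000, n_variant_sites=1_000, seed=9)
        )
        probe, first = members[40], members[:40]
        panel_40 = build_panel(first, "ref")
        d_ext = distances_to_members(probe, panel_40)
        from exosds.distance import pair_sums

        A, C = pair_sums(members, panel_all)
        d_mem = 1 - A[40, :40] / C[40, :40]
        assert abs(np.mean(d_ext) - np.mean(d_mem)) < 1e-3

    def test_flag_off_reproduces_full_count_weights(self, tiny_region):
        sites = {("chr1", 100): PanelSite("A", {("A", "G"): 2})}
        panel = ReferencePanel(4, "p", sites, tiny_region)
        g = make_call("chr1", 100, "A", "A", "G")
        assert _raw_frequency(panel, g.site, g, exclude_self=False) == pytest.approx(
            genotype_frequency(panel, g.site, g)
        )
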