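"""Genotype-frequency-weighted distance between variant call sets.

For a pair of samples the comparison runs over every position where at
least one of the two called genotypes differs from the reference sequence.
Agreement at position k is scored by the indicator I(k), weighted by
W(k) = 2 / (f_i(k) + f_j(k)) — the harmonic weight of the two genotype
frequencies in the reference panel — and the distance is

    d = 1 - ( sum_k I(k) W(k) ) / ( sum_k W(k) ).

A disagreement at a position of low variability in the panel therefore
contributes more than one at a highly variable position.  d = 0 means total
agreement, d = 1 total disagreement.  With ``weighted=False`` all weights
are 1 and the distance reduces to a Hamming-style mismatch fraction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .reference_panel import ReferencePanel
from .types import HOMREF_CODE, GenomicSite, GenotypeCall, VariantSet, hom_ref_call

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PairwiseDistance:
    """One pairwise dissimilarity with its normalizing constant."""

    value: float
    union_size: int
    c_norm: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.value <= 1 + 1e-12:
            raise ValueError(f"distance {self.value} outside [0, 1]")


class DistanceMatrix:
    """Symmetric matrix of pairwise weighted distances with sample labels."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("labels and matrix shape disagree")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix must be symmetric")
        self.labels = list(labels)
        self.values = values

    def __len__(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: PathLike) -> None:
        df = pd.DataFrame(np.round(self.values, 6), index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: PathLike) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy())


def indicator(g_i: Optional[GenotypeCall], g_j: Optional[GenotypeCall]) -> int:
    """1 iff the two (canonical) genotypes at the same site are equal.

    ``None`` stands for the implicit homozygous-reference genotype.
    """
    if g_i is None and g_j is None:
        return 1
    if g_i is not None and g_j is not None:
        if g_i.site.key != g_j.site.key:
            raise ValueError(
                f"genotypes at different sites: {g_i.site.key} vs {g_j.site.key}"
            )
        return int(g_i.alleles == g_j.alleles)
    call = g_i if g_i is not None else g_j
    return int(call.is_hom_ref)


def weight(f_i: float, f_j: float) -> float:
    """W = 2 / (f_i + f_j); equals 1 when both genotypes are universal."""
    if not (0 < f_i <= 1 and 0 < f_j <= 1):
        raise ValueError(f"genotype frequencies must lie in (0, 1], got {f_i}, {f_j}")
    return 2.0 / (f_i + f_j)


def _raw_frequency(
    panel: ReferencePanel, site: GenomicSite, g: GenotypeCall, exclude_self: bool
) -> float:
    """Unfloored count-based frequency of ``g``; the carrying sample's own
    copy is removed when ``exclude_self``.  Hom-ref at a site the panel
    does not list has frequency 1."""
    n = panel.n
    entry = panel.sites.get(site.key)
    is_hom_ref = g.alleles == (site.ref_allele, site.ref_allele)
    if entry is None:
        return 1.0 if is_hom_ref else 0.0
    if is_hom_ref:
        count = n - entry.explicit_total
    else:
        count = entry.counts.get(g.alleles, 0)
    if exclude_self:
        count -= 1
    return count / n


def pairwise_distance(
    x_i: VariantSet,
    x_j: VariantSet,
    panel: ReferencePanel,
    weighted: bool = True,
    leave_one_out: bool = True,
) -> PairwiseDistance:
    """Weighted distance between two variant sets (scalar reference path).

    The comparison runs over the union of the two call maps; positions
    hom-ref in both samples are excluded even if variable in the panel.
    An empty union yields d = 0 by convention (logged as degenerate).
    With ``leave_one_out`` (default), the copies of the two compared
    samples themselves are removed from the frequency counts (a member's
    own copy always, the partner's copy at agreement sites), so panel
    members and external samples are weighted on the same footing.
    """
    if x_i.region != x_j.region or x_i.region != panel.region:
        raise ValueError("variant sets and panel must share one target region")
    member_ids = set(panel.member_ids or []) if panel.n >= 2 else set()
    loo_i = leave_one_out and x_i.sample_id in member_ids
    loo_j = leave_one_out and x_j.sample_id in member_ids
    unseen = panel.unseen_frequency
    inv_n = 1.0 / panel.n
    union = set(x_i.calls) | set(x_j.calls)
    if not union:
        logger.info(
            "empty union between %s and %s; distance defined as 0",
            x_i.sample_id, x_j.sample_id,
        )
        return PairwiseDistance(0.0, 0, 0.0)
    num = 0.0
    den = 0.0
    for key in union:
        ci = x_i.calls.get(key)
        cj = x_j.calls.get(key)
        some = ci if ci is not None else cj
        entry = panel.sites.get(key)
        ref = entry.ref_allele if entry is not None else some.site.ref_allele
        site = GenomicSite(key[0], key[1], ref)
        gi = ci if ci is not None else hom_ref_call(site)
        gj = cj if cj is not None else hom_ref_call(site)
        agree = gi.alleles == gj.alleles
        if weighted:
            raw_i = _raw_frequency(panel, site, gi, loo_i)
            raw_j = _raw_frequency(panel, site, gj, loo_j)
            if agree:  # the partner's copy is not evidence about the pair
                if loo_j:
                    raw_i -= inv_n
                if loo_i:
                    raw_j -= inv_n
            w = weight(max(raw_i, unseen), max(raw_j, unseen))
        else:
            w = 1.0
        num += w * agree
        den += w
    return PairwiseDistance(1.0 - num / den, len(union), den)


def _encode_over_universe(
    sets: Sequence[VariantSet], panel: ReferencePanel, leave_one_out: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Encode variant sets over panel sites plus any extra called positions.

    Returns (codes, raw_freqs, homref_codes, member_flags) with codes and
    raw (unfloored) frequencies of shape (n_sets, n_universe_sites).  At
    sites absent from the panel, hom-ref has raw frequency 1 and any
    variant genotype 0 (floored to the unseen pseudo-frequency at pair
    time).  Panel members have their own genotype copy removed from the
    counts when ``leave_one_out`` is set.
    """
    idx = panel.index
    extra_keys: dict[tuple[str, int], str] = {}
    for vs in sets:
        for key, call in vs.calls.items():
            if key not in idx.pos_index and key not in extra_keys:
                extra_keys[key] = call.site.ref_allele
    extras_sorted = sorted(extra_keys)
    extra_index = {k: i for i, k in enumerate(extras_sorted)}
    n_core = len(idx.positions)
    n_extra = len(extras_sorted)
    hom = np.concatenate(
        [
            idx.homref_codes,
            np.array([HOMREF_CODE[extra_keys[k]] for k in extras_sorted], dtype=np.int8)
            if n_extra
            else np.empty(0, dtype=np.int8),
        ]
    )
    site_rows = np.arange(n_core)
    codes = np.tile(hom, (len(sets), 1))
    raws = np.empty((len(sets), n_core + n_extra))
    member_flags = np.zeros(len(sets), dtype=bool)
    for s, vs in enumerate(sets):
        loo = leave_one_out and idx.is_member(vs) and panel.n >= 2
        member_flags[s] = loo
        table = idx.raw_loo if loo else idx.raw_full
        raws[s, :n_core] = table[site_rows, idx.homref_codes]
        raws[s, n_core:] = 1.0
        for key, call in vs.calls.items():
            code = call.code
            i = idx.pos_index.get(key)
            if i is None:
                i = n_core + extra_index[key]
                f = 0.0  # variant genotype at a site the panel does not list
            else:
                f = table[i, code]
            codes[s, i] = code
            raws[s, i] = f
    return codes, raws, hom, member_flags


def pair_sums(
    sets: Sequence[VariantSet],
    panel: ReferencePanel,
    weighted: bool = True,
    leave_one_out: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Agreement sums A and normalizing constants C for every pair of sets.

    Returns (A, C), each (m, m); the diagonal holds each sample's
    self-comparison (A_ii = C_ii = total weight of its own calls).
    The distance matrix is 1 - A/C wherever C > 0.
    """
    codes, raws, hom, member_flags = _encode_over_universe(
        sets, panel, leave_one_out=leave_one_out
    )
    m = len(sets)
    A = np.zeros((m, m))
    C = np.zeros((m, m))
    nonref = codes != hom[None, :]
    unseen = panel.unseen_frequency
    inv_n = 1.0 / panel.n
    for i in range(m):
        for j in range(i, m):
            mask = nonref[i] | nonref[j]
            if not mask.any():
                continue
            agree = codes[i, mask] == codes[j, mask]
            if weighted:
                raw_i = raws[i, mask]
                raw_j = raws[j, mask]
                # at agreement sites the partner's panel copy is removed too
                if member_flags[j] and i != j:
                    raw_i = raw_i - inv_n * agree
                if member_flags[i] and i != j:
                    raw_j = raw_j - inv_n * agree
                f_i = np.maximum(raw_i, unseen)
                f_j = np.maximum(raw_j, unseen)
                w = 2.0 / (f_i + f_j)
            else:
                w = np.ones(int(mask.sum()))
            A[i, j] = A[j, i] = float(w[agree].sum())
            C[i, j] = C[j, i] = float(w.sum())
    return A, C


def distance_matrix(
    sets: Sequence[VariantSet],
    panel: ReferencePanel,
    weighted: bool = True,
    leave_one_out: bool = True,
) -> DistanceMatrix:
    """Full symmetric distance matrix over a list of variant sets."""
    if len(sets) < 2:
        raise ValueError("a distance matrix needs at least 2 variant sets")
    labels = [vs.sample_id for vs in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample ids in distance matrix input")
    A, C = pair_sums(sets, panel, weighted=weighted, leave_one_out=leave_one_out)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.divide(A, C, out=np.ones_like(A), where=C > 0)
    d[C == 0] = 0.0  # empty-union convention
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


def distances_to_members(
    test: VariantSet,
    panel: ReferencePanel,
    weighted: bool = True,
    leave_one_out: bool = True,
) -> np.ndarray:
    """Distances from a test sample to every panel member (vectorized).

    Calls the test sample makes at positions the panel does not list are
    disagreements against every member with a constant weight, so they are
    folded into the normalizing constant analytically.
    """
    if panel.member_sets is None:
        raise ValueError("panel has no member variant sets")
    if test.region != panel.region:
        raise ValueError("test sample and panel must share one target region")
    idx = panel.index
    m_codes, m_raws = idx.member_matrix(loo=leave_one_out)
    test_loo = leave_one_out and idx.is_member(test) and panel.n >= 2
    t_codes, t_raws, extras = idx.encode(test, loo=test_loo, raw=True)
    hom = idx.homref_codes
    unseen = panel.unseen_frequency
    inv_n = 1.0 / panel.n
    mask = (m_codes != hom[None, :]) | (t_codes != hom)[None, :]
    agree = (m_codes == t_codes[None, :]) & mask
    if weighted:
        # at agreement sites the partner's panel copy is removed as well
        adj_m = inv_n * agree if test_loo else 0.0
        adj_t = inv_n * agree if leave_one_out and panel.n >= 2 else 0.0
        f_m = np.maximum(m_raws - adj_m, unseen)
        f_t = np.maximum(t_raws[None, :] - adj_t, unseen)
        w = np.where(mask, 2.0 / (f_m + f_t), 0.0)
    else:
        w = mask.astype(np.float64)
    A = np.where(agree, w, 0.0).sum(axis=1)
    C = w.sum(axis=1)
    if extras:
        # each extra call: test genotype unseen, members hom-ref at a site
        # the panel does not list (f=1); always a disagreement
        if weighted:
            C = C + len(extras) * weight(unseen, 1.0)
        else:
            C = C + len(extras)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.divide(A, C, out=np.ones_like(A), where=C > 0)
    d[C == 0] = 0.0
    return d
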