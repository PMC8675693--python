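"""Archaic haplotype reconstruction, identical-tract scanning, mosaic
labelling, frequency bounds, tract-survival tests and the five-step
archaic-ancestry screen.

Archaic genotypes arrive unphased with missing (N) calls. Phasing leans on a
fully homozygous reference individual (the Altai Neanderthal in the original
data): wherever another individual is heterozygous, the allele matching the
homozygous reference is assigned to haplotype "-2" and the other to "-1", so
the "-2" haplotypes of all individuals share the reference haplotype.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel_io import GenomicRegion, HaplotypePanel
from .params import EvoParams
from .phylo import DistanceMatrix, nj_tree, pairwise_difference_matrix
from .haplotypes import (
    HaplotypeGroup,
    PromoterType,
    SnpTriplet,
    enumerate_haplotypes,
    group_population_counts,
)

log = logging.getLogger(__name__)


@dataclass
class UnphasedDiploid:
    """Per-site unordered allele pairs; a missing site is ('N', 'N')."""

    sample: str
    positions: np.ndarray
    genotypes: np.ndarray  # (n_sites, 2) over {A,C,G,T,N}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype="<U1")
        if self.genotypes.shape != (len(self.positions), 2):
            raise ValueError("genotypes must be (n_sites, 2)")

    def is_het(self) -> np.ndarray:
        g = self.genotypes
        return (g[:, 0] != g[:, 1]) & (g[:, 0] != "N") & (g[:, 1] != "N")


RESOLVED_HOM = "homozygous"
RESOLVED_REF = "reference-resolved"
UNRESOLVED = "unresolved"


@dataclass
class PhasedArchaic:
    """Two reference-linked haplotypes; "-2" carries the reference-matching
    phase at every resolved heterozygous site."""

    sample: str
    positions: np.ndarray
    hap1: np.ndarray
    hap2: np.ndarray
    resolution: np.ndarray  # per-site flag

    @property
    def haplotype_ids(self) -> tuple[str, str]:
        return (f"{self.sample}-1", f"{self.sample}-2")


def phase_by_reference(target: UnphasedDiploid, reference: UnphasedDiploid) -> PhasedArchaic:
    """Phase ``target`` against a fully homozygous reference individual."""
    if not np.array_equal(target.positions, reference.positions):
        raise ValueError("target and reference site sets differ")
    het_ref = reference.is_het()
    if het_ref.any():
        pos = int(reference.positions[np.argmax(het_ref)])
        raise ValueError(f"reference not homozygous at position {pos}")

    n = len(target.positions)
    hap1 = np.full(n, "N", dtype="<U1")
    hap2 = np.full(n, "N", dtype="<U1")
    flags = np.full(n, UNRESOLVED, dtype="<U20")
    ref_allele = reference.genotypes[:, 0]  # 'N' where reference missing
    for i in range(n):
        a, b = target.genotypes[i]
        if a == "N" or b == "N":
            continue
        if a == b:
            hap1[i] = hap2[i] = a
            flags[i] = RESOLVED_HOM
        else:
            r = ref_allele[i]
            if r == a:
                hap2[i], hap1[i] = a, b
                flags[i] = RESOLVED_REF
            elif r == b:
                hap2[i], hap1[i] = b, a
                flags[i] = RESOLVED_REF
            # else: reference missing or third allele -> unresolved (both N)
    return PhasedArchaic(target.sample, target.positions.copy(), hap1, hap2, flags)


def diploid_distance(a, b: UnphasedDiploid) -> float:
    """Nucleotide distance between diploids (or a haploid and a diploid).

    Per compared site the contribution is half the mismatch count under the
    better of the two allele pairings: hom X vs hom Y scores 1, hom X vs het
    XY scores 1/2, het XY vs het XZ scores 1/2, and so on. Sites missing in
    either individual are skipped.
    """
    ga = a.genotypes if isinstance(a, UnphasedDiploid) else None
    if ga is None:
        seq = np.asarray(a, dtype="<U1")
        ga = np.stack([seq, seq], axis=1)
    gb = b.genotypes
    if ga.shape != gb.shape:
        raise ValueError("site sets differ")
    total = 0.0
    for (a1, a2), (b1, b2) in zip(ga, gb):
        if "N" in (a1, a2, b1, b2):
            continue
        p1 = (a1 != b1) + (a2 != b2)
        p2 = (a1 != b2) + (a2 != b1)
        total += min(p1, p2) / 2.0
    return total


@dataclass
class TractHit:
    """A maximal mismatch-free run around an anchor, in bp."""

    partner: str
    start: int  # 1-based inclusive
    end: int
    length: int
    n_compared: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("tract length must be positive")


def _mismatch_positions(query, subject, positions) -> np.ndarray:
    q = np.asarray(query, dtype="<U1")
    s = np.asarray(subject, dtype="<U1")
    ok = (q != "N") & (s != "N")
    return positions[ok & (q != s)]


def longest_identical_tract(
    query,
    subject,
    positions: np.ndarray,
    region: GenomicRegion,
    anchor,
    partner: str = "",
) -> TractHit:
    """Longest run identical between ``query`` and ``subject`` overlapping the
    anchor position/interval. N sites are skipped and never break a run; tract
    boundaries are the flanking mismatch positions (exclusive), or the region
    edges when no mismatch flanks the run.
    """
    if isinstance(anchor, (tuple, list)):
        a_lo, a_hi = int(anchor[0]), int(anchor[-1])
    else:
        a_lo = a_hi = int(anchor)
    if not (region.contains(a_lo) and region.contains(a_hi)):
        raise ValueError("anchor outside region")
    positions = np.asarray(positions, dtype=np.int64)
    mism = _mismatch_positions(query, subject, positions)
    bounds = np.concatenate([[region.start - 1], mism, [region.end + 1]])
    # clean intervals are (bounds[k], bounds[k+1]) exclusive on both ends
    best = None
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        start, end = int(lo) + 1, int(hi) - 1
        if end < start:
            continue
        if end < a_lo or start > a_hi:  # must intersect the anchor
            continue
        length = end - start + 1
        if best is None or length > best[2]:
            best = (start, end, length)
    if best is None:  # anchor fully covered by mismatches: no identical run
        raise ValueError("no mismatch-free run overlaps the anchor")
    start, end, length = best
    q = np.asarray(query, dtype="<U1")
    s = np.asarray(subject, dtype="<U1")
    inside = (positions >= start) & (positions <= end)
    ncomp = int(((q != "N") & (s != "N") & inside).sum())
    return TractHit(partner, start, end, length, ncomp)


def rank_tract_partners(
    query, subjects: dict[str, np.ndarray], positions, region, anchor
) -> list[TractHit]:
    """Longest identical tract against every subject, longest first (ties by
    partner label)."""
    if not subjects:
        raise ValueError("empty subject set")
    hits = [
        longest_identical_tract(query, seq, positions, region, anchor, partner=lab)
        for lab, seq in subjects.items()
    ]
    return sorted(hits, key=lambda h: (-h.length, h.partner))


@dataclass
class MosaicSegment:
    label: str
    start: int
    end: int


def infer_mosaic_structure(
    query, donors: dict[str, np.ndarray], positions, region: GenomicRegion
) -> list[MosaicSegment]:
    """Greedy segmentation of ``query`` into donor-type segments.

    Each site is assigned to the donor whose mismatch-free run covering that
    site is locally longest; adjacent same-label segments are merged, and
    segment boundaries extend halfway to the neighbouring segment's first
    site (region edges at the ends).
    """
    if len(donors) < 2:
        raise ValueError("need at least two donor types")
    positions = np.asarray(positions, dtype=np.int64)
    q = np.asarray(query, dtype="<U1")
    names = sorted(donors)
    # run length (bp) of each donor's clean interval covering each site
    run_len = np.zeros((len(names), len(positions)))
    for k, name in enumerate(names):
        mism = _mismatch_positions(q, donors[name], positions)
        bounds = np.concatenate([[region.start - 1], mism, [region.end + 1]])
        idx = np.searchsorted(bounds, positions, side="left")
        lo = bounds[idx - 1]
        hi = bounds[np.minimum(idx, len(bounds) - 1)]
        length = hi - lo - 1
        on_mismatch = np.isin(positions, mism)
        run_len[k] = np.where(on_mismatch, 0, length)
    labels = [names[k] for k in np.argmax(run_len, axis=0)]

    segments: list[MosaicSegment] = []
    seg_start_idx = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[seg_start_idx]:
            first, last = positions[seg_start_idx], positions[i - 1]
            start = (
                region.start
                if seg_start_idx == 0
                else (positions[seg_start_idx - 1] + first) // 2 + 1
            )
            end = region.end if i == len(labels) else (last + positions[i]) // 2
            segments.append(MosaicSegment(labels[seg_start_idx], int(start), int(end)))
            seg_start_idx = i
    return segments


def beta_frequency_lower_bound(
    n_type_alleles: int, n_other_alleles: int, level: float = 0.95
) -> float:
    """Lower endpoint f0 of the one-sided credible interval for an allele
    frequency under a uniform prior: P(f > f0 | data) = level with posterior
    Beta(n_type+1, n_other+1)."""
    if n_type_alleles < 0 or n_other_alleles < 0:
        raise ValueError("counts must be nonnegative")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    return float(stats.beta.ppf(1 - level, n_type_alleles + 1, n_other_alleles + 1))


def tract_survival_probability(m: float, params: EvoParams, t_total: float) -> float:
    """Probability that a haplotype tract of length >= m bp survives
    unrecombined over t_total years: exp(-m * r * t_total / g).

    Small values reject a shared-ancestral (incomplete lineage sorting)
    origin of a long identical tract in favour of recent introgression.
    """
    if m < 0:
        raise ValueError("tract length must be nonnegative")
    if t_total <= 0:
        raise ValueError("t_total must be positive")
    return float(np.exp(-m * params.r * t_total / params.g))


def amh_ah_difference_range(
    labels_a, seqs_a, labels_b, seqs_b, exclusions=()
) -> tuple[int, int]:
    """(min, max) raw pairwise site differences between two haplotype sets,
    after dropping excluded (e.g. recombinant) labels from either set."""
    excl = set(exclusions)
    a = [(l, s) for l, s in zip(labels_a, seqs_a) if l not in excl]
    b = [(l, s) for l, s in zip(labels_b, seqs_b) if l not in excl]
    if not a or not b:
        raise ValueError("a haplotype set is empty after exclusions")
    diffs = []
    for (_, sa), (_, sb) in itertools.product(a, b):
        qa = np.asarray(list(sa) if isinstance(sa, str) else sa, dtype="<U1")
        qb = np.asarray(list(sb) if isinstance(sb, str) else sb, dtype="<U1")
        ok = (qa != "N") & (qb != "N")
        diffs.append(int((qa[ok] != qb[ok]).sum()))
    return (min(diffs), max(diffs))


@dataclass
class ScreenResult:
    """Audited outcome of the five-step archaic-ancestry screen."""

    promoter_type: PromoterType
    amh_ah_range: tuple[int, int]
    groups: list[HaplotypeGroup]
    matrix: DistanceMatrix | None
    selected: list[str]
    partition: tuple[list[str], list[str]] | None
    afr_widespread: list[str]
    rejected_afr: list[str]
    rejected_relatives: list[str]
    rejected_age: list[str]
    age_unknown: list[str]
    survivors: list[str]
    audit: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "promoter_type": self.promoter_type.value,
            "amh_ah_range": list(self.amh_ah_range),
            "n_groups": len(self.groups),
            "selected": self.selected,
            "partition": [list(p) for p in self.partition] if self.partition else None,
            "afr_widespread": self.afr_widespread,
            "rejected_afr": self.rejected_afr,
            "rejected_relatives": self.rejected_relatives,
            "rejected_age": self.rejected_age,
            "age_unknown": self.age_unknown,
            "survivors": self.survivors,
            "audit": self.audit,
        }


def _two_cluster_partition(tree, labels) -> tuple[list[str], list[str]]:
    """Bipartition induced by the longest internal edge of an unrooted tree."""
    best_len, best_side = -1.0, None
    for node in tree.non_tips(include_self=False):
        if node.length is not None and node.length > best_len:
            best_len = node.length
            best_side = frozenset(t.name for t in node.tips())
    if best_side is None:  # star tree: arbitrary split on first taxon
        best_side = frozenset([sorted(labels)[0]])
    side_a = sorted(best_side)
    side_b = sorted(set(labels) - best_side)
    return side_a, side_b


def archaic_candidate_screen(
    panel: HaplotypePanel,
    triplet: SnpTriplet,
    promoter_type: PromoterType,
    amh_ah_range: tuple[int, int],
    age_table: dict[int, float],
    *,
    african_metapop: str = "AFR",
    afr_subpop_min: int = 2,
    introgression_window: tuple[float, float] = (30_000.0, 80_000.0),
) -> ScreenResult:
    """Five-step screen for haplotypes of archaic ancestry.

    Step 1 is the externally supplied ``amh_ah_range`` of AMH-AH site
    differences. Step 2 selects haplotype groups showing at least one pairwise
    difference inside that range. Step 3 records the two-cluster partition of
    an NJ tree of the selected groups. Step 4 rejects groups distributed
    widely in Africa (>= ``afr_subpop_min`` African subpopulations) together
    with their relatives at fewer than min(range) differences. Step 5 rejects
    remaining candidates whose shared (else private) variant ages fall outside
    the introgression window; candidates with no age information are flagged
    age-unknown and kept.
    """
    lo, hi = amh_ah_range
    groups = [
        g
        for g in enumerate_haplotypes(panel, triplet)
        if g.promoter_type == promoter_type
    ]
    empty = ScreenResult(
        promoter_type, (lo, hi), groups, None, [], None, [], [], [], [], [], []
    )
    if len(groups) < 2:
        empty.audit["note"] = "fewer than two groups of the requested type"
        return empty

    names = [g.name for g in groups]
    dm = pairwise_difference_matrix(names, [g.sequence for g in groups])

    # Step 2: any pairwise difference inside the AMH-AH range
    in_range = (dm.matrix >= lo) & (dm.matrix <= hi)
    np.fill_diagonal(in_range, False)
    selected = [n for i, n in enumerate(names) if in_range[i].any()]

    # Step 3: two-cluster partition of the NJ tree of the selected groups
    partition = None
    if len(selected) >= 3:
        sel_idx = [names.index(n) for n in selected]
        sub = DistanceMatrix(selected, dm.matrix[np.ix_(sel_idx, sel_idx)])
        partition = _two_cluster_partition(nj_tree(sub), selected)

    # Step 4: reject African-widespread groups and their close relatives
    afr_subpops = set(panel.population_map.subpops_of(african_metapop))
    widespread = []
    for g in groups:
        occupied = {
            s for s in group_population_counts(g, panel, level="subpop") if s in afr_subpops
        }
        if len(occupied) >= afr_subpop_min:
            widespread.append(g.name)
    rejected_afr = [n for n in selected if n in widespread]
    rejected_rel = []
    for n in selected:
        if n in widespread:
            continue
        i = names.index(n)
        for w in widespread:
            if dm.matrix[i, names.index(w)] < lo:
                rejected_rel.append(n)
                break
    remaining = [n for n in selected if n not in rejected_afr and n not in rejected_rel]

    # Step 5: ages of variants shared only by (or unique to) the remaining set
    group_of = {g.name: g for g in groups}
    rejected_age: list[str] = []
    age_unknown: list[str] = []
    survivors: list[str] = []
    shared_sites: list[int] = []
    if remaining:
        member_ids = {m for n in remaining for m in group_of[n].members}
        rows_in = [i for i, h in enumerate(panel.haplotype_ids) if h in member_ids]
        rows_out = [i for i, h in enumerate(panel.haplotype_ids) if h not in member_ids]
        inside = panel.alleles[rows_in]
        outside = panel.alleles[rows_out]
        for j, pos in enumerate(panel.positions):
            col_in = inside[:, j][inside[:, j] != "N"]
            if col_in.size == 0 or len(set(col_in)) != 1:
                continue
            allele = col_in[0]
            col_out = outside[:, j]
            if not np.any(col_out == allele):
                shared_sites.append(int(pos))

        def verdict(sites, name) -> str:
            ages = [age_table[p] for p in sites if p in age_table]
            unknown = [p for p in sites if p not in age_table]
            if not ages:
                return "unknown"
            med = float(np.median(ages))
            lo_t, hi_t = introgression_window
            return "pass" if lo_t <= med <= hi_t else "fail"

        for n in remaining:
            if shared_sites:
                sites = shared_sites
            else:  # fall back on variants unique to this group
                g = group_of[n]
                rows_g = [i for i, h in enumerate(panel.haplotype_ids) if h in set(g.members)]
                rows_o = [i for i in range(panel.n_haplotypes) if i not in rows_g]
                sites = []
                for j, pos in enumerate(panel.positions):
                    col_g = panel.alleles[rows_g, j]
                    col_g = col_g[col_g != "N"]
                    if col_g.size == 0 or len(set(col_g)) != 1:
                        continue
                    if not np.any(panel.alleles[rows_o, j] == col_g[0]):
                        sites.append(int(pos))
            v = verdict(sites, n)
            if v == "pass":
                survivors.append(n)
            elif v == "unknown":
                age_unknown.append(n)
                survivors.append(n)
            else:
                rejected_age.append(n)

    result = ScreenResult(
        promoter_type,
        (lo, hi),
        groups,
        dm,
        selected,
        partition,
        widespread,
        rejected_afr,
        rejected_rel,
        rejected_age,
        age_unknown,
        survivors,
    )
    result.audit = {
        "n_focal_groups": len(groups),
        "shared_only_sites": shared_sites,
        "afr_subpop_min": afr_subpop_min,
        "introgression_window": list(introgression_window),
    }
    return result
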