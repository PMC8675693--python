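"""Promoter-type classification, MAF filtering, haplotype enumeration and
frequency/diversity statistics.

The promoter type of a haplotype is the ordered allele triplet at the three
promoter SNPs rs3759916 / rs3759915 / rs3759914; the four common types are
TGT (ancestral), TCT, CGT and CGC, everything else (including anything with a
missing call) is OTHER.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import HaplotypePanel


class PromoterType(str, Enum):
    TGT = "TGT"
    TCT = "TCT"
    CGT = "CGT"
    CGC = "CGC"
    OTHER = "OTHER"


_KNOWN_TYPES = {"TGT", "TCT", "CGT", "CGC"}
#: The four scored promoter types, ordered by relative promoter activity.
MAJOR_TYPES = (PromoterType.TGT, PromoterType.CGT, PromoterType.TCT, PromoterType.CGC)


@dataclass(frozen=True)
class SnpTriplet:
    """The ordered promoter SNPs and their panel positions."""

    ids: tuple[str, str, str] = ("rs3759916", "rs3759915", "rs3759914")
    positions: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if len(self.ids) != 3 or len(self.positions) != 3:
            raise ValueError("a promoter triplet has exactly three sites")


def classify_promoter_type(alleles) -> PromoterType:
    """Map the ordered alleles at the three promoter SNPs to a promoter type."""
    alleles = list(alleles)
    if len(alleles) != 3:
        raise ValueError(f"expected 3 alleles, got {len(alleles)}")
    for a in alleles:
        if a not in "ACGTN":
            raise ValueError(f"invalid allele {a!r}")
    combo = "".join(alleles)
    return PromoterType(combo) if combo in _KNOWN_TYPES else PromoterType.OTHER


def classify_panel(panel: HaplotypePanel, triplet: SnpTriplet) -> dict[str, PromoterType]:
    """Promoter type of every haplotype in the panel."""
    idx = [panel.site_index(p) for p in triplet.positions]
    sub = panel.alleles[:, idx]
    return {
        hid: classify_promoter_type(sub[i]) for i, hid in enumerate(panel.haplotype_ids)
    }


def site_minor_allele_frequencies(panel: HaplotypePanel) -> np.ndarray:
    """Per-site minor allele frequency over all haplotypes, N excluded."""
    mafs = np.zeros(panel.n_sites)
    for j in range(panel.n_sites):
        col = panel.alleles[:, j]
        col = col[col != "N"]
        if col.size == 0:
            continue
        _, counts = np.unique(col, return_counts=True)
        counts = np.sort(counts)[::-1]
        if len(counts) > 1:
            mafs[j] = counts[1:].sum() / counts.sum()
    return mafs


def filter_by_maf(
    panel: HaplotypePanel, threshold: float, *, keep_positions=()
) -> HaplotypePanel:
    """Keep sites whose panel-wide MAF is >= ``threshold``.

    MAF is computed with all populations pooled. ``keep_positions`` lists
    positions retained regardless of frequency (e.g. sites that are only
    variable once archaic samples are included in the comparison).
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    mafs = site_minor_allele_frequencies(panel)
    keep = set(int(p) for p in keep_positions)
    mask = (mafs >= threshold) | np.isin(panel.positions, list(keep) or [-1])
    return replace(panel, positions=panel.positions[mask], alleles=panel.alleles[:, mask])


@dataclass
class HaplotypeGroup:
    """A set of haplotypes identical over the filtered site set.

    The group is named after its first carrier in panel (population-map)
    order, e.g. ``HG00097.1``.
    """

    name: str
    members: list[str]
    sequence: str
    promoter_type: PromoterType

    @property
    def size(self) -> int:
        return len(self.members)


def enumerate_haplotypes(
    panel: HaplotypePanel, triplet: SnpTriplet | None = None
) -> list[HaplotypeGroup]:
    """Group identical sequences; groups partition the panel.

    Promoter types are looked up from ``triplet`` if its positions are present
    in the panel, otherwise OTHER.
    """
    if panel.n_haplotypes == 0:
        raise ValueError("empty panel")
    types: dict[str, PromoterType]
    if triplet is not None and all(
        p in set(panel.positions.tolist()) for p in triplet.positions
    ):
        types = classify_panel(panel, triplet)
    else:
        types = {hid: PromoterType.OTHER for hid in panel.haplotype_ids}

    groups: dict[str, HaplotypeGroup] = {}
    for i, hid in enumerate(panel.haplotype_ids):
        seq = "".join(panel.alleles[i])
        if seq in groups:
            groups[seq].members.append(hid)
        else:
            groups[seq] = HaplotypeGroup(hid, [hid], seq, types[hid])
    return list(groups.values())


def group_population_counts(
    group: HaplotypeGroup, panel: HaplotypePanel, level: str = "metapop"
) -> dict[str, int]:
    """Member counts of a group per subpopulation or meta-population."""
    getter = panel.metapop_of if level == "metapop" else panel.subpop_of
    out: dict[str, int] = {}
    for hid in group.members:
        pop = getter(hid)
        out[pop] = out.get(pop, 0) + 1
    return out


def frequency_table(
    panel: HaplotypePanel,
    grouping: SnpTriplet | list[HaplotypeGroup],
    level: str = "metapop",
) -> pd.DataFrame:
    """Counts and frequencies per population and category.

    ``grouping`` is either a promoter-SNP triplet (categories are promoter
    types) or a list of haplotype groups (categories are group names). The
    returned frame has columns population, category, count, total, frequency,
    plus a pooled ``ALL`` population.
    """
    getter = panel.metapop_of if level == "metapop" else panel.subpop_of
    if isinstance(grouping, SnpTriplet):
        cat_of = {h: t.value for h, t in classify_panel(panel, grouping).items()}
    else:
        cat_of = {}
        for g in grouping:
            for hid in g.members:
                cat_of[hid] = g.name

    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for hid in panel.haplotype_ids:
        pop, cat = getter(hid), cat_of[hid]
        counts[(pop, cat)] = counts.get((pop, cat), 0) + 1
        counts[("ALL", cat)] = counts.get(("ALL", cat), 0) + 1
        totals[pop] = totals.get(pop, 0) + 1
        totals["ALL"] = totals.get("ALL", 0) + 1
    rows = [
        (pop, cat, n, totals[pop], n / totals[pop])
        for (pop, cat), n in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["population", "category", "count", "total", "frequency"]
    )


def fold_difference(freq_a: float, freq_b: float) -> float:
    """freq_a / freq_b (e.g. the TCT-type frequency in EUR over that in AFR)."""
    if freq_b <= 0:
        raise ValueError("zero or negative denominator frequency")
    return freq_a / freq_b


def nucleotide_diversity(sequences) -> float:
    """Mean pairwise difference per site (pi), N pairwise-deleted per site."""
    seqs = np.asarray([list(s) if isinstance(s, str) else s for s in sequences], dtype="<U1")
    if seqs.shape[0] < 2:
        raise ValueError("need at least two sequences")
    total = 0.0
    npairs = 0
    for i, j in itertools.combinations(range(seqs.shape[0]), 2):
        ok = (seqs[i] != "N") & (seqs[j] != "N")
        ncomp = int(ok.sum())
        if ncomp == 0:
            continue
        total += (seqs[i][ok] != seqs[j][ok]).sum() / ncomp
        npairs += 1
    if npairs == 0:
        raise ValueError("no comparable pairs (all sites missing)")
    return total / npairs


def compare_proportions(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Two-sided Fisher's exact p for a difference in two proportions."""
    if count_a > n_a or count_b > n_b:
        raise ValueError("counts exceed totals")
    table = [[count_a, n_a - count_a], [count_b, n_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
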