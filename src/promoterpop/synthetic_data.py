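"""Synthetic fixtures: phased panels with planted promoter-type compositions,
archaic donors with introgression tracts, unphased archaic diploids, and index
SNP frequency tables.

The generator emulates the structure of the real study inputs — a
hotspot-flanked ~18-kb promoter region inside a wider window, five
meta-populations with planted promoter-type frequencies, an archaic donor
lineage that split 550-765 kyr ago and introgressed ~50 kyr ago at low
frequency — without attempting demographic realism beyond what the estimators
assume. Haplotype diversity within a promoter type is modelled as a star
genealogy over discrete *lineages* (identical haplotype copies shared across
populations), which matches both the Poisson mutation-count estimators and
the haplotype-group bookkeeping of the analyses. Every stochastic quantity is
recorded in a truth object for exact downstream assertions, and every
operation is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel_io import GenomicRegion, HaplotypePanel, PopulationMap
from .params import EvoParams
from .archaic_tracts import UnphasedDiploid

SUBPOPS: dict[str, list[str]] = {
    "AFR": ["YRI", "LWK", "GWD", "MSL", "ESN", "ASW", "ACB"],
    "EUR": ["CEU", "TSI", "FIN", "GBR", "IBS"],
    "SAS": ["GIH", "PJL", "BEB", "STU", "ITU"],
    "EAS": ["CHB", "JPT", "CHS", "CDX", "KHV"],
    "AMR": ["MXL", "PUR", "CLM", "PEL"],
}

#: Planted promoter-type frequencies per meta-population (observed global
#: compositions of the four major types; the remainder is OTHER).
DEFAULT_TYPE_FREQS: dict[str, dict[str, float]] = {
    "AFR": {"TGT": 0.463, "TCT": 0.473, "CGT": 0.035, "CGC": 0.008},
    "EUR": {"TGT": 0.033, "TCT": 0.963, "CGT": 0.001, "CGC": 0.002},
    "SAS": {"TGT": 0.111, "TCT": 0.800, "CGT": 0.011, "CGC": 0.078},
    "EAS": {"TGT": 0.132, "TCT": 0.511, "CGT": 0.008, "CGC": 0.346},
    "AMR": {"TGT": 0.181, "TCT": 0.689, "CGT": 0.012, "CGC": 0.118},
}

DEFAULT_N_LINEAGES = {"TGT": 12, "TCT": 16, "CGT": 4, "CGC": 5, "OTHER": 2}

DEFAULT_SUBPOP_SIZE = {"AFR": 16, "EUR": 12, "SAS": 12, "EAS": 12, "AMR": 10}

#: Derived promoter alleles relative to the ancestral TGT triplet
#: (rs3759916 T>C, rs3759915 G>C, rs3759914 T>C).
_TYPE_DERIVED = {
    "TGT": (),
    "TCT": (1,),
    "CGT": (0,),
    "CGC": (0, 2),
    "OTHER": (0, 1),  # CCT, a rare non-major combination
}


@dataclass(frozen=True)
class IntrogressionConfig:
    donor_type: str = "CGT"
    recipient_metapop: str = "SAS"
    recipient_frequency: float = 0.1
    t_donor_split: float = 600_000.0
    t_introgression: float = 50_000.0
    n_intro_lineages: int = 3


@dataclass(frozen=True)
class ArchaicConfig:
    individuals: tuple[str, ...] = ("Altai", "Vindija", "Chagyrskaya", "Denisovan")
    homozygous_reference: str = "Altai"
    include_mosaic: bool = True  # Denisovan "-1" becomes a TGT-CGT-TGT recombinant
    n_mask_rate: float = 0.02
    t_private: float = 20_000.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic panel; the seed is mandatory."""

    seed: int
    chrom: str = "15"
    window_length: int = 40_000
    core_length: int = 18_000
    subpop_individuals: dict = field(default_factory=lambda: dict(DEFAULT_SUBPOP_SIZE))
    type_frequencies: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_TYPE_FREQS.items()
    })
    n_lineages: dict = field(default_factory=lambda: dict(DEFAULT_N_LINEAGES))
    t_type_depth: float = 300_000.0
    t_lineage_depth: float = 200_000.0
    crossover_mean: float = 0.03  # expected template crossovers per haplotype copy
    age_noise_sd: float = 0.2  # lognormal sd of the emulated variant-age estimates
    params: EvoParams = field(default_factory=EvoParams)
    introgression: IntrogressionConfig | None = field(default_factory=IntrogressionConfig)
    archaic: ArchaicConfig = field(default_factory=ArchaicConfig)

    def __post_init__(self) -> None:
        if self.core_length >= self.window_length:
            raise ValueError("core must fit inside the window")
        for meta, freqs in self.type_frequencies.items():
            if sum(freqs.values()) > 1.0 + 1e-9:
                raise ValueError(f"type frequencies for {meta} sum above 1")
        if self.introgression is not None:
            if self.introgression.t_donor_split <= self.introgression.t_introgression:
                raise ValueError("donor split must predate introgression")

    @property
    def window(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, 1, self.window_length, "window")

    @property
    def core(self) -> GenomicRegion:
        start = (self.window_length - self.core_length) // 2 + 1
        return GenomicRegion(self.chrom, start, start + self.core_length - 1, "core")

    @property
    def promoter_positions(self) -> tuple[int, int, int]:
        mid = (self.core.start + self.core.end) // 2
        return (mid - 350, mid, mid + 350)


@dataclass
class SimTruth:
    """Bookkeeping of every stochastic choice made by the generator."""

    registry: dict[int, tuple[str, str]]  # position -> (ancestral, derived)
    promoter_positions: tuple[int, int, int]
    type_templates: dict[str, frozenset[int]]
    lineages: dict[str, frozenset[int]]  # lineage id -> derived positions
    lineage_type: dict[str, str]
    hap_assignment: dict[str, tuple[str, str]]  # hap id -> (type, lineage id)
    crossovers: dict[str, list]  # hap id -> [(breakpoint, partner lineage), ...]
    type_counts: dict[tuple[str, str], int]  # (metapop, type) multinomial draws
    donor_trunk: frozenset[int] = frozenset()
    intro_lineages: dict[str, frozenset[int]] = field(default_factory=dict)
    intro_carriers: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    intro_tract_draws: dict[str, float] = field(default_factory=dict)  # raw lengths
    archaic_haplotypes: dict[str, frozenset[int]] = field(default_factory=dict)
    archaic_mosaic: dict[str, list] = field(default_factory=dict)
    mutation_time: dict[int, float] = field(default_factory=dict)
    site_origin: dict[int, str] = field(default_factory=dict)

    def derived_sequence(self, derived: frozenset[int], positions: np.ndarray) -> np.ndarray:
        seq = np.array([self.registry[int(p)][0] for p in positions], dtype="<U1")
        for k, p in enumerate(positions):
            if int(p) in derived:
                seq[k] = self.registry[int(p)][1]
        return seq


_BASES = np.array(list("ACGT"))


class _SiteFactory:
    """Allocates unique biallelic sites over the window."""

    def __init__(self, rng, window_length: int, reserved):
        self.rng = rng
        self.window_length = window_length
        self.used = set(int(p) for p in reserved)

    def new_sites(self, k: int) -> list[int]:
        out = []
        while len(out) < k:
            p = int(self.rng.integers(1, self.window_length + 1))
            if p not in self.used:
                self.used.add(p)
                out.append(p)
        return out


def _poisson_branch(rng, factory, registry, mutation_time, site_origin,
                    rate_per_year, t_lo, t_hi, origin) -> frozenset[int]:
    """New mutations on a branch spanning [t_lo, t_hi] years before present."""
    k = rng.poisson(rate_per_year * (t_hi - t_lo))
    sites = factory.new_sites(k)
    for p in sites:
        anc = str(rng.choice(_BASES))
        der = str(rng.choice([b for b in "ACGT" if b != anc]))
        registry[p] = (anc, der)
        mutation_time[p] = float(rng.uniform(t_lo, t_hi))
        site_origin[p] = origin
    return frozenset(sites)


def simulate_panel(config: SimConfig) -> tuple[HaplotypePanel, SimTruth]:
    """Phased AMH panel with planted type compositions plus donor/archaic
    truth haplotypes (no introgression planted yet; see plant_introgression).
    """
    rng = np.random.default_rng([config.seed, 1])
    params = config.params
    mu_window = params.mu * config.window_length

    prom = config.promoter_positions
    registry: dict[int, tuple[str, str]] = {}
    mutation_time: dict[int, float] = {}
    site_origin: dict[int, str] = {}
    prom_alleles = [("T", "C"), ("G", "C"), ("T", "C")]
    for p, (anc, der) in zip(prom, prom_alleles):
        registry[p] = (anc, der)
        mutation_time[p] = config.t_type_depth
        site_origin[p] = "promoter"
    factory = _SiteFactory(rng, config.window_length, prom)

    # type templates: derived promoter alleles + template branch mutations
    templates: dict[str, frozenset[int]] = {}
    for t, derived_idx in _TYPE_DERIVED.items():
        muts = _poisson_branch(
            rng, factory, registry, mutation_time, site_origin,
            mu_window, config.t_lineage_depth, config.t_type_depth, f"template:{t}",
        )
        templates[t] = muts | frozenset(prom[i] for i in derived_idx)

    # lineages: star over each type at depth t_lineage_depth
    lineages: dict[str, frozenset[int]] = {}
    lineage_type: dict[str, str] = {}
    for t in _TYPE_DERIVED:
        for i in range(config.n_lineages.get(t, 1)):
            lid = f"{t}_L{i}"
            muts = _poisson_branch(
                rng, factory, registry, mutation_time, site_origin,
                mu_window, 0.0, config.t_lineage_depth, f"lineage:{lid}",
            )
            lineages[lid] = templates[t] | muts
            lineage_type[lid] = t

    # per-metapopulation lineage popularity within each type
    lineage_probs: dict[tuple[str, str], tuple[list[str], np.ndarray]] = {}
    for meta in SUBPOPS:
        for t in _TYPE_DERIVED:
            lids = [l for l, tt in lineage_type.items() if tt == t]
            probs = rng.dirichlet(np.full(len(lids), 0.8))
            lineage_probs[(meta, t)] = (lids, probs)

    # haplotype sampling, population-map order
    assignments: dict[str, tuple[str, str]] = {}
    hap_assignment: dict[str, tuple[str, str]] = {}
    crossovers: dict[str, list] = {}
    type_counts: dict[tuple[str, str], int] = {}
    hap_rows: list[tuple[str, frozenset[int]]] = []
    sample_no = 0
    type_names = list(_TYPE_DERIVED)
    for meta, subs in SUBPOPS.items():
        freqs = config.type_frequencies.get(meta, {})
        probs = np.array([freqs.get(t, 0.0) for t in type_names[:4]] +
                         [max(0.0, 1.0 - sum(freqs.values()))])
        probs = probs / probs.sum()
        for sub in subs:
            for _ in range(config.subpop_individuals.get(meta, 0)):
                sample = f"HG{sample_no:05d}"
                sample_no += 1
                assignments[sample] = (sub, meta)
                for k in (0, 1):
                    hid = f"{sample}.{k}"
                    t = type_names[int(rng.choice(5, p=probs))]
                    lids, lp = lineage_probs[(meta, t)]
                    lid = lids[int(rng.choice(len(lids), p=lp))]
                    derived = lineages[lid]
                    n_x = rng.poisson(config.crossover_mean)
                    xovers = []
                    if n_x > 0:
                        # template crossovers: take the right-hand side from a
                        # random partner lineage at each breakpoint
                        current = derived
                        for bp in sorted(rng.integers(1, config.window_length, size=n_x)):
                            partner = list(lineages)[int(rng.integers(len(lineages)))]
                            left = frozenset(p for p in current if p <= bp)
                            right = frozenset(p for p in lineages[partner] if p > bp)
                            current = left | right
                            xovers.append((int(bp), partner))
                        derived = current
                        t = _classify_derived(derived, prom)
                    hap_assignment[hid] = (t, lid)
                    crossovers[hid] = xovers
                    type_counts[(meta, t)] = type_counts.get((meta, t), 0) + 1
                    hap_rows.append((hid, derived))

    truth = SimTruth(
        registry=registry,
        promoter_positions=prom,
        type_templates=templates,
        lineages=lineages,
        lineage_type=lineage_type,
        hap_assignment=hap_assignment,
        crossovers=crossovers,
        type_counts=type_counts,
        mutation_time=mutation_time,
        site_origin=site_origin,
    )

    # donor lineage and archaic haplotypes (recorded in truth; the archaic
    # private sites become monomorphic panel columns, emulating a joint callset)
    intro = config.introgression
    if intro is not None:
        t_trunk_lo = intro.t_introgression
        t_trunk_hi = 2 * intro.t_donor_split - intro.t_introgression - config.t_lineage_depth
        trunk = _poisson_branch(
            rng, factory, registry, mutation_time, site_origin,
            mu_window, t_trunk_lo, t_trunk_hi, "donor_trunk",
        )
        truth.donor_trunk = trunk
        donor_base = templates[intro.donor_type] | trunk
        for i in range(intro.n_intro_lineages):
            lid = f"INTRO_L{i}"
            muts = _poisson_branch(
                rng, factory, registry, mutation_time, site_origin,
                mu_window, 0.0, intro.t_introgression, f"intro:{lid}",
            )
            truth.intro_lineages[lid] = donor_base | muts
        arch = config.archaic
        for ind in arch.individuals:
            n_haps = 1 if ind == arch.homozygous_reference else 2
            hap_sets = []
            for h in range(n_haps):
                muts = _poisson_branch(
                    rng, factory, registry, mutation_time, site_origin,
                    mu_window, 0.0, arch.t_private, f"archaic:{ind}-{h+1}",
                )
                hap_sets.append(donor_base | muts)
            if n_haps == 1:
                hap_sets.append(hap_sets[0])
            truth.archaic_haplotypes[f"{ind}-1"] = hap_sets[0]
            truth.archaic_haplotypes[f"{ind}-2"] = hap_sets[1]
        if arch.include_mosaic and "Denisovan" in arch.individuals:
            # Denisovan-1: TGT flanks around the donor (CGT) middle, the
            # recombinant mosaic observed in the original alignment
            mid_lo, mid_hi = prom[0] - 4000, prom[2] + 4000
            tgt = templates["TGT"]
            donor_mid = truth.archaic_haplotypes["Denisovan-1"]
            mosaic = frozenset(
                p for p in tgt if p < mid_lo or p > mid_hi
            ) | frozenset(p for p in donor_mid if mid_lo <= p <= mid_hi)
            truth.archaic_haplotypes["Denisovan-1"] = mosaic
            truth.archaic_mosaic["Denisovan-1"] = [
                ("TGT", 1, mid_lo - 1),
                (intro.donor_type, mid_lo, mid_hi),
                ("TGT", mid_hi + 1, config.window_length),
            ]

    positions = np.array(sorted(registry), dtype=np.int64)
    col = {int(p): j for j, p in enumerate(positions)}
    anc = np.array([registry[int(p)][0] for p in positions], dtype="<U1")
    matrix = np.tile(anc, (len(hap_rows), 1))
    for i, (_, derived) in enumerate(hap_rows):
        for p in derived:
            matrix[i, col[p]] = registry[p][1]

    panel = HaplotypePanel(
        config.window,
        positions,
        matrix,
        [hid for hid, _ in hap_rows],
        PopulationMap(assignments),
    )
    return panel, truth


def _classify_derived(derived: frozenset[int], prom) -> str:
    state = tuple(p in derived for p in prom)
    for t, idx in _TYPE_DERIVED.items():
        if state == tuple(i in idx for i in range(3)):
            return t
    return "OTHER"


def plant_introgression(
    panel: HaplotypePanel, truth: SimTruth, config: SimConfig
) -> tuple[HaplotypePanel, SimTruth]:
    """Overlay donor tracts onto recipient haplotypes.

    Carrier count is Binomial(n recipient haplotypes, recipient_frequency);
    each carrier receives one donor (introgressed-lineage) tract whose total
    length is Exponential(mean = g/(r * t_introgression)), centred on the
    promoter SNPs and clipped to the window. Outside the tract the carrier
    keeps its original sequence. Tract intervals are recorded in the truth.
    """
    intro = config.introgression
    if intro is None or intro.recipient_frequency == 0:
        return panel, truth
    rng = np.random.default_rng([config.seed, 2])
    params = config.params
    recipients = [
        i for i, hid in enumerate(panel.haplotype_ids)
        if panel.metapop_of(hid) == intro.recipient_metapop
    ]
    n_carriers = rng.binomial(len(recipients), intro.recipient_frequency)
    carrier_rows = sorted(rng.choice(recipients, size=n_carriers, replace=False))

    mean_len = params.g / (params.r * intro.t_introgression)
    mid = (truth.promoter_positions[0] + truth.promoter_positions[2]) // 2
    col = {int(p): j for j, p in enumerate(panel.positions)}
    matrix = panel.alleles.copy()
    carriers: dict[str, tuple[str, int, int]] = {}
    draws: dict[str, float] = {}
    lineage_ids = sorted(truth.intro_lineages)
    for row in carrier_rows:
        hid = panel.haplotype_ids[row]
        lid = lineage_ids[int(rng.integers(len(lineage_ids)))]
        length = rng.exponential(mean_len)
        draws[hid] = float(length)
        start = max(panel.region.start, int(mid - length / 2))
        end = min(panel.region.end, int(mid + length / 2))
        derived = truth.intro_lineages[lid]
        for p, j in col.items():
            if start <= p <= end:
                anc, der = truth.registry[p]
                matrix[row, j] = der if p in derived else anc
        carriers[hid] = (lid, start, end)

    new_truth = replace(truth)
    new_truth.intro_carriers = dict(truth.intro_carriers)
    new_truth.intro_carriers.update(carriers)
    new_truth.intro_tract_draws = dict(truth.intro_tract_draws)
    new_truth.intro_tract_draws.update(draws)
    new_panel = HaplotypePanel(
        panel.region, panel.positions.copy(), matrix,
        list(panel.haplotype_ids), panel.population_map,
    )
    return new_panel, new_truth


def simulate_archaic_diploids(
    panel: HaplotypePanel, truth: SimTruth, config: SimConfig
) -> list[UnphasedDiploid]:
    """Unphased archaic diploids over the panel's site set.

    The configured reference individual is fully homozygous (its two truth
    haplotypes are identical); sites are masked to N per individual at the
    configured rate. Truth phases live in ``truth.archaic_haplotypes``.
    """
    if not truth.archaic_haplotypes:
        raise ValueError("no archaic haplotypes in truth (introgression config absent)")
    rng = np.random.default_rng([config.seed, 3])
    arch = config.archaic
    out = []
    for ind in arch.individuals:
        h1 = truth.derived_sequence(truth.archaic_haplotypes[f"{ind}-1"], panel.positions)
        h2 = truth.derived_sequence(truth.archaic_haplotypes[f"{ind}-2"], panel.positions)
        lo = np.where(h1 <= h2, h1, h2)  # unordered: canonical per-site order
        hi = np.where(h1 <= h2, h2, h1)
        geno = np.stack([lo, hi], axis=1)
        mask = rng.random(len(panel.positions)) < arch.n_mask_rate
        geno[mask] = "N"
        out.append(UnphasedDiploid(ind, panel.positions.copy(), geno))
    return out


def simulate_variant_ages(
    panel: HaplotypePanel, truth: SimTruth, config: SimConfig
) -> dict[int, float]:
    """Emulated variant-age estimates for panel-segregating variants.

    Ages mimic a genealogy-based dating resource built from modern genomes:
    a variant delivered by introgression coalesces within moderns at the
    introgression event, so its estimated age clusters near t_introgression
    regardless of its (older) true mutation time on the donor branch; other
    variants are dated near their true mutation time. Both carry lognormal
    estimation noise. Variants never observed in moderns (archaic privates,
    or donor variants when no introgression was planted) are absent from the
    table, as they are from the real resource.
    """
    rng = np.random.default_rng([config.seed, 4])
    intro = config.introgression
    introgressed_sites: set[int] = set()
    if truth.intro_carriers:
        for lid, _, _ in truth.intro_carriers.values():
            introgressed_sites |= set(truth.intro_lineages[lid])
    # positions actually segregating among modern haplotypes
    segregating = set()
    for j, p in enumerate(panel.positions):
        col = panel.alleles[:, j]
        col = col[col != "N"]
        if len(set(col)) > 1:
            segregating.add(int(p))
    sd = config.age_noise_sd
    ages: dict[int, float] = {}
    for p in sorted(segregating):
        origin = truth.site_origin.get(p, "")
        if origin.startswith(("donor_trunk", "intro")) or (
            p in introgressed_sites and origin.startswith(("donor", "intro"))
        ):
            base = (intro.t_introgression if intro else 50_000.0)
            ages[p] = float(base * np.exp(rng.normal(0.1, sd)))
        else:
            t_true = truth.mutation_time.get(p, config.t_type_depth)
            ages[p] = float(t_true * np.exp(rng.normal(0.0, sd)))
    return ages


def write_age_table(ages: dict[int, float], path) -> None:
    rows = [(f"site{p}", p, round(a, 1), "synthetic-joint-clock") for p, a in sorted(ages.items())]
    pd.DataFrame(rows, columns=["variant_id", "position", "age_years", "estimator"]).to_csv(
        path, sep="\t", index=False
    )


def read_age_table(path) -> dict[int, float]:
    df = pd.read_csv(path, sep="\t")
    return {int(p): float(a) for p, a in zip(df["position"], df["age_years"])}


def simulate_snp_panel_table(
    n_snps: int,
    bin_window: tuple[float, float],
    fold_mean: float,
    fold_sd: float,
    seed: int,
    pop_a: str = "AFR",
    pop_b: str = "EUR",
) -> pd.DataFrame:
    """Index-SNP frequency table: pop_a frequencies uniform inside the bin,
    pop_b = pop_a * fold with fold ~ Normal(mean, sd) truncated so that the
    pop_b frequency stays in [0, 1]."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = bin_window
    rows = []
    for i in range(n_snps):
        fa = rng.uniform(lo, hi)
        while True:
            fold = rng.normal(fold_mean, fold_sd) if fold_sd > 0 else fold_mean
            fb = fa * fold
            if 0.0 <= fb <= 1.0:
                break
        rows.append((f"snp{i:04d}", fa, fb))
    return pd.DataFrame(rows, columns=["snp_id", pop_a, pop_b])


@dataclass
class SyntheticDataset:
    """One fully generated study: panel (introgression applied), archaic
    diploids, variant ages and the underlying truth."""

    config: SimConfig
    panel: HaplotypePanel
    diploids: list[UnphasedDiploid]
    ages: dict[int, float]
    truth: SimTruth


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    panel, truth = simulate_panel(config)
    panel, truth = plant_introgression(panel, truth, config)
    diploids = (
        simulate_archaic_diploids(panel, truth, config)
        if config.introgression is not None
        else []
    )
    ages = simulate_variant_ages(panel, truth, config)
    return SyntheticDataset(config, panel, diploids, ages, truth)
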