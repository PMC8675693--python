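"""End-to-end orchestration: classify -> enumerate -> compare -> phase
archaics -> screen -> date -> PPA, emitting one structured report.

The pipeline is a pure function of (inputs, config, seed); every stage's
parameters and counts are recorded in the report for auditability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .panel_io import GenomicRegion, HaplotypePanel, restrict_to_region
from .haplotypes import (
    PromoterType,
    SnpTriplet,
    classify_panel,
    enumerate_haplotypes,
    filter_by_maf,
    fold_difference,
    frequency_table,
    group_population_counts,
)
from .phylo import pairwise_difference_matrix, nj_tree
from .archaic_tracts import (
    PhasedArchaic,
    ScreenResult,
    UnphasedDiploid,
    amh_ah_difference_range,
    archaic_candidate_screen,
    beta_frequency_lower_bound,
    infer_mosaic_structure,
    phase_by_reference,
)
from .dating import (
    CladeMutationSummary,
    expected_pairwise_differences,
    homozygosity_tract_lengths,
    htl_to_age,
    poisson_ml_tmrca,
)
from .ppa_stats import (
    DEFAULT_ACTIVITIES,
    compare_activity_distributions,
    enumerate_ah_compositions,
    individual_activity,
    panel_fold_comparison,
    population_ppa,
)
from .synthetic_data import (
    SimConfig,
    SyntheticDataset,
    simulate_dataset,
    simulate_snp_panel_table,
)

log = logging.getLogger(__name__)


def phase_archaic_set(
    diploids: list[UnphasedDiploid], reference_sample: str
) -> dict[str, PhasedArchaic]:
    """Phase every archaic diploid against the homozygous reference individual."""
    by_name = {d.sample: d for d in diploids}
    if reference_sample not in by_name:
        raise ValueError(f"reference individual {reference_sample!r} not among diploids")
    ref = by_name[reference_sample]
    return {name: phase_by_reference(d, ref) for name, d in by_name.items()}


def archaic_informative_positions(
    panel: HaplotypePanel, archaic_seqs: dict[str, np.ndarray]
) -> list[int]:
    """Panel positions where archaic haplotypes differ from the modern
    consensus or are polymorphic among themselves.

    These sites must survive MAF filtering for modern-vs-archaic distances to
    be meaningful: a fixed modern/archaic difference is monomorphic among
    moderns and would otherwise be dropped.
    """
    arch = np.stack([np.asarray(s, dtype="<U1") for s in archaic_seqs.values()])
    keep = []
    for j, pos in enumerate(panel.positions):
        col = panel.alleles[:, j]
        col = col[col != "N"]
        a = arch[:, j]
        a = a[a != "N"]
        if a.size == 0 or col.size == 0:
            continue
        if len(set(a)) > 1 or a[0] != _majority(col):
            keep.append(int(pos))
    return keep


def _majority(col: np.ndarray) -> str:
    vals, counts = np.unique(col, return_counts=True)
    return str(vals[np.argmax(counts)])


def flag_archaic_recombinants(
    archaic_seqs: dict[str, np.ndarray],
    type_representatives: dict[str, np.ndarray],
    positions: np.ndarray,
    region: GenomicRegion,
    min_segment_bp: int = 2000,
) -> list[str]:
    """Archaic haplotypes carrying a modern-type segment (recombinants).

    Each archaic haplotype is segmented against the modern type
    representatives plus the archaic consensus ("AH"); any non-AH segment
    longer than ``min_segment_bp`` marks the haplotype as a recombinant.
    """
    arch = np.stack([np.asarray(s, dtype="<U1") for s in archaic_seqs.values()])
    consensus = np.array([_majority(arch[:, j][arch[:, j] != "N"]) if (arch[:, j] != "N").any() else "N"
                          for j in range(arch.shape[1])], dtype="<U1")
    donors = {f"type:{t}": seq for t, seq in type_representatives.items()}
    donors["AH"] = consensus
    out = []
    for name, seq in archaic_seqs.items():
        segments = infer_mosaic_structure(seq, donors, positions, region)
        for seg in segments:
            if seg.label != "AH" and (seg.end - seg.start + 1) >= min_segment_bp:
                out.append(name)
                break
    return out


@dataclass
class ScreenWorkflowResult:
    screen: ScreenResult
    amh_ah_range: tuple[int, int]
    archaic_recombinants: list[str]
    screen_panel: HaplotypePanel
    archaic_core_seqs: dict[str, np.ndarray]


def run_archaic_screen(
    panel: HaplotypePanel,
    diploids: list[UnphasedDiploid],
    age_table: dict[int, float],
    core: GenomicRegion,
    triplet: SnpTriplet,
    focal_type: PromoterType = PromoterType.CGT,
    *,
    reference_individual: str = "Altai",
    maf: float = 0.005,
    african_metapop: str = "AFR",
    afr_subpop_min: int = 2,
    introgression_window: tuple[float, float] = (30_000.0, 80_000.0),
) -> ScreenWorkflowResult:
    """Full screen workflow on one region panel plus archaic diploids.

    Phases the archaics against the homozygous reference, restricts to the
    core region, keeps archaic-informative sites through the MAF filter,
    derives the modern-archaic site-difference range from African haplotypes
    of the focal type versus non-recombinant archaic haplotypes (step 1), and
    runs the five-step screen.
    """
    core_panel = restrict_to_region(panel, core)
    phased = phase_archaic_set(diploids, reference_individual)
    core_mask = (panel.positions >= core.start) & (panel.positions <= core.end)
    arch_core = {}
    for name, ph in phased.items():
        for hap, seq in zip(ph.haplotype_ids, (ph.hap1, ph.hap2)):
            arch_core[hap] = seq[core_mask]

    keep = archaic_informative_positions(core_panel, arch_core)
    keep = sorted(set(keep) | set(triplet.positions))
    screen_panel = filter_by_maf(core_panel, maf, keep_positions=keep)
    sub = np.isin(core_panel.positions, screen_panel.positions)
    arch_sub = {name: seq[sub] for name, seq in arch_core.items()}

    groups = enumerate_haplotypes(screen_panel, triplet)
    reps: dict[str, np.ndarray] = {}
    for t in ("TGT", "TCT", "CGT", "CGC"):
        of_type = [g for g in groups if g.promoter_type.value == t]
        if of_type:
            biggest = max(of_type, key=lambda g: g.size)
            reps[t] = np.array(list(biggest.sequence), dtype="<U1")
    recombinants = flag_archaic_recombinants(
        arch_sub, reps, screen_panel.positions, core
    )

    afr_groups = [
        g
        for g in groups
        if g.promoter_type == focal_type
        and any(screen_panel.metapop_of(m) == african_metapop for m in g.members)
    ]
    if not afr_groups:
        raise ValueError(
            f"no {focal_type.value} haplotype groups with {african_metapop} members; "
            "cannot anchor the modern-archaic difference range"
        )
    arch_names = [n for n in sorted(arch_sub) if n not in recombinants]
    rng_lo, rng_hi = amh_ah_difference_range(
        [g.name for g in afr_groups],
        [g.sequence for g in afr_groups],
        arch_names,
        [arch_sub[n] for n in arch_names],
    )
    screen = archaic_candidate_screen(
        screen_panel,
        triplet,
        focal_type,
        (rng_lo, rng_hi),
        age_table,
        african_metapop=african_metapop,
        afr_subpop_min=afr_subpop_min,
        introgression_window=introgression_window,
    )
    return ScreenWorkflowResult(screen, (rng_lo, rng_hi), recombinants, screen_panel, arch_sub)


@dataclass
class PipelineConfig:
    """One structured configuration for the full analysis.

    When ``sim`` is given the inputs are generated; otherwise ``vcf_path``,
    ``popmap_path`` and friends are read from disk.
    """

    seed: int = 0
    sim: SimConfig | None = None
    vcf_path: str | None = None
    popmap_path: str | None = None
    age_table_path: str | None = None
    region: GenomicRegion | None = None
    core: GenomicRegion | None = None
    promoter_positions: tuple[int, int, int] | None = None
    maf_common: float = 0.01
    maf_archaic: float = 0.005
    credibility: float = 0.95
    grid_step: float = 0.001
    introgression_window: tuple[float, float] = (30_000.0, 80_000.0)
    activities: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVITIES))
    snp_panel_n: int = 45
    snp_panel_bin: tuple[float, float] = (0.401, 0.492)
    snp_panel_fold: tuple[float, float] = (1.20, 0.07)


def _load_inputs(cfg: PipelineConfig):
    if cfg.sim is not None:
        ds = simulate_dataset(cfg.sim)
        triplet = SnpTriplet(positions=cfg.sim.promoter_positions)
        return ds.panel, ds.diploids, ds.ages, cfg.sim.core, triplet, ds
    from .panel_io import PopulationMap, read_vcf_panel
    from .synthetic_data import read_age_table

    if not (cfg.vcf_path and cfg.popmap_path and cfg.region and cfg.promoter_positions):
        raise ValueError("either sim or (vcf, popmap, region, promoter positions) required")
    pop_map = PopulationMap.read(cfg.popmap_path)
    panel = read_vcf_panel(cfg.vcf_path, cfg.region, pop_map)
    ages = read_age_table(cfg.age_table_path) if cfg.age_table_path else {}
    core = cfg.core or cfg.region
    return panel, [], ages, core, SnpTriplet(positions=cfg.promoter_positions), None


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Run every stage and return one JSON-serializable report."""
    panel, diploids, ages, core, triplet, ds = _load_inputs(cfg)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "synthetic": ds is not None,
            "maf_common": cfg.maf_common,
            "maf_archaic": cfg.maf_archaic,
            "credibility": cfg.credibility,
            "grid_step": cfg.grid_step,
            "introgression_window": list(cfg.introgression_window),
            "activities": {k.value: v for k, v in cfg.activities.items()},
        }
    }

    # --- promoter-type classification and frequencies -----------------------
    types = classify_panel(panel, triplet)
    freq = frequency_table(panel, triplet, level="metapop")
    freq_sub = frequency_table(panel, triplet, level="subpop")
    report["type_frequencies"] = freq.to_dict(orient="records")

    def f(pop: str, cat: str) -> float:
        row = freq[(freq.population == pop) & (freq.category == cat)]
        return float(row.frequency.iloc[0]) if len(row) else 0.0

    folds = {}
    for pop in ("EUR", "SAS", "EAS", "AMR"):
        try:
            folds[f"TCT_{pop}_over_AFR"] = fold_difference(f(pop, "TCT"), f("AFR", "TCT"))
        except ValueError:
            folds[f"TCT_{pop}_over_AFR"] = None
    report["tct_folds"] = folds

    # --- haplotype enumeration at the common-variant threshold --------------
    core_panel = restrict_to_region(panel, core)
    common = filter_by_maf(core_panel, cfg.maf_common, keep_positions=triplet.positions)
    groups = enumerate_haplotypes(common, triplet)
    report["haplotype_groups"] = {
        t.value: sum(1 for g in groups if g.promoter_type is t)
        for t in PromoterType
    }

    # --- archaic stages (only when archaic diploids exist) -------------------
    if diploids:
        type_of_diploid = []
        tri_idx = [panel.site_index(p) for p in triplet.positions]
        from .haplotypes import classify_promoter_type

        for d in diploids:
            g = d.genotypes[tri_idx]
            t1 = classify_promoter_type(g[:, 0])
            t2 = classify_promoter_type(g[:, 1])
            type_of_diploid.append((d.sample, t1.value, t2.value))
        donor_type = PromoterType.CGT
        # only fully called promoter triplets contribute observed alleles
        n_type = n_other = 0
        for d in diploids:
            g = d.genotypes[tri_idx]
            for phase in (0, 1):
                alleles = g[:, phase]
                if "N" in alleles:
                    continue
                if classify_promoter_type(alleles) is donor_type:
                    n_type += 1
                else:
                    n_other += 1
        bound = beta_frequency_lower_bound(n_type, n_other, cfg.credibility)
        report["archaic"] = {
            "diploid_promoter_types": type_of_diploid,
            "cgt_allele_counts": [n_type, n_other],
            "cgt_frequency_lower_bound": bound,
        }

        wf = run_archaic_screen(
            panel, diploids, ages, core, triplet,
            donor_type,
            maf=cfg.maf_archaic,
            introgression_window=cfg.introgression_window,
        )
        report["screen"] = wf.screen.to_dict()
        report["screen"]["archaic_recombinants"] = wf.archaic_recombinants

        # --- dating of the surviving (introgressed) clade --------------------
        survivors = wf.screen.survivors
        if len(survivors) >= 2:
            group_of = {g.name: g for g in wf.screen.groups}
            carrier_ids = [m for n in survivors for m in group_of[n].members]
            rows = [panel.haplotype_ids.index(h) for h in carrier_ids]
            prom_mid = int(np.median(triplet.positions))
            htl = homozygosity_tract_lengths(
                carrier_ids,
                [panel.alleles[r] for r in rows],
                panel.positions,
                panel.region,
                (prom_mid - 400, prom_mid + 400),
                side="upstream",
            )
            p = cfg.sim.params if cfg.sim else None
            from .params import EvoParams

            p = p or EvoParams()
            # count clade mutations over the promoter-centred subregion,
            # which stays inside the introgressed tracts of the survivors
            seqs = np.stack([
                np.array(list(group_of[n].sequence), dtype="<U1") for n in survivors
            ])
            sub_lo, sub_hi = prom_mid - 4000, prom_mid + 4000
            sub_cols = [
                j for j, pos in enumerate(wf.screen_panel.positions)
                if sub_lo <= pos <= sub_hi
            ]
            consensus = np.array(
                [_majority(seqs[:, j]) for j in sub_cols], dtype="<U1"
            )
            # drop survivors whose tract does not span the subregion (their
            # modern flanks would masquerade as clade mutations)
            per_surv = [(row[sub_cols] != consensus).sum() for row in seqs]
            retained = [i for i, d in enumerate(per_surv) if d <= 2]
            if len(retained) < 2:
                retained = list(range(len(survivors)))
            s_muts = int(sum(per_surv[i] for i in retained))
            tm = poisson_ml_tmrca(
                CladeMutationSummary(
                    s_muts, len(retained), sub_hi - sub_lo + 1, p.mu
                )
            )
            report["dating"] = {
                "mean_upstream_htl_bp": htl.mean,
                "htl_age_years_k1": htl_to_age(htl.mean, p, k=1),
                "clade_mutations": s_muts,
                "tmrca_years": tm[0],
                "tmrca_ci_years": list(tm[1]),
                "expected_amh_ah_differences": [
                    expected_pairwise_differences(t, p.mu, core.length, rounded=True)
                    for t in p.t_split_amh_ah
                ],
            }

    # --- PPA -----------------------------------------------------------------
    by_meta: dict[str, list] = {}
    by_sub: dict[str, list] = {}
    for sample in panel.population_map.samples:
        pair = (types[f"{sample}.0"], types[f"{sample}.1"])
        sub, meta = panel.population_map.assignments[sample]
        by_meta.setdefault(meta, []).append(pair)
        by_sub.setdefault(sub, []).append(pair)
    ppa_meta = {}
    act_meta = {}
    for meta, pairs in by_meta.items():
        res = population_ppa(pairs, cfg.activities, meta)
        ppa_meta[meta] = res.ppa
        act_meta[meta] = res.individual_activities
    ppa_sub = {}
    for sub, pairs in by_sub.items():
        try:
            ppa_sub[sub] = population_ppa(pairs, cfg.activities, sub).ppa
        except ValueError:
            ppa_sub[sub] = None
    ks = {}
    metas = sorted(act_meta)
    for i, a in enumerate(metas):
        for b in metas[i + 1:]:
            d, pval = compare_activity_distributions(act_meta[a], act_meta[b])
            ks[f"{a}_vs_{b}"] = {"D": d, "p": pval}
    report["ppa"] = {
        "metapopulations": ppa_meta,
        "subpopulations": ppa_sub,
        "ks_tests": ks,
        "lowest_metapopulation": min(ppa_meta, key=ppa_meta.get),
    }

    # --- archaic composition enumeration -------------------------------------
    if diploids and "archaic" in report:
        ah = enumerate_ah_compositions(
            report["archaic"]["cgt_frequency_lower_bound"],
            cfg.grid_step,
            reference_ppa=ppa_meta.get("AFR"),
            activities=cfg.activities,
        )
        report["ah_ppa"] = {
            "min_ppa": ah.min_ppa,
            "max_ppa": ah.max_ppa,
            "min_fold_vs_AFR": ah.min_fold,
            "max_fold_vs_AFR": ah.max_fold,
        }

    # --- index-SNP fold envelope ---------------------------------------------
    table = simulate_snp_panel_table(
        cfg.snp_panel_n, cfg.snp_panel_bin,
        cfg.snp_panel_fold[0], cfg.snp_panel_fold[1],
        seed=cfg.seed + 101, pop_a="AFR", pop_b="EUR",
    )
    focal = folds.get("TCT_EUR_over_AFR")
    if focal:
        fc = panel_fold_comparison(table, focal, "AFR", "EUR", cfg.snp_panel_bin)
        report["panel_fold_comparison"] = {
            "mean": fc.mean, "sd": fc.sd, "ci": list(fc.ci),
            "ks_p": fc.ks_p, "focal_fold": fc.focal_fold, "flag": fc.flag,
        }
    return report


def write_report(report: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    if "type_frequencies" in report:
        pd.DataFrame(report["type_frequencies"]).to_csv(
            out / "type_frequencies.tsv", sep="\t", index=False
        )
    if "ppa" in report:
        pd.Series(report["ppa"]["metapopulations"]).rename("PPA").to_csv(
            out / "ppa_metapopulations.tsv", sep="\t"
        )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, PromoterType):
        return x.value
    raise TypeError(f"not JSON serializable: {type(x)}")
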