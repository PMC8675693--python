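"""Readers, writers and the in-memory haplotype panel.

External coordinates follow VCF conventions (1-based, inclusive); internal
arrays are 0-based. A panel holds one row per *phase* of each diploid sample,
so a sample ``HG00097`` contributes haplotypes ``HG00097.0`` and ``HG00097.1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("regions are 1-based; start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class PopulationMap:
    """sample id -> (subpopulation code, meta-population code).

    Sample order is meaningful: it fixes the haplotype order of panels and the
    first-carrier naming of haplotype groups.
    """

    assignments: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("population map is empty")

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    def subpop(self, sample: str) -> str:
        return self.assignments[sample][0]

    def metapop(self, sample: str) -> str:
        return self.assignments[sample][1]

    @property
    def metapops(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, (_, meta) in self.assignments.items():
            seen.setdefault(meta, None)
        return list(seen)

    def subpops_of(self, metapop: str) -> list[str]:
        seen: dict[str, None] = {}
        for _, (sub, meta) in self.assignments.items():
            if meta == metapop:
                seen.setdefault(sub, None)
        return list(seen)

    @classmethod
    def read(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample", "subpop", "metapop"}
        if not required.issubset(df.columns):
            raise ValueError(f"population map needs columns {sorted(required)}")
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"sample {dup!r} appears more than once in map")
        return cls({r["sample"]: (r["subpop"], r["metapop"]) for _, r in df.iterrows()})

    def write(self, path) -> None:
        rows = [(s, sub, meta) for s, (sub, meta) in self.assignments.items()]
        pd.DataFrame(rows, columns=["sample", "subpop", "metapop"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class HaplotypePanel:
    """Phased allele matrix (haplotypes x sites) with population metadata."""

    region: GenomicRegion
    positions: np.ndarray  # 1-based site coordinates, strictly increasing
    alleles: np.ndarray  # dtype '<U1' over {A,C,G,T,N}
    haplotype_ids: list[str]  # "SAMPLE.k", k in {0,1}
    population_map: PopulationMap

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype="<U1")
        if self.alleles.shape != (len(self.haplotype_ids), len(self.positions)):
            raise ValueError(
                f"allele matrix {self.alleles.shape} inconsistent with "
                f"{len(self.haplotype_ids)} haplotypes x {len(self.positions)} sites"
            )
        if len(self.positions) and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.positions) and (
            self.positions[0] < self.region.start or self.positions[-1] > self.region.end
        ):
            raise ValueError("site positions fall outside the region")
        counts: dict[str, int] = {}
        for hid in self.haplotype_ids:
            counts[self.sample_of(hid)] = counts.get(self.sample_of(hid), 0) + 1
        bad = {s: c for s, c in counts.items() if c != 2}
        if bad:
            raise ValueError(f"expected exactly two haplotypes per sample; got {bad}")

    @staticmethod
    def sample_of(haplotype_id: str) -> str:
        return haplotype_id.rsplit(".", 1)[0]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def site_index(self, pos: int) -> int:
        idx = int(np.searchsorted(self.positions, pos))
        if idx >= len(self.positions) or self.positions[idx] != pos:
            raise KeyError(f"position {pos} not in panel")
        return idx

    def haplotype(self, haplotype_id: str) -> np.ndarray:
        return self.alleles[self.haplotype_ids.index(haplotype_id)]

    def subpop_of(self, haplotype_id: str) -> str:
        return self.population_map.subpop(self.sample_of(haplotype_id))

    def metapop_of(self, haplotype_id: str) -> str:
        return self.population_map.metapop(self.sample_of(haplotype_id))


def read_vcf_panel(path, region: GenomicRegion, pop_map: PopulationMap) -> HaplotypePanel:
    """Materialize a phased panel from a VCF over ``region``.

    Missing genotypes become ``N``; indels and symbolic alleles are skipped
    with a warning. Any unphased, non-missing genotype inside the region is an
    error (the analyses assume experimentally or statistically phased input).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    extra = [s for s in vcf_samples if s not in pop_map.assignments]
    if extra:
        raise ValueError(f"VCF sample(s) {extra} absent from population map")
    missing = [s for s in pop_map.samples if s not in vcf_samples]
    if missing:
        raise ValueError(f"map sample(s) {missing} absent from VCF")

    # Rows follow population-map order, phase 0 then phase 1 per sample.
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    order = [col_of[s] for s in pop_map.samples]

    positions: list[int] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if str(var.CHROM) != region.chrom or not region.contains(var.POS):
            continue
        alts = [a for a in var.ALT if a]
        alleles = [var.REF] + alts
        if any(len(a) != 1 or a not in "ACGT" for a in alleles):
            log.warning("skipping non-SNV record at %s:%d", var.CHROM, var.POS)
            continue
        lookup = np.array(alleles + ["N"], dtype="<U1")
        geno = np.asarray(var.genotypes)  # (n_samples, 3): a0, a1, phased
        col = np.empty(2 * len(order), dtype="<U1")
        for row, j in enumerate(order):
            a0, a1, phased = int(geno[j, 0]), int(geno[j, 1]), bool(geno[j, 2])
            if a0 < 0 or a1 < 0:
                col[2 * row] = "N"
                col[2 * row + 1] = "N"
                continue
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {vcf_samples[j]} at "
                    f"{var.CHROM}:{var.POS}"
                )
            col[2 * row] = lookup[a0]
            col[2 * row + 1] = lookup[a1]
        positions.append(var.POS)
        columns.append(col)

    hap_ids = [f"{s}.{k}" for s in pop_map.samples for k in (0, 1)]
    if columns:
        matrix = np.stack(columns, axis=1)
    else:
        matrix = np.empty((len(hap_ids), 0), dtype="<U1")
    return HaplotypePanel(region, np.array(positions), matrix, hap_ids, pop_map)


def write_vcf_panel(panel: HaplotypePanel, path) -> None:
    """Emit a minimal phased VCF 4.2 for the panel (text, uncompressed)."""
    samples = panel.population_map.samples
    row_of = {hid: i for i, hid in enumerate(panel.haplotype_ids)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.region.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, pos in enumerate(panel.positions):
            col = panel.alleles[:, j]
            seen: list[str] = []
            for b in col:
                if b != "N" and b not in seen:
                    seen.append(b)
            if not seen:  # fully missing column; arbitrary ref
                seen = ["A"]
            ref, alts = seen[0], seen[1:]
            code = {b: str(i) for i, b in enumerate(seen)}
            gts = []
            for s in samples:
                a0 = col[row_of[f"{s}.0"]]
                a1 = col[row_of[f"{s}.1"]]
                if a0 == "N" or a1 == "N":
                    gts.append(".|.")
                else:
                    gts.append(f"{code[a0]}|{code[a1]}")
            alt_field = ",".join(alts) if alts else "."
            fh.write(
                f"{panel.region.chrom}\t{pos}\tsite{pos}\t{ref}\t{alt_field}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_haplotype_fasta(panel: HaplotypePanel, path) -> None:
    """One FASTA record per haplotype; sequence is the concatenated site alleles."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if panel.n_sites == 0:
        raise ValueError("empty panel: no sites to write")
    records = [
        SeqRecord(Seq("".join(panel.alleles[i])), id=hid, description="")
        for i, hid in enumerate(panel.haplotype_ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_sites(panel: HaplotypePanel, positions) -> HaplotypePanel:
    """Sub-panel restricted to ``positions`` (order preserved, metadata kept)."""
    idx = [panel.site_index(int(p)) for p in positions]
    return replace(
        panel,
        positions=panel.positions[idx],
        alleles=panel.alleles[:, idx],
    )


def restrict_to_region(panel: HaplotypePanel, region: GenomicRegion) -> HaplotypePanel:
    """Sub-panel of sites falling inside ``region`` (same chromosome)."""
    mask = (panel.positions >= region.start) & (panel.positions <= region.end)
    return HaplotypePanel(
        region,
        panel.positions[mask],
        panel.alleles[:, mask],
        panel.haplotype_ids,
        panel.population_map,
    )
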