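import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from promoterpop.panel_io import GenomicRegion
from promoterpop.params import EvoParams
from promoterpop.haplotypes import PromoterType, SnpTriplet
from promoterpop.archaic_tracts import (
    UnphasedDiploid,
    amh_ah_difference_range,
    archaic_candidate_screen,
    beta_frequency_lower_bound,
    diploid_distance,
    infer_mosaic_structure,
    longest_identical_tract,
    phase_by_reference,
    rank_tract_partners,
    tract_survival_probability,
)
from promoterpop.synthetic_data import SimConfig, simulate_archaic_diploids, simulate_dataset

from conftest import build_panel


def diploid(sample, genotypes, positions=None):
    positions = positions or list(range(100, 100 + 100 * len(genotypes), 100))
    return UnphasedDiploid(sample, np.array(positions), np.array(genotypes, dtype="<U1"))


# --- phasing -----------------------------------------------------------------

def test_phase_by_reference_rules():
    ref = diploid("Altai", [("A", "A"), ("G", "G"), ("N", "N"), ("C", "C")])
    target = diploid("Vindija", [("A", "G"), ("G", "G"), ("A", "T"), ("N", "N")])
    ph = phase_by_reference(target, ref)
    # het A/G with hom-A reference: reference allele goes to haplotype "-2"
    assert ph.hap2[0] == "A" and ph.hap1[0] == "G"
    assert ph.hap1[1] == ph.hap2[1] == "G"  # homozygous copied to both
    assert ph.hap1[2] == "N" and ph.hap2[2] == "N"  # ref missing: unresolved
    assert ph.hap1[3] == "N"  # target missing
    assert list(ph.resolution) == [
        "reference-resolved", "homozygous", "unresolved", "unresolved",
    ]


def test_phase_by_reference_rejects_het_reference():
    ref = diploid("X", [("A", "G")])
    with pytest.raises(ValueError, match="reference not homozygous"):
        phase_by_reference(diploid("Y", [("A", "A")]), ref)


def test_phase_remerge_reproduces_genotypes():
    rng = np.random.default_rng(2)
    n = 50
    ref_allele = rng.choice(list("ACGT"), size=n)
    ref = UnphasedDiploid("R", np.arange(1, n + 1) * 10,
                          np.stack([ref_allele, ref_allele], axis=1))
    geno = np.stack([rng.choice(list("ACGT"), size=n), ref_allele], axis=1)
    target = UnphasedDiploid("T", ref.positions, geno)
    ph = phase_by_reference(target, ref)
    for i in range(n):
        if ph.resolution[i] != "unresolved":
            assert sorted([ph.hap1[i], ph.hap2[i]]) == sorted(geno[i])
    # one truth haplotype equals the reference at every het site, so both
    # phases are recovered exactly at resolved sites
    het = target.is_het()
    assert np.array_equal(ph.hap2[het], ref_allele[het])


def test_phase_end_to_end_recovers_simulated_truth(sim_dataset):
    ds = sim_dataset
    ref = next(d for d in ds.diploids if d.sample == "Altai")
    target = next(d for d in ds.diploids if d.sample == "Vindija")
    ph = phase_by_reference(target, ref)
    truth1 = ds.truth.derived_sequence(
        ds.truth.archaic_haplotypes["Vindija-1"], ds.panel.positions
    )
    truth2 = ds.truth.derived_sequence(
        ds.truth.archaic_haplotypes["Vindija-2"], ds.panel.positions
    )
    resolved = ph.resolution != "unresolved"
    # the reference-matching phase is "-2" by construction of the donor clade
    het = target.is_het()
    ok = resolved & het
    assert ok.sum() > 0
    assert np.array_equal(ph.hap2[ok], truth2[ok])
    assert np.array_equal(ph.hap1[ok], truth1[ok])


# --- diploid distance --------------------------------------------------------

def test_diploid_distance_site_rules():
    a = diploid("a", [("A", "A")])
    b = diploid("b", [("A", "G")])
    assert diploid_distance(a, b) == 0.5  # hom vs het sharing an allele
    assert diploid_distance(a, a) == 0.0
    c = diploid("c", [("C", "C")])
    assert diploid_distance(a, c) == 1.0  # hom vs different hom
    d1 = diploid("d", [("A", "G")])
    d2 = diploid("e", [("A", "C")])
    assert diploid_distance(d1, d2) == 0.5  # het vs het sharing one allele
    d3 = diploid("f", [("C", "T")])
    assert diploid_distance(d1, d3) == 1.0  # het vs disjoint het
    # haploid query behaves as a homozygote
    assert diploid_distance(np.array(["A"]), b) == 0.5


def test_diploid_distance_matches_pairing_enumeration():
    rng = np.random.default_rng(8)
    n = 60
    ga = rng.choice(list("ACGTN"), size=(n, 2), p=[0.3, 0.3, 0.2, 0.15, 0.05])
    gb = rng.choice(list("ACGTN"), size=(n, 2), p=[0.3, 0.3, 0.2, 0.15, 0.05])
    a = UnphasedDiploid("a", np.arange(n) + 1, ga)
    b = UnphasedDiploid("b", np.arange(n) + 1, gb)
    expected = 0.0
    for (a1, a2), (b1, b2) in zip(ga, gb):
        if "N" in (a1, a2, b1, b2):
            continue
        expected += min(
            ((a1 != b1) + (a2 != b2)) / 2.0,
            ((a1 != b2) + (a2 != b1)) / 2.0,
        )
    assert diploid_distance(a, b) == pytest.approx(expected)


# --- tracts ------------------------------------------------------------------

REGION = GenomicRegion("15", 1, 10_000)


def test_longest_identical_tract_whole_region_and_boundary():
    pos = np.arange(500, 9501, 500)
    q = np.array(["A"] * len(pos), dtype="<U1")
    hit = longest_identical_tract(q, q, pos, REGION, anchor=5000)
    assert (hit.start, hit.end, hit.length) == (1, 10_000, 10_000)
    s = q.copy()
    s[3] = "G"  # mismatch at position 2000, left of the anchor
    hit = longest_identical_tract(q, s, pos, REGION, anchor=5000)
    assert hit.start == 2001 and hit.end == 10_000  # starts just right of it
    # N sites are skipped and never break the run
    s2 = q.copy()
    s2[5] = "N"
    hit = longest_identical_tract(q, s2, pos, REGION, anchor=5000)
    assert (hit.start, hit.end) == (1, 10_000)
    assert hit.n_compared == len(pos) - 1
    with pytest.raises(ValueError, match="anchor"):
        longest_identical_tract(q, q, pos, REGION, anchor=20_000)


def test_planted_tract_interval_is_recovered(sim_dataset):
    ds = sim_dataset
    panel = ds.panel
    prom = ds.truth.promoter_positions
    carriers = list(ds.truth.intro_carriers)
    assert carriers
    recovered = 0
    for hid in carriers:
        lid, start, end = ds.truth.intro_carriers[hid]
        donor = ds.truth.derived_sequence(ds.truth.intro_lineages[lid], panel.positions)
        row = panel.alleles[panel.haplotype_ids.index(hid)]
        if not (start <= prom[0] and prom[2] <= end):
            continue  # tract too short to cover the promoter triplet
        hit = longest_identical_tract(
            row, donor, panel.positions, panel.region, anchor=(prom[0], prom[2])
        )
        # recovered boundaries within the local inter-SNP spacing
        sites = panel.positions
        lo_slack = _spacing(sites, start)
        hi_slack = _spacing(sites, end)
        if hit.start <= start + lo_slack and hit.end >= end - hi_slack:
            recovered += 1
    assert recovered >= 0.9 * sum(
        1 for h, (_, s, e) in ds.truth.intro_carriers.items()
        if s <= prom[0] and prom[2] <= e
    )


def _spacing(sites, pos):
    idx = np.searchsorted(sites, pos)
    lo = sites[max(idx - 1, 0)]
    hi = sites[min(idx, len(sites) - 1)]
    return int(hi - lo) + 1


def test_rank_tract_partners_orders_by_length():
    pos = np.arange(500, 9501, 500)
    q = np.array(list("AAAAAAAAAAAAAAAAAAA"), dtype="<U1")
    near = q.copy(); near[1] = "G"           # clean run from 1001 onward
    far = q.copy(); far[16] = "G"            # clean run up to 8499
    with pytest.raises(ValueError):
        rank_tract_partners(q, {}, pos, REGION, 5000)
    hits = rank_tract_partners(
        q, {"tgt_rep": near, "tct_rep": far, "exact": q.copy()}, pos, REGION, 5000
    )
    assert [h.partner for h in hits] == ["exact", "tgt_rep", "tct_rep"]
    assert hits[1].length == 9000 and hits[2].length == 8499
    assert hits[0].length == 10_000


def test_mosaic_structure_patterns():
    pos = np.arange(100, 10_001, 100)
    rng = np.random.default_rng(5)
    tgt = rng.choice(list("ACGT"), size=len(pos))
    cgt = tgt.copy()
    cgt[::4] = np.where(cgt[::4] == "A", "C", "A")  # diverged donor
    tct = tgt.copy()
    tct[1::4] = np.where(tct[1::4] == "G", "T", "G")
    donors = {"TGT": tgt, "CGT": cgt, "TCT": tct}
    # TGT - CGT - TGT mosaic
    q = tgt.copy()
    mid = (pos >= 3000) & (pos <= 7000)
    q[mid] = cgt[mid]
    labels = [s.label for s in infer_mosaic_structure(q, donors, pos, REGION)]
    assert labels == ["TGT", "CGT", "TGT"]
    # CGT - TCT - CGT mosaic
    q2 = cgt.copy()
    q2[mid] = tct[mid]
    labels2 = [s.label for s in infer_mosaic_structure(q2, donors, pos, REGION)]
    assert labels2 == ["CGT", "TCT", "CGT"]
    # pure single-donor sequence -> one segment
    labels3 = [s.label for s in infer_mosaic_structure(tct.copy(), donors, pos, REGION)]
    assert labels3 == ["TCT"]
    with pytest.raises(ValueError):
        infer_mosaic_structure(q, {"TGT": tgt}, pos, REGION)


def test_simulated_archaic_mosaic_is_labelled(sim_dataset):
    ds = sim_dataset
    assert "Denisovan-1" in ds.truth.archaic_mosaic
    pos = ds.panel.positions
    q = ds.truth.derived_sequence(ds.truth.archaic_haplotypes["Denisovan-1"], pos)
    donors = {
        "TGT": ds.truth.derived_sequence(ds.truth.type_templates["TGT"], pos),
        "AH": ds.truth.derived_sequence(
            ds.truth.archaic_haplotypes["Altai-1"], pos
        ),
    }
    labels = [s.label for s in infer_mosaic_structure(q, donors, pos, ds.panel.region)]
    assert labels == ["TGT", "AH", "TGT"]


# --- beta bound --------------------------------------------------------------

def test_beta_frequency_lower_bound_values():
    assert beta_frequency_lower_bound(8, 0, 0.95) == pytest.approx(0.717, abs=5e-4)
    assert beta_frequency_lower_bound(0, 0, 0.95) == pytest.approx(0.05)
    assert beta_frequency_lower_bound(2, 0, 0.95) == pytest.approx(0.05 ** (1 / 3))


@given(st.integers(0, 50), st.sampled_from([0.5, 0.9, 0.95, 0.99]))
def test_beta_bound_closed_form_when_no_alternatives(n, level):
    assert beta_frequency_lower_bound(n, 0, level) == pytest.approx(
        (1 - level) ** (1 / (n + 1)), rel=1e-12
    )


# --- tract survival ----------------------------------------------------------

def test_tract_survival_monotonic_and_limits():
    p = EvoParams()
    assert tract_survival_probability(0, p, 450_000) == 1.0
    vals_m = [tract_survival_probability(m, p, 450_000) for m in (1e3, 1e4, 1e5)]
    assert vals_m == sorted(vals_m, reverse=True)
    vals_t = [tract_survival_probability(1e4, p, t) for t in (1e5, 5e5, 1e6)]
    assert vals_t == sorted(vals_t, reverse=True)


def test_tract_survival_matches_monte_carlo():
    p = EvoParams()
    rng = np.random.default_rng(12)
    for m, t in ((9_000, 450_000.0), (28_042, 550_000.0)):
        lam = m * p.r * t / p.g  # expected crossovers in the tract
        reps = 100_000
        k = rng.poisson(lam, size=reps)
        mc = np.mean(k == 0)
        se = np.sqrt(mc * (1 - mc) / reps)
        assert abs(tract_survival_probability(m, p, t) - mc) <= 3 * max(se, 1e-6)


# --- AMH-AH range and screen -------------------------------------------------

def test_amh_ah_difference_range_basics():
    a = ["AAAA", "AAAA"]
    assert amh_ah_difference_range(["x", "y"], a, ["z"], ["AAAA"]) == (0, 0)
    with pytest.raises(ValueError):
        amh_ah_difference_range(["x"], ["AAAA"], ["z"], ["AAAA"], exclusions=["x"])
    # removing a planted recombinant narrows the range
    clade_a = ["AAAAAAAAAA", "AAAAAAAAAC"]
    clade_b = ["GGGGGGGGGC"]
    recombinant = "AAAAAGGGGC"  # half donor half modern
    full = amh_ah_difference_range(
        ["a1", "a2", "rec"], clade_a + [recombinant], ["b1"], clade_b
    )
    clean = amh_ah_difference_range(
        ["a1", "a2", "rec"], clade_a + [recombinant], ["b1"], clade_b,
        exclusions=["rec"],
    )
    assert full == (5, 10) and clean == (9, 10)


AFR_SEQ = "AAAAAAAAAAAA"
AFR_REL = "AAAAAAAAAAAC"  # 1 difference from AFR_SEQ: a close relative
CANDIDATE = "GGGGGGGGGGGG"  # 12 differences: inside the (10, 14) range


def _screen_fixture():
    """Tiny panel: one widespread African lineage, one distant candidate.

    S000 (YRI) and S001 phase 0 (LWK) carry the widespread lineage; S001
    phase 1 its close relative; S002 phase 0 (GIH) the distant candidate.
    """
    seqs = [AFR_SEQ, AFR_SEQ, AFR_SEQ, AFR_REL, CANDIDATE, AFR_SEQ]
    pops = [("YRI", "AFR"), ("LWK", "AFR"), ("GIH", "SAS")]
    return build_panel(seqs, pops)


def test_screen_rejects_african_widespread_and_relatives():
    panel = _screen_fixture()
    triplet = SnpTriplet(positions=(100, 200, 300))  # degenerate: all OTHER
    ages = {p * 100: 50_000.0 for p in range(1, 13)}
    res = archaic_candidate_screen(
        panel, triplet, PromoterType.OTHER, (10, 14), ages
    )
    # the all-A group spans >= 2 African subpops: rejected; its 1-difference
    # relative is rejected as well; the distant candidate survives
    assert res.afr_widespread == ["S000.0"]
    assert res.rejected_afr == ["S000.0"]
    assert res.rejected_relatives == ["S001.1"]
    assert res.survivors == ["S002.0"]
    assert res.age_unknown == []


def test_screen_flags_age_unknown_candidates():
    panel = _screen_fixture()
    triplet = SnpTriplet(positions=(100, 200, 300))
    res = archaic_candidate_screen(
        panel, triplet, PromoterType.OTHER, (10, 14), age_table={}
    )
    assert res.survivors == ["S002.0"]
    assert res.age_unknown == ["S002.0"]  # kept, not silently rejected


def test_screen_rejects_old_candidates_by_age():
    panel = _screen_fixture()
    triplet = SnpTriplet(positions=(100, 200, 300))
    old_ages = {p * 100: 800_000.0 for p in range(1, 13)}
    res = archaic_candidate_screen(
        panel, triplet, PromoterType.OTHER, (10, 14), old_ages
    )
    assert res.survivors == [] and res.rejected_age == ["S002.0"]


def test_screen_is_invariant_to_sample_relabelling():
    # permuting sample blocks must permute, not change, the surviving set
    triplet = SnpTriplet(positions=(100, 200, 300))
    base = archaic_candidate_screen(
        _screen_fixture(), triplet, PromoterType.OTHER, (10, 14), {}
    )
    perm_seqs = [CANDIDATE, AFR_SEQ, AFR_SEQ, AFR_REL, AFR_SEQ, AFR_SEQ]
    perm_pops = [("GIH", "SAS"), ("LWK", "AFR"), ("YRI", "AFR")]
    perm = archaic_candidate_screen(
        build_panel(perm_seqs, perm_pops), triplet, PromoterType.OTHER, (10, 14), {}
    )
    base_surv = {g.sequence for g in base.groups if g.name in base.survivors}
    perm_surv = {g.sequence for g in perm.groups if g.name in perm.survivors}
    assert base_surv == perm_surv == {CANDIDATE}
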