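"""Diploid locus vetting, diagnostic SNV discovery, read partition, consensus."""

import numpy as np
import pytest

from clamtc.mapping import SeedIndex, is_confident, place_reads
from clamtc.nuclear import (ConsensusHaplotype, DiagnosticSite, call_consensus,
                            cohort_allele_matrix, consensus_from_partition,
                            diploid_locus_filter, find_diagnostic_sites,
                            partition_reads, specimen_vaf)
from clamtc.seqcodes import encode
from clamtc.simulate import (SimulationConfig, simulate_cohort,
                             simulate_neoplastic_cohort, simulate_species_pair,
                             simulate_specimen_reads, simulate_tumour_lineage,
                             substream)


# ---------------------------------------------------------------------------
# diploid locus filter
# ---------------------------------------------------------------------------

def _table(vafs, depth=30):
    v = np.asarray(vafs, dtype=float)
    return v, np.full(v.size, depth)


def test_grid_vafs_accepted():
    tables = {"locus0": {"host": [_table([0, 0.5, 1.0, 0.0])],
                         "donor": [_table([0, 0, 0.5, 1.0])]}}
    res = diploid_locus_filter(tables)
    assert res["locus0"] == (True, "ok")


def test_off_grid_vaf_rejects_locus():
    # a paralog-collapsed site shows a 1/3-ish VAF in one specimen
    tables = {"locus0": {"host": [_table([0, 0.33, 1.0])],
                         "donor": [_table([0, 0, 0])]}}
    accepted, reason = diploid_locus_filter(tables)["locus0"]
    assert not accepted and reason == "off-grid VAF"


def test_locus_missing_from_one_species_rejected():
    tables = {"locus0": {"host": [_table([0, 0.5])], "donor": []}}
    accepted, reason = diploid_locus_filter(tables)["locus0"]
    assert not accepted and "not present" in reason


def test_low_depth_sites_not_evaluated():
    tables = {"locus0": {"host": [(np.array([0.33]), np.array([4]))],
                         "donor": [_table([0.0])]}}
    assert diploid_locus_filter(tables, min_depth=8)["locus0"][0]


def test_tolerance_bounds_validated():
    with pytest.raises(ValueError, match="tolerance"):
        diploid_locus_filter({}, tolerance=0.3)


def test_sequenced_single_copy_loci_pass_grid_filter():
    """Single-copy loci pass the grid filter at depth-matched tolerance.

    A het site's VAF is binomial over *fragments* (mates are correlated),
    so its SD at 100x coverage is ~sqrt(0.25/50) ~ 0.07; tolerance 0.2
    then bounds the per-site failure probability near 0.005 and the
    per-locus acceptance above 0.95.
    """
    cfg = SimulationConfig(seed=41, mito_length=2000, nuclear_locus_lengths=(600,),
                           coverage_nuclear=100)
    accepted = 0
    n_loci = 100
    for i in range(n_loci):
        cfg_i = cfg.with_(seed=41 + i)
        pair = simulate_species_pair(cfg_i)
        sp = simulate_cohort(pair, "host", 1, cfg_i)[0]
        bundle = simulate_specimen_reads(sp, None, pair, cfg_i, "foot",
                                         templates=("nuclear",))
        ids, mat = bundle.all_reads()
        idx = SeedIndex({"locus0": pair.host_loci[0]})
        pl = [p if is_confident(p) else None for p in place_reads(mat, ids, idx)]
        from clamtc.mapping import build_pileup
        pile = build_pileup(pl, mat, "locus0", pair.host_loci[0])
        vaf, depth = specimen_vaf(pile, pair.host_loci[0])
        tables = {"locus0": {"host": [(vaf, depth)], "donor": [_table([0.0])]}}
        accepted += diploid_locus_filter(tables, tolerance=0.2)["locus0"][0]
    assert accepted / n_loci >= 0.95


# ---------------------------------------------------------------------------
# diagnostic sites
# ---------------------------------------------------------------------------

def test_identical_cohorts_have_no_diagnostic_sites():
    mat = np.vstack([encode("ACGTACGT")] * 6)
    assert find_diagnostic_sites(mat, mat.copy()) == []


def test_toy_fixed_difference_found():
    a = np.vstack([encode("AAAAAAAC")] * 18)   # 9 diploids, homozygous C at pos 7
    a[:, 7] = 1
    b = np.vstack([encode("AAAAAAAT")] * 24)   # 12 diploids, homozygous T
    b[:, 7] = 3
    sites = find_diagnostic_sites(a, b, "toy")
    assert len(sites) == 1
    s = sites[0]
    assert (s.position, s.allele_a, s.allele_b) == (7, "C", "T")
    assert s.freq_a == 1.0 and s.freq_b == 1.0


def test_single_variant_copy_keeps_site_diagnostic():
    """24 copies with one mutated still clears the 95% fixation bar."""
    a = np.vstack([encode("AAAA")] * 24)
    a[0, 2] = 2  # one G copy at position 2
    a[:, 2] = np.where(a[:, 2] == 0, 1, a[:, 2])  # cohort otherwise C
    b = np.vstack([encode("AAAA")] * 18)
    b[:, 2] = 3
    sites = find_diagnostic_sites(a, b)
    assert any(s.position == 2 and s.freq_a == pytest.approx(23 / 24) for s in sites)


def test_empty_cohort_rejected():
    with pytest.raises(ValueError, match="empty cohort"):
        find_diagnostic_sites(np.zeros((0, 5), dtype=np.uint8),
                              np.vstack([encode("ACGTA")]))


def test_symmetry_under_cohort_swap(species_pair, host_cohort, donor_cohort):
    a = cohort_allele_matrix(host_cohort, 0)
    b = cohort_allele_matrix(donor_cohort, 0)
    s_ab = find_diagnostic_sites(a, b, "locus0")
    s_ba = find_diagnostic_sites(b, a, "locus0")
    assert {(s.position, s.allele_a, s.allele_b) for s in s_ab} == \
        {(s.position, s.allele_b, s.allele_a) for s in s_ba}


def test_planted_differences_recovered_exactly(species_pair, host_cohort, donor_cohort):
    truth = {p for p, _, _ in species_pair.fixed_differences["locus0"]}
    a = cohort_allele_matrix(host_cohort, 0)
    b = cohort_allele_matrix(donor_cohort, 0)
    found = {s.position for s in find_diagnostic_sites(a, b, "locus0")}
    assert found == truth


# ---------------------------------------------------------------------------
# read partition
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def partition_setup():
    cfg = SimulationConfig(seed=47, mito_length=2000, nuclear_locus_lengths=(1500,),
                           coverage_nuclear=60)
    pair = simulate_species_pair(cfg)
    lineage = simulate_tumour_lineage(pair, cfg)
    hosts = simulate_cohort(pair, "host", 12, cfg)
    donors = simulate_cohort(pair, "donor", 9, cfg)
    sites = find_diagnostic_sites(cohort_allele_matrix(hosts, 0),
                                  cohort_allele_matrix(donors, 0), "locus0")
    prof = simulate_neoplastic_cohort(pair, 1, cfg, stages=["N3"])[0]
    bundle = simulate_specimen_reads(prof, lineage, pair, cfg, "haemolymph",
                                     templates=("nuclear",))
    ids, mat = bundle.all_reads()
    idx = SeedIndex({"locus0": pair.host_loci[0]})
    conf = [p if is_confident(p) else None for p in place_reads(mat, ids, idx)]
    return cfg, pair, lineage, prof, sites, bundle, mat, conf


def test_partition_is_disjoint_and_exhaustive(partition_setup):
    cfg, pair, lineage, prof, sites, bundle, mat, conf = partition_setup
    part = partition_reads(conf, mat, sites, reference_id="locus0")
    groups = [set(part.host_reads), set(part.donor_reads), set(part.ambiguous_reads)]
    assert sum(len(g) for g in groups) == len(set().union(*groups))
    # exhaustive over reads covering >= 1 diagnostic site
    pos = np.array([s.position for s in sites])
    covered = {i for i, p in enumerate(conf) if p is not None
               and ((pos >= p.position) & (pos < p.position + mat.shape[1])).any()}
    assert set().union(*groups) == covered


def test_partition_agrees_with_truth_table(partition_setup):
    cfg, pair, lineage, prof, sites, bundle, mat, conf = partition_setup
    ids, _ = bundle.all_reads()
    truth = dict(zip(bundle.truth.read_id, bundle.truth.source))
    part = partition_reads(conf, mat, sites, reference_id="locus0")
    wrong = sum(truth[ids[i]] != "host_cell" for i in part.host_reads) + \
        sum(truth[ids[i]] != "tumour_cell" for i in part.donor_reads)
    assigned = len(part.host_reads) + len(part.donor_reads)
    assert assigned > 0
    assert wrong / assigned <= 0.001
    # donor share among assigned tracks the N3 haemolymph cell fraction
    assert abs(len(part.donor_reads) / assigned - 0.9) <= 0.05


def test_mixed_allele_read_is_ambiguous():
    sites = [DiagnosticSite("l", 2, "A", "G", 1.0, 1.0),
             DiagnosticSite("l", 5, "C", "T", 1.0, 1.0)]
    from clamtc.mapping import ReadPlacement
    reads = np.vstack([encode("AAATTTAA"), encode("AAATTCAA"), encode("GGGTTTAA")])
    reads[0, 2], reads[0, 5] = 0, 3   # host allele then donor allele -> ambiguous
    reads[1, 2], reads[1, 5] = 0, 1   # both host alleles -> host
    reads[2, 2], reads[2, 5] = 2, 3   # both donor alleles -> donor
    pl = [ReadPlacement(f"r{i}", "l", 0, "+", 8, 8) for i in range(3)]
    part = partition_reads(pl, reads, sites)
    assert part.ambiguous_reads == [0]
    assert part.host_reads == [1] and part.donor_reads == [2]


def test_error_free_disjoint_haplotypes_leave_no_ambiguity():
    cfg = SimulationConfig(seed=48, mito_length=2000, nuclear_locus_lengths=(1200,),
                           coverage_nuclear=40, error_rate=0.0, theta_within=0.0)
    pair = simulate_species_pair(cfg)
    lineage = simulate_tumour_lineage(pair, cfg)
    prof = simulate_neoplastic_cohort(pair, 1, cfg, stages=["N2"])[0]
    hosts = simulate_cohort(pair, "host", 3, cfg)
    donors = simulate_cohort(pair, "donor", 3, cfg)
    sites = find_diagnostic_sites(cohort_allele_matrix(hosts, 0),
                                  cohort_allele_matrix(donors, 0), "locus0")
    bundle = simulate_specimen_reads(prof, lineage, pair, cfg, "haemolymph",
                                     templates=("nuclear",))
    ids, mat = bundle.all_reads()
    idx = SeedIndex({"locus0": pair.host_loci[0]})
    conf = [p if is_confident(p) else None for p in place_reads(mat, ids, idx)]
    part = partition_reads(conf, mat, sites, reference_id="locus0")
    assert part.ambiguous_reads == []


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_pure_error_free_reads_give_exact_consensus():
    cfg = SimulationConfig(seed=49, mito_length=2000, nuclear_locus_lengths=(900,),
                           coverage_nuclear=30, error_rate=0.0, theta_within=0.0)
    pair = simulate_species_pair(cfg)
    sp = simulate_cohort(pair, "host", 1, cfg)[0]
    bundle = simulate_specimen_reads(sp, None, pair, cfg, "foot",
                                     templates=("nuclear",))
    ids, mat = bundle.all_reads()
    idx = SeedIndex({"locus0": pair.host_loci[0]})
    conf = [p if is_confident(p) else None for p in place_reads(mat, ids, idx)]
    cons = consensus_from_partition(list(range(len(conf))), conf, mat,
                                    "locus0", pair.host_loci[0], "locus0", "host")
    called = np.array(list(cons.sequence)) != "N"
    assert cons.identity_to(pair.host_loci[0]) == 1.0
    # coverage ramps over ~1 insert length at each end of a linear locus,
    # so only those edges may stay uncalled
    assert called.mean() > 0.8
    assert called[400:500].all()


def test_subfixation_vaf_yields_N():
    from clamtc.mapping import Pileup
    pile = Pileup("l", 3)
    pile.counts[0, 0] = 30          # pure A: called
    pile.counts[0, 1], pile.counts[2, 1] = 17, 3   # 0.85 A: below 0.9 -> N
    pile.counts[1, 2] = 5           # depth below min_depth -> N
    cons = call_consensus(pile, "l", "host")
    assert cons.sequence == "ANN"


def test_empty_partition_warns_and_returns_all_N():
    from clamtc.mapping import Pileup
    with pytest.warns(UserWarning, match="empty partition"):
        cons = call_consensus(Pileup("l", 5), "l", "tumour")
    assert cons.sequence == "NNNNN"


def test_tumour_consensus_identity_and_clonality():
    """Six specimens' tumour consensuses match the lineage and each other."""
    from clamtc.experiments import consensus_study
    res = consensus_study(seed=50, n_specimens=3, coverage=60,
                          locus_lengths=(900,))
    assert res["tumour_identity_min"] >= 0.999
    assert res["host_identity_min"] >= 0.999
    assert res["identical_tumour_pair_fraction"] == 1.0
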