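"""Seeded simulation studies that validate each inference stage.

These are the package's parameter-recovery experiments: each function
generates synthetic data under known ground truth, runs the relevant
inference stage(s), and reports recovery statistics. They are shared by
the test suite and the acceptance script so that every reported number
is recomputed from scratch.

Problem sizes are scaled to keep each study in the seconds-to-a-couple-
of-minutes range: mitogenomes of a few kb carry the same per-read
information as 18-kb ones for fraction recovery and topology tests,
since every statistic here concentrates with total read count or
alignment length, both of which are kept large enough for the stated
tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import deconv, markers, nuclear, phylo
from .mapping import SeedIndex, is_confident, place_reads
from .seqcodes import encode
from .simulate import (SimulationConfig, SpecimenProfile, mixture_expected_fraction,
                       simulate_cohort, simulate_neoplastic_cohort, simulate_outgroup,
                       simulate_species_pair, simulate_specimen_reads,
                       simulate_tumour_lineage, substream)

__all__ = [
    "species_pair_summary", "mixture_recovery_study", "diagnostic_recovery_study",
    "consensus_study", "placement_study", "marker_study",
]


def species_pair_summary(seed: int, mito_length: int = 18000,
                         target_k2p: float = 0.21, kappa: float = 2.0) -> dict:
    """Realised K2P and transition/transversion ratio of a simulated pair."""
    cfg = SimulationConfig(seed=seed, mito_length=mito_length,
                           target_k2p=target_k2p, kappa=kappa)
    pair = simulate_species_pair(cfg)
    c = phylo.count_substitutions(pair.host_mito, pair.donor_mito)
    return {
        "realized_k2p": phylo.k2p(c),
        "ts_tv_ratio": c.transitions / c.transversions,
        "n_differences": c.transitions + c.transversions,
        "n_sites": c.n,
    }


def _profile_with_fraction(pair, cfg: SimulationConfig, f: float,
                           idx: int) -> SpecimenProfile:
    prof = simulate_cohort(pair, "host", 1, cfg, stage="N0",
                           id_prefix=f"mix_{idx}")[0]
    prof.stage = "N2"
    prof.tissue_tumour_fraction = {"haemolymph": f, "foot": 0.0}
    return prof


def mixture_recovery_study(seed: int, fractions=tuple(np.round(np.arange(0.1, 0.95, 0.1), 2)),
                           replicates: int = 20, coverage: float = 100.0,
                           mito_length: int = 4000, copy_ratio: float = 1.0,
                           tolerance: float = 0.03) -> dict:
    """Recover the donor mtDNA read fraction across tumour cell fractions.

    For each cell fraction, ``replicates`` independent libraries are
    simulated at the given mitochondrial coverage and deconvolved; a
    replicate counts as recovered when |phi - expected| <= tolerance.
    """
    results = []
    for f in fractions:
        for r in range(replicates):
            cfg = SimulationConfig(seed=int(seed), mito_length=mito_length,
                                   coverage_mito=coverage,
                                   mito_copy_ratio=copy_ratio).validate()
            # each (fraction, replicate) gets its own pair and library
            sub = substream(seed, "mixrep", int(round(f * 100)), r)
            rep_seed = int(sub.integers(0, 2**31 - 1))
            cfg = cfg.with_(seed=rep_seed)
            pair = simulate_species_pair(cfg)
            lineage = simulate_tumour_lineage(pair, cfg)
            prof = _profile_with_fraction(pair, cfg, float(f), r)
            bundle = simulate_specimen_reads(prof, lineage, pair, cfg, "haemolymph",
                                             templates=("mito",))
            ids, mat = bundle.all_reads()
            res = deconv.deconvolve_tissue(mat, ids, pair.host_mito, pair.donor_mito)
            expected = mixture_expected_fraction(float(f), copy_ratio)
            results.append({"fraction": float(f), "replicate": r,
                            "phi": res.phi, "expected": expected,
                            "abs_error": abs(res.phi - expected)})
    errors = np.array([r["abs_error"] for r in results])
    return {
        "per_replicate": results,
        "within_tolerance_rate": float((errors <= tolerance).mean()),
        "mean_abs_error": float(errors.mean()),
        "max_abs_error": float(errors.max()),
        "n_replicates": len(results),
    }


def diagnostic_recovery_study(seed: int, n_seeds: int = 50, n_host: int = 12,
                              n_donor: int = 9, theta: float = 0.002,
                              n_fixed: int = 20, locus_length: int = 1000,
                              min_freq: float = 0.95) -> dict:
    """Sensitivity/specificity of diagnostic-site discovery from cohorts.

    Healthy diploid cohorts of both species are simulated with
    ``n_fixed`` planted interspecific differences per locus; discovered
    sites are compared with the planted ground truth.
    """
    per_seed = []
    for s in range(n_seeds):
        sub = substream(seed, "diag", s)
        cfg = SimulationConfig(seed=int(sub.integers(0, 2**31 - 1)),
                               nuclear_locus_lengths=(locus_length,),
                               nuclear_fixed_counts=(n_fixed,),
                               theta_within=theta).validate()
        pair = simulate_species_pair(cfg)
        hosts = simulate_cohort(pair, "host", n_host, cfg)
        donors = simulate_cohort(pair, "donor", n_donor, cfg)
        mat_a = nuclear.cohort_allele_matrix(hosts, 0)
        mat_b = nuclear.cohort_allele_matrix(donors, 0)
        sites = nuclear.find_diagnostic_sites(mat_a, mat_b, "locus0", min_freq)
        found = {s_.position for s_ in sites}
        truth = {p for p, _, _ in pair.fixed_differences["locus0"]}
        tp = len(found & truth)
        per_seed.append({"seed_index": s, "sensitivity": tp / len(truth),
                         "false_sites": len(found - truth)})
    sens = np.array([r["sensitivity"] for r in per_seed])
    fps = np.array([r["false_sites"] for r in per_seed])
    return {
        "per_seed": per_seed,
        "perfect_rate": float(((sens == 1.0) & (fps == 0)).mean()),
        "mean_sensitivity": float(sens.mean()),
        "total_false_sites": int(fps.sum()),
        "n_seeds": n_seeds,
    }


def consensus_study(seed: int, n_specimens: int = 6, coverage: float = 100.0,
                    locus_lengths=(2900, 2200), stage: str = "N2") -> dict:
    """Tumour/host consensus recovery from partitioned neoplastic reads.

    Simulates ``n_specimens`` neoplastic animals sharing one clonal
    lineage, maps their haemolymph nuclear reads onto the host-species
    locus references, partitions reads at the diagnostic sites found
    from healthy cohorts, calls per-origin consensus, and measures
    identity against the true haplotypes.
    """
    cfg = SimulationConfig(seed=seed, nuclear_locus_lengths=tuple(locus_lengths),
                           coverage_nuclear=coverage).validate()
    pair = simulate_species_pair(cfg)
    lineage = simulate_tumour_lineage(pair, cfg)
    hosts = simulate_cohort(pair, "host", 12, cfg)
    donors = simulate_cohort(pair, "donor", 9, cfg)
    neo = simulate_neoplastic_cohort(pair, n_specimens, cfg,
                                     stages=[stage] * n_specimens)

    refs = {name: seq for name, seq in zip(pair.locus_names, pair.host_loci)}
    index = SeedIndex(refs, k=21)
    sites_by_locus = {}
    for li, name in enumerate(pair.locus_names):
        mat_a = nuclear.cohort_allele_matrix(hosts, li)
        mat_b = nuclear.cohort_allele_matrix(donors, li)
        sites_by_locus[name] = nuclear.find_diagnostic_sites(mat_a, mat_b, name)

    tumour_ident, host_ident = [], []
    tumour_seqs: dict[str, list[str]] = {n_: [] for n_ in pair.locus_names}
    min_part_depth = []
    for prof in neo:
        bundle = simulate_specimen_reads(prof, lineage, pair, cfg, "haemolymph",
                                         templates=("nuclear",))
        ids, mat = bundle.all_reads()
        placements = place_reads(mat, ids, index)
        conf = [p if is_confident(p) else None for p in placements]
        for li, name in enumerate(pair.locus_names):
            part = nuclear.partition_reads(conf, mat, sites_by_locus[name],
                                           reference_id=name)
            tum = nuclear.consensus_from_partition(
                part.donor_reads, conf, mat, name, refs[name], name, "tumour")
            hst = nuclear.consensus_from_partition(
                part.host_reads, conf, mat, name, refs[name], name, "host")
            tumour_ident.append(tum.identity_to(lineage.locus_haplotypes[li][0]))
            host_ident.append(hst.identity_to(prof.germline_loci[li][0]))
            tumour_seqs[name].append(tum.sequence)
            called = encode(tum.sequence) < 4
            if called.any():
                min_part_depth.append(float(np.median(tum.depth[called])))

    # pairwise comparison of tumour consensuses at jointly called sites
    mismatch_pairs = 0
    total_pairs = 0
    for name, seqs in tumour_seqs.items():
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                a, b = encode(seqs[i]), encode(seqs[j])
                both = (a < 4) & (b < 4)
                total_pairs += 1
                if (a[both] != b[both]).any():
                    mismatch_pairs += 1
    return {
        "tumour_identity_min": float(np.min(tumour_ident)),
        "tumour_identity_mean": float(np.mean(tumour_ident)),
        "host_identity_min": float(np.min(host_ident)),
        "host_identity_mean": float(np.mean(host_ident)),
        "identical_tumour_pair_fraction": 1.0 - mismatch_pairs / total_pairs,
        "median_partition_depth": float(np.median(min_part_depth)),
        "n_specimens": n_specimens,
    }


def placement_study(seed: int, n_seeds: int = 100, n_tumour: int = 6,
                    n_host: int = 5, n_donor: int = 2, mito_length: int = 2000,
                    bootstrap_seeds: int = 3, n_replicates: int = 100) -> dict:
    """Phylogenetic placement of the tumour lineage over seeded simulations.

    For each seed a species pair, healthy germlines of both species, a
    clonal lineage (shared by all tumour leaves) and an outgroup are
    simulated; the K2P/NJ tree is tested for tumour monophyly and
    donor-sister placement. Bootstrap support of the interspecies split
    is computed for the first ``bootstrap_seeds`` seeds.
    """
    mono, sister, supports = [], [], []
    for s in range(n_seeds):
        sub = substream(seed, "placement", s)
        cfg = SimulationConfig(seed=int(sub.integers(0, 2**31 - 1)),
                               mito_length=mito_length).validate()
        pair = simulate_species_pair(cfg)
        lineage = simulate_tumour_lineage(pair, cfg)
        hosts = simulate_cohort(pair, "host", n_host, cfg)
        donors = simulate_cohort(pair, "donor", n_donor, cfg)
        outgroup = simulate_outgroup(pair, cfg)

        labels, rows, classes = [], [], {}
        labels.append("outgroup")
        rows.append(encode(outgroup))
        classes["outgroup"] = "outgroup"
        for i, sp in enumerate(donors):
            lab = f"donor_{i}"
            labels.append(lab)
            rows.append(encode(sp.germline_mito))
            classes[lab] = "donor"
        for i, sp in enumerate(hosts):
            lab = f"host_{i}"
            labels.append(lab)
            rows.append(encode(sp.germline_mito))
            classes[lab] = "host"
        for i in range(n_tumour):
            lab = f"tumour_{i}"
            labels.append(lab)
            rows.append(encode(lineage.mito_haplotype))
            classes[lab] = "tumour"
        aln = np.vstack(rows)
        result = phylo.neighbor_joining(labels, phylo.k2p_matrix(aln))
        verdict = phylo.tumour_placement_test(result, classes)
        mono.append(verdict.tumour_monophyletic)
        sister.append(verdict.sister_is_donor)
        if s < bootstrap_seeds:
            _, sup = phylo.bootstrap_support(labels, aln, n_replicates=n_replicates,
                                             seed=substream(seed, "bs", s))
            host_side = frozenset(l for l, c in classes.items() if c == "host")
            universe = frozenset(labels)
            key = phylo._normalise(host_side, labels[0], universe)
            supports.append(sup.get(key, 0.0))
    return {
        "monophyly_rate": float(np.mean(mono)),
        "sister_rate": float(np.mean(sister)),
        "both_rate": float(np.mean(np.array(mono) & np.array(sister))),
        "species_split_bootstrap_min": float(np.min(supports)) if supports else None,
        "n_seeds": n_seeds,
    }


def marker_study(seed: int, stage: str = "N3", coverage: float = 30.0,
                 mito_length: int = 6000, n_decoys: int = 116) -> dict:
    """Marker-panel screen of one neoplastic haemolymph library.

    Whole-mitogenome reads are classified against the 118-entry barcode
    panel; reads away from the marker region go unassigned, and the
    assigned ones should collapse onto the host and donor species.
    """
    cfg = SimulationConfig(seed=seed, mito_length=mito_length,
                           coverage_mito=coverage).validate()
    pair = simulate_species_pair(cfg)
    lineage = simulate_tumour_lineage(pair, cfg)
    prof = simulate_neoplastic_cohort(pair, 1, cfg, stages=[stage])[0]
    bundle = simulate_specimen_reads(prof, lineage, pair, cfg, "haemolymph",
                                     templates=("mito",))
    ids, mat = bundle.all_reads()
    panel = markers.build_marker_panel(pair, cfg, n_decoys=n_decoys)
    report = markers.classify_reads(mat, ids, panel)
    flag, top = markers.two_species_test(report)
    joint = sum(p for _, p in report.top(2))
    return {
        "two_species_flag": bool(flag),
        "top_species": list(top),
        "top_two_joint_fraction": float(joint),
        "assigned": report.assigned,
        "total_reads": report.total_reads,
    }
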