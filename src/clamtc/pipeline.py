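"""End-to-end pipeline: simulate -> classify -> deconvolve -> nuclear -> phylogeny.

Each stage is a file-based function (so the CLI subcommands can run them
independently on a simulation directory) and :func:`run_all` chains
them. All outputs are plain text (FASTA, gzipped FASTQ, TSV, JSON,
newick) under the chosen output directory, and a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, deconv, markers, nuclear, phylo
from .io import read_fasta, read_fastq_codes, write_fasta, write_fastq_gz
from .mapping import (DEFAULT_MIN_MARGIN, SeedIndex, build_pileup, is_confident,
                      place_reads)
from .seqcodes import encode
from .simulate import (SimulationConfig, simulate_cohort, simulate_neoplastic_cohort,
                       simulate_outgroup, simulate_species_pair,
                       simulate_specimen_reads, simulate_tumour_lineage)

log = logging.getLogger("clamtc")

DEFAULT_NEOPLASTIC_STAGES = ("N2", "N2", "N2", "N3", "N3", "N3")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-study run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_healthy_host: int = 12
    n_healthy_donor: int = 9
    n_neoplastic: int = 6
    neoplastic_stages: tuple[str, ...] = DEFAULT_NEOPLASTIC_STAGES
    min_margin: int = DEFAULT_MIN_MARGIN
    two_species_threshold: float = 0.99
    tau: float = deconv.DEFAULT_TAU
    min_windows: int = deconv.DEFAULT_MIN_WINDOWS
    window_size: int = deconv.DEFAULT_WINDOW
    min_freq: float = nuclear.DEFAULT_MIN_FREQ
    fixation_threshold: float = nuclear.DEFAULT_FIXATION
    vaf_tolerance: float = nuclear.DEFAULT_VAF_TOLERANCE
    min_depth: int = nuclear.DEFAULT_MIN_DEPTH
    bootstrap_replicates: int = 100
    n_phylo_host_leaves: int = 5
    n_phylo_donor_leaves: int = 2
    do_classify: bool = True
    do_deconv: bool = True
    do_nuclear: bool = True
    do_phylo: bool = True

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        if self.n_neoplastic > len(self.neoplastic_stages):
            raise ValueError("not enough neoplastic_stages for n_neoplastic")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["nuclear_locus_lengths"] = list(self.sim.nuclear_locus_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            known = set(SimulationConfig.__dataclass_fields__)
            bad = set(sim) - known
            if bad:
                raise ValueError(f"unknown simulation config field(s): {sorted(bad)}")
            if "nuclear_locus_lengths" in sim:
                sim["nuclear_locus_lengths"] = tuple(sim["nuclear_locus_lengths"])
            if "nuclear_fixed_counts" in sim and sim["nuclear_fixed_counts"] is not None:
                sim["nuclear_fixed_counts"] = tuple(sim["nuclear_fixed_counts"])
            sim = SimulationConfig(**sim)
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown pipeline config field(s): {sorted(bad)}")
        if "neoplastic_stages" in d:
            d["neoplastic_stages"] = tuple(d["neoplastic_stages"])
        return cls(sim=sim, **d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        text = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stage: simulate
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate the synthetic study and write references, reads and truth."""
    config.validate()
    out = Path(out_dir)
    (out / "refs").mkdir(parents=True, exist_ok=True)
    (out / "cohorts").mkdir(exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    cfg = config.sim

    pair = simulate_species_pair(cfg)
    lineage = simulate_tumour_lineage(pair, cfg)
    outgroup = simulate_outgroup(pair, cfg)
    write_fasta(out / "refs" / "host_mito.fasta", [("host_mito", pair.host_mito)])
    write_fasta(out / "refs" / "donor_mito.fasta", [("donor_mito", pair.donor_mito)])
    write_fasta(out / "refs" / "outgroup_mito.fasta", [("outgroup_mito", outgroup)])
    write_fasta(out / "refs" / "host_loci.fasta",
                list(zip(pair.locus_names, pair.host_loci)))
    write_fasta(out / "refs" / "donor_loci.fasta",
                list(zip(pair.locus_names, pair.donor_loci)))
    panel = markers.build_marker_panel(pair, cfg)
    write_fasta(out / "refs" / "marker_panel.fasta", sorted(panel.entries.items()))
    truth_rows = [{"sequence": name, "position": p, "host_allele": h, "donor_allele": d}
                  for name, diffs in pair.fixed_differences.items()
                  for p, h, d in diffs]
    pd.DataFrame(truth_rows).to_csv(out / "truth" / "fixed_differences.tsv",
                                    sep="\t", index=False)

    healthy_host = simulate_cohort(pair, "host", config.n_healthy_host, cfg)
    healthy_donor = simulate_cohort(pair, "donor", config.n_healthy_donor, cfg)
    for species, cohort in (("host", healthy_host), ("donor", healthy_donor)):
        write_fasta(out / "cohorts" / f"{species}_mito.fasta",
                    [(sp.specimen_id, sp.germline_mito) for sp in cohort])
        for li, name in enumerate(pair.locus_names):
            recs = []
            for sp in cohort:
                h0, h1 = sp.germline_loci[li]
                recs.append((f"{sp.specimen_id}|h0", h0))
                recs.append((f"{sp.specimen_id}|h1", h1))
            write_fasta(out / "cohorts" / f"{species}_{name}.fasta", recs)

    neo = simulate_neoplastic_cohort(
        pair, config.n_neoplastic, cfg,
        stages=config.neoplastic_stages[:config.n_neoplastic])
    manifest = []
    for prof in neo:
        for tissue in prof.tissue_tumour_fraction:
            bundle = simulate_specimen_reads(prof, lineage, pair, cfg, tissue)
            r1 = out / "reads" / f"{prof.specimen_id}_{tissue}_R1.fastq.gz"
            r2 = out / "reads" / f"{prof.specimen_id}_{tissue}_R2.fastq.gz"
            write_fastq_gz(r1, bundle.ids, bundle.r1, mate=1)
            write_fastq_gz(r2, bundle.ids, bundle.r2, mate=2)
            bundle.truth.to_csv(out / "truth" / f"{prof.specimen_id}_{tissue}.tsv",
                                sep="\t", index=False)
            manifest.append({"specimen_id": prof.specimen_id, "species": prof.species,
                             "stage": prof.stage, "tissue": tissue,
                             "fastq1": str(r1.relative_to(out)),
                             "fastq2": str(r2.relative_to(out))})
        # per-specimen germline (the matched-normal truth)
        write_fasta(out / "truth" / f"{prof.specimen_id}_germline_mito.fasta",
                    [(f"{prof.specimen_id}|germline_mito", prof.germline_mito)])
    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
    log.info("simulated %d healthy host, %d healthy donor, %d neoplastic specimens",
             config.n_healthy_host, config.n_healthy_donor, config.n_neoplastic)
    return out


def _manifest(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "manifest.tsv", sep="\t")


def _library(out: Path, row) -> tuple[list[str], np.ndarray]:
    ids1, m1 = read_fastq_codes(out / row.fastq1)
    ids2, m2 = read_fastq_codes(out / row.fastq2)
    return ids1 + ids2, np.vstack([m1, m2]) if m1.size else m1


# ---------------------------------------------------------------------------
# Stage: marker classification
# ---------------------------------------------------------------------------

def stage_classify(config: PipelineConfig, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    (out / "markers").mkdir(exist_ok=True)
    panel = markers.MarkerPanel(read_fasta(out / "refs" / "marker_panel.fasta"))
    results = {}
    for row in _manifest(out).itertuples():
        ids, mat = _library(out, row)
        report = markers.classify_reads(mat, ids, panel, config.min_margin)
        flag, top = (False, ())
        if report.assigned:
            flag, top = markers.two_species_test(report, config.two_species_threshold)
        key = f"{row.specimen_id}_{row.tissue}"
        summary = {"total_reads": report.total_reads, "assigned": report.assigned,
                   "unassigned": report.unassigned,
                   "proportions": report.proportions,
                   "two_species": flag, "top_species": list(top)}
        _write_json(out / "markers" / f"{key}.json", summary)
        pd.DataFrame(
            sorted(report.counts.items()), columns=["species", "reads"]
        ).to_csv(out / "markers" / f"{key}.tsv", sep="\t", index=False)
        results[key] = summary
    return results


# ---------------------------------------------------------------------------
# Stage: mitochondrial deconvolution
# ---------------------------------------------------------------------------

def stage_deconv(config: PipelineConfig, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    (out / "deconv").mkdir(exist_ok=True)
    host_mito = read_fasta(out / "refs" / "host_mito.fasta")["host_mito"]
    donor_mito = read_fasta(out / "refs" / "donor_mito.fasta")["donor_mito"]
    index = SeedIndex({"host_mito": host_mito, "donor_mito": donor_mito},
                      circular=("host_mito", "donor_mito"))
    results = {}
    for row in _manifest(out).itertuples():
        ids, mat = _library(out, row)
        placements = place_reads(mat, ids, index)
        conf = [p if is_confident(p, config.min_margin) else None for p in placements]
        piles = {name: build_pileup(conf, mat, name, seq, circular=True)
                 for name, seq in (("host_mito", host_mito), ("donor_mito", donor_mito))}
        prof_h = deconv.windowed_depth(piles["host_mito"], config.window_size)
        prof_d = deconv.windowed_depth(piles["donor_mito"], config.window_size)
        n_h = sum(1 for p in conf if p is not None and p.reference_id == "host_mito")
        n_d = sum(1 for p in conf if p is not None and p.reference_id == "donor_mito")
        key = f"{row.specimen_id}_{row.tissue}"
        try:
            phi, ci = deconv.donor_fraction(prof_h, prof_d, n_h, n_d)
        except ValueError:
            results[key] = {"error": "no mitochondrial signal"}
            continue
        res = deconv.DeconvResult(prof_h, prof_d, phi, ci, n_h, n_d)
        res.coexistence = deconv.detect_coexistence(res, config.tau, config.min_windows)
        pd.DataFrame({
            "window": np.arange(max(prof_h.n_windows, prof_d.n_windows)),
            "host_depth": prof_h.window_means,
            "donor_depth": prof_d.window_means,
        }).to_csv(out / "deconv" / f"{key}_windows.tsv", sep="\t", index=False)
        # per-reference mito consensus (tumour = donor-reference side)
        for origin, ref_name, ref_seq in (("host", "host_mito", host_mito),
                                          ("tumour", "donor_mito", donor_mito)):
            cons = nuclear.call_consensus(piles[ref_name], "mito", origin,
                                          config.fixation_threshold, config.min_depth)
            write_fasta(out / "deconv" / f"{key}_{origin}_mito.fasta",
                        [(f"{key}|{origin}_mito", cons.sequence)])
        summary = {"phi": phi, "phi_ci": list(ci), "n_host_reads": n_h,
                   "n_donor_reads": n_d, "coexistence": res.coexistence,
                   "stage": row.stage}
        _write_json(out / "deconv" / f"{key}.json", summary)
        results[key] = summary
    return results


# ---------------------------------------------------------------------------
# Stage: nuclear markers and consensus
# ---------------------------------------------------------------------------

def stage_nuclear(config: PipelineConfig, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    (out / "nuclear").mkdir(exist_ok=True)
    host_loci = read_fasta(out / "refs" / "host_loci.fasta")
    locus_names = sorted(host_loci)
    index = SeedIndex(host_loci)

    sites_by_locus: dict[str, list[nuclear.DiagnosticSite]] = {}
    rows = []
    for name in locus_names:
        mats = {}
        for species in ("host", "donor"):
            recs = read_fasta(out / "cohorts" / f"{species}_{name}.fasta")
            mats[species] = np.vstack([encode(s) for _, s in sorted(recs.items())])
        sites = nuclear.find_diagnostic_sites(mats["host"], mats["donor"], name,
                                              config.min_freq)
        sites_by_locus[name] = sites
        rows += [{"locus": s.locus, "position": s.position, "host_allele": s.allele_a,
                  "donor_allele": s.allele_b, "host_freq": s.freq_a,
                  "donor_freq": s.freq_b} for s in sites]
    pd.DataFrame(rows).to_csv(out / "nuclear" / "diagnostic_sites.tsv",
                              sep="\t", index=False)

    results: dict = {"n_diagnostic_sites": {n: len(s) for n, s in sites_by_locus.items()},
                     "specimens": {}}
    man = _manifest(out)
    for row in man[man.tissue == "haemolymph"].itertuples():
        ids, mat = _library(out, row)
        placements = place_reads(mat, ids, index)
        conf = [p if is_confident(p, config.min_margin) else None for p in placements]
        recs, spec_info = [], {}
        for name in locus_names:
            part = nuclear.partition_reads(conf, mat, sites_by_locus[name],
                                           reference_id=name)
            for origin, part_rows in (("tumour", part.donor_reads),
                                      ("host", part.host_reads)):
                cons = nuclear.consensus_from_partition(
                    part_rows, conf, mat, name, host_loci[name], name, origin,
                    config.fixation_threshold, config.min_depth)
                recs.append((f"{row.specimen_id}|{origin}|{name}", cons.sequence))
            spec_info[name] = {"host_reads": len(part.host_reads),
                               "donor_reads": len(part.donor_reads),
                               "ambiguous_reads": len(part.ambiguous_reads)}
        write_fasta(out / "nuclear" / f"{row.specimen_id}_consensus.fasta", recs)
        results["specimens"][row.specimen_id] = spec_info
    _write_json(out / "nuclear" / "summary.json", results)
    return results


# ---------------------------------------------------------------------------
# Stage: phylogeny
# ---------------------------------------------------------------------------

def stage_phylo(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Mitochondrial K2P/NJ tree over tumour and host consensus haplotypes."""
    out = Path(out_dir)
    (out / "phylo").mkdir(exist_ok=True)
    man = _manifest(out)
    labels, rows, classes = [], [], {}

    outgroup = read_fasta(out / "refs" / "outgroup_mito.fasta")["outgroup_mito"]
    labels.append("outgroup")
    rows.append(encode(outgroup))
    classes["outgroup"] = "outgroup"
    donor_germ = read_fasta(out / "cohorts" / "donor_mito.fasta")
    for name in sorted(donor_germ)[:config.n_phylo_donor_leaves]:
        labels.append(name)
        rows.append(encode(donor_germ[name]))
        classes[name] = "donor"
    host_germ = read_fasta(out / "cohorts" / "host_mito.fasta")
    for name in sorted(host_germ)[:config.n_phylo_host_leaves]:
        labels.append(name)
        rows.append(encode(host_germ[name]))
        classes[name] = "host"
    for spec in sorted(man.specimen_id.unique()):
        tum = read_fasta(out / "deconv" / f"{spec}_haemolymph_tumour_mito.fasta")
        seq = next(iter(tum.values()))
        lab = f"{spec}_tumour"
        labels.append(lab)
        rows.append(encode(seq))
        classes[lab] = "tumour"
        has_foot = ((man.specimen_id == spec) & (man.tissue == "foot")).any()
        normal_tissue = "foot" if has_foot else "haemolymph"
        hst = read_fasta(out / "deconv" / f"{spec}_{normal_tissue}_host_mito.fasta")
        lab = f"{spec}_host"
        labels.append(lab)
        rows.append(encode(next(iter(hst.values()))))
        classes[lab] = "host"

    aln = np.vstack(rows)
    dmat = phylo.k2p_matrix(aln)
    pd.DataFrame(dmat, index=labels, columns=labels).to_csv(
        out / "phylo" / "k2p_distances.tsv", sep="\t")
    result, supports = phylo.bootstrap_support(
        labels, aln, n_replicates=config.bootstrap_replicates,
        seed=np.random.default_rng(config.sim.seed + 7))
    (out / "phylo" / "mito_nj.nwk").write_text(result.newick + "\n")
    verdict = phylo.tumour_placement_test(result, classes)
    summary = {"tumour_monophyletic": verdict.tumour_monophyletic,
               "sister_is_donor": verdict.sister_is_donor,
               "n_leaves": len(labels),
               "bootstrap_replicates": config.bootstrap_replicates}
    _write_json(out / "phylo" / "placement.json", summary)
    return summary


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every enabled stage in order and write the run report."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": {"config_hash": config.config_hash(),
                                   "seed": config.sim.seed,
                                   "version": __version__}}
    stages: list[tuple[str, bool, object]] = [
        ("simulate", True, stage_simulate),
        ("classify", config.do_classify, stage_classify),
        ("deconv", config.do_deconv, stage_deconv),
        ("nuclear", config.do_nuclear, stage_nuclear),
        ("phylo", config.do_phylo and config.do_deconv, stage_phylo),
    ]
    for name, enabled, fn in stages:
        if not enabled:
            log.info("stage %s disabled", name)
            continue
        log.info("running stage %s", name)
        try:
            res = fn(config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
        if name != "simulate":
            report[name] = res
    _write_json(out / "report.json", report)
    lines = [f"clamtc run report (seed {config.sim.seed}, "
             f"config {config.config_hash()})"]
    for key, res in report.get("deconv", {}).items():
        if "phi" in res:
            lines.append(f"  {key}: phi={res['phi']:.3f} "
                         f"coexistence={res['coexistence']} stage={res['stage']}")
    if "phylo" in report:
        lines.append(f"  tumour monophyletic: {report['phylo']['tumour_monophyletic']}, "
                     f"sister to donor: {report['phylo']['sister_is_donor']}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
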