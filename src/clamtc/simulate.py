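"""Synthetic study generator for interspecies clam-leukaemia inference.

Emulates the study design end to end: two sister venerid clam species
whose mitogenomes sit at ~21% K2P divergence, diploid nuclear loci
carrying differentially fixed interspecific SNVs and low intraspecific
polymorphism, a clonal tumour lineage of donor-species origin, and
neoplastic host-species specimens whose tissues carry stage-dependent
mixtures of their own cells and tumour cells. Reads are 150-bp
Illumina-style pairs from ~350-bp inserts with i.i.d. substitution
errors, and every read carries a ground-truth record.

Evolution is substitution-only (no indels), so homologous coordinates
stay aligned by construction; the mitogenome is circular with
wrap-around fragment sampling. All randomness flows from a single master
seed through named sub-streams, so adding a specimen never perturbs the
reads of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .phylo import count_substitutions, k2p
from .seqcodes import complement, decode, encode, random_sequence

__all__ = [
    "SimulationConfig",
    "SpeciesPair",
    "TumourLineage",
    "SpecimenProfile",
    "ReadBundle",
    "DEFAULT_STAGE_FRACTIONS",
    "substream",
    "simulate_species_pair",
    "simulate_outgroup",
    "simulate_tumour_lineage",
    "simulate_cohort",
    "simulate_neoplastic_cohort",
    "simulate_specimen_reads",
    "simulate_single_reads",
    "mixture_expected_fraction",
]

TISSUES = ("haemolymph", "foot")

#: Default per-tissue tumour cell fractions by disease stage. The study
#: system reports no numeric fractions; these are plausible stand-ins
#: encoding the documented gradient (haemolymph >= foot, rising with
#: stage) and are config-overridable.
DEFAULT_STAGE_FRACTIONS: dict[str, dict[str, float]] = {
    "N0": {"haemolymph": 0.0, "foot": 0.0},
    "N1": {"haemolymph": 0.05, "foot": 0.0},
    "N2": {"haemolymph": 0.6, "foot": 0.1},
    "N3": {"haemolymph": 0.9, "foot": 0.15},
}


def substream(seed: int, *tokens: str | int) -> np.random.Generator:
    """Independent named RNG stream derived from the master seed.

    Stream identity depends only on ``seed`` and the token path, so the
    reads of one specimen/tissue are unaffected by how many other
    specimens exist.
    """
    entropy = [int(seed)]
    for t in tokens:
        if isinstance(t, int):
            entropy.append(t & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(t).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: an ~18-kb circular
    mitogenome, a 2.9-kb and a 2.2-kb single-copy nuclear locus, 21%
    interspecific mitogenome divergence (K2P), 150-bp paired-end reads
    from 350-bp inserts.
    """

    seed: int = 0
    mito_length: int = 18000
    nuclear_locus_lengths: tuple[int, ...] = (2900, 2200)
    target_k2p: float = 0.21
    kappa: float = 2.0
    theta_within: float = 0.002
    #: interspecific divergence of nuclear loci, as the proportion of
    #: differentially fixed sites (~3%, matching the density of
    #: diagnostic sites seen on short sequenced fragments)
    nuclear_divergence: float = 0.03
    #: exact planted fixed-difference count per locus (overrides
    #: nuclear_divergence when set)
    nuclear_fixed_counts: tuple[int, ...] | None = None
    read_length: int = 150
    insert_size: int = 350
    insert_sd: float = 30.0
    error_rate: float = 0.001
    mito_copy_ratio: float = 1.0
    coverage_mito: float = 100.0
    coverage_nuclear: float = 60.0
    stage_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STAGE_FRACTIONS.items()})

    def validate(self) -> "SimulationConfig":
        if self.read_length > self.insert_size:
            raise ValueError("read_length must be <= insert_size")
        if self.mito_length <= 2 * self.insert_size:
            raise ValueError("mito_length must exceed twice the insert size")
        for name in ("target_k2p", "theta_within", "nuclear_divergence", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 and name != "target_k2p":
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.target_k2p < 0:
            raise ValueError("target_k2p must be non-negative")
        if self.kappa <= 0 or self.mito_copy_ratio <= 0:
            raise ValueError("kappa and mito_copy_ratio must be positive")
        for stage, fr in self.stage_fractions.items():
            for tissue, f in fr.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"tumour fraction for {stage}/{tissue} outside [0,1]")
        return self

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw).validate()


@dataclass
class SpeciesPair:
    """Two sister species plus the ancestral sequences they diverged from.

    ``fixed_differences`` maps each homologous sequence name ("mito",
    "locus0", ...) to the ground-truth list of interspecific differences
    as ``(position, host_allele, donor_allele)``.
    """

    ancestral_mito: str
    host_mito: str
    donor_mito: str
    ancestral_loci: list[str]
    host_loci: list[str]
    donor_loci: list[str]
    fixed_differences: dict[str, list[tuple[int, str, str]]]

    @property
    def locus_names(self) -> list[str]:
        return [f"locus{i}" for i in range(len(self.host_loci))]

    def fixed_positions(self, name: str) -> np.ndarray:
        return np.array([p for p, _, _ in self.fixed_differences[name]], dtype=int)


@dataclass
class TumourLineage:
    """The clonal cancer lineage, derived from the donor species.

    The mitochondrial haplotype and diploid nuclear haplotypes are those
    of the founder individual (donor consensus plus its own germline
    polymorphism) and are shared by every neoplastic specimen — the
    lineage carries no within-tumour diversity unless
    ``private_mutations`` are added.
    """

    mito_haplotype: str
    locus_haplotypes: list[tuple[str, str]]
    private_mutations: list[int] = field(default_factory=list)


@dataclass
class SpecimenProfile:
    """One animal: identity, disease stage and germline genotypes."""

    specimen_id: str
    species: str                      # "host" | "donor"
    stage: str                        # "N0" | "N1" | "N2" | "N3"
    tissue_tumour_fraction: dict[str, float]
    germline_mito: str
    germline_loci: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.stage == "N0" and any(v > 0 for v in self.tissue_tumour_fraction.values()):
            raise ValueError("N0 specimens must have zero tumour fraction everywhere")
        hf = self.tissue_tumour_fraction.get("haemolymph", 0.0)
        ff = self.tissue_tumour_fraction.get("foot", 0.0)
        if hf < ff:
            raise ValueError("haemolymph tumour fraction must be >= foot fraction")


# ---------------------------------------------------------------------------
# Species pair
# ---------------------------------------------------------------------------

def _k2p_proportions(target: float, kappa: float) -> tuple[float, float]:
    """Observed (P, Q) with P = kappa*Q whose K2P distance equals target."""
    if target == 0:
        return 0.0, 0.0

    def f(q: float) -> float:
        return k2p(P=kappa * q, Q=q) - target

    # reject targets whose inversion sits within 1% of the saturation
    # asymptote Q -> 1/(2*kappa+1), where the formula is ill-conditioned
    qcap = 0.99 / (2.0 * kappa + 1.0)
    if f(qcap) < 0:
        raise ValueError("unattainable divergence: target beyond K2P saturation")
    q = brentq(f, 1e-12, qcap)
    return kappa * q, q


def _place_differences(ancestor: np.ndarray, n_ts: int, n_tv: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str, str]]]:
    """Place exact transition/transversion difference counts on two lineages.

    Each chosen site is substituted on one randomly chosen descendant;
    transitions flip within the purine/pyrimidine pair, transversions
    pick one of the two cross-class bases.
    """
    L = ancestor.size
    total = n_ts + n_tv
    host = ancestor.copy()
    donor = ancestor.copy()
    diffs: list[tuple[int, str, str]] = []
    if total == 0:
        return host, donor, diffs
    positions = rng.choice(L, size=total, replace=False)
    is_ts = np.zeros(total, dtype=bool)
    is_ts[:n_ts] = True
    rng.shuffle(is_ts)
    on_donor = rng.random(total) < 0.5
    tv_pick = rng.integers(0, 2, size=total)
    for pos, ts, dn, pick in zip(positions, is_ts, on_donor, tv_pick):
        base = int(ancestor[pos])
        if ts:
            new = base ^ 2                      # A<->G, C<->T
        else:
            new = base ^ (1 if pick == 0 else 3)  # the two transversion partners
        if dn:
            donor[pos] = new
        else:
            host[pos] = new
        diffs.append((int(pos), decode(host[pos:pos + 1]), decode(donor[pos:pos + 1])))
    diffs.sort()
    return host, donor, diffs


def simulate_species_pair(config: SimulationConfig) -> SpeciesPair:
    """Simulate the host/donor species pair with known fixed differences.

    The mitogenome pair realises the target K2P distance essentially
    exactly: the transition and transversion difference proportions that
    invert the K2P formula at the target (with transition:transversion
    ratio ``kappa``) are solved for, and the corresponding integer
    counts of differing sites placed at random positions. Nuclear loci
    carry a fixed number of planted interspecific differences.
    """
    config.validate()
    rng = substream(config.seed, "species_pair")
    anc_mito = random_sequence(config.mito_length, rng)
    p, q = _k2p_proportions(config.target_k2p, config.kappa)
    n_ts = int(round(p * config.mito_length))
    n_tv = int(round(q * config.mito_length))
    host_mito, donor_mito, mito_diffs = _place_differences(anc_mito, n_ts, n_tv, rng)

    fixed: dict[str, list[tuple[int, str, str]]] = {"mito": mito_diffs}
    anc_loci, host_loci, donor_loci = [], [], []
    for i, L in enumerate(config.nuclear_locus_lengths):
        anc = random_sequence(L, rng)
        if config.nuclear_fixed_counts is not None:
            n_fix = config.nuclear_fixed_counts[i]
        else:
            n_fix = int(round(L * config.nuclear_divergence))
        ts_frac = config.kappa / (config.kappa + 1.0)
        n_ts_l = int(rng.binomial(n_fix, ts_frac))
        h, d, diffs = _place_differences(anc, n_ts_l, n_fix - n_ts_l, rng)
        anc_loci.append(decode(anc))
        host_loci.append(decode(h))
        donor_loci.append(decode(d))
        fixed[f"locus{i}"] = diffs

    return SpeciesPair(
        ancestral_mito=decode(anc_mito),
        host_mito=decode(host_mito),
        donor_mito=decode(donor_mito),
        ancestral_loci=anc_loci,
        host_loci=host_loci,
        donor_loci=donor_loci,
        fixed_differences=fixed,
    )


def simulate_outgroup(pair: SpeciesPair, config: SimulationConfig,
                      divergence: float = 0.15) -> str:
    """An outgroup mitogenome: the ancestor evolved along its own branch.

    ``divergence`` is the proportion of additionally substituted sites.
    """
    rng = substream(config.seed, "outgroup")
    anc = encode(pair.ancestral_mito)
    n = int(round(divergence * anc.size))
    ts_frac = config.kappa / (config.kappa + 1.0)
    n_ts = int(rng.binomial(n, ts_frac))
    out, _, _ = _place_differences(anc, n_ts, n - n_ts, rng)
    return decode(out)


# ---------------------------------------------------------------------------
# Germlines, cohorts, tumour lineage
# ---------------------------------------------------------------------------

def _mutate_germline(consensus: np.ndarray, theta: float, rng: np.random.Generator,
                     forbidden: np.ndarray | None = None) -> np.ndarray:
    """Intraspecific polymorphism: i.i.d. per-site mutation at rate theta.

    Positions carrying an interspecific fixed difference are excluded
    (non-overlap of intra- and interspecific variation; collisions are
    vanishingly rare at realistic theta and this keeps the planted
    diagnostic sites exactly fixed within species).
    """
    out = consensus.copy()
    hit = rng.random(consensus.size) < theta
    if forbidden is not None and forbidden.size:
        hit[forbidden] = False
    idx = np.nonzero(hit)[0]
    if idx.size:
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return out


def simulate_tumour_lineage(pair: SpeciesPair, config: SimulationConfig,
                            n_private: int = 0) -> TumourLineage:
    """The clonal lineage: a donor-species founder genotype.

    Drawn exactly like one donor germline (consensus plus theta_within
    polymorphism), optionally with ``n_private`` somatic substitutions
    on the mitochondrial haplotype.
    """
    rng = substream(config.seed, "tumour_lineage")
    forb = pair.fixed_positions("mito")
    mito = _mutate_germline(encode(pair.donor_mito), config.theta_within, rng, forb)
    private: list[int] = []
    if n_private:
        pos = rng.choice(mito.size, size=n_private, replace=False)
        mito = mito.copy()
        mito[pos] = (mito[pos] + rng.integers(1, 4, size=n_private)) % 4
        private = sorted(int(x) for x in pos)
    loci = []
    for i, seq in enumerate(pair.donor_loci):
        forb_l = pair.fixed_positions(f"locus{i}")
        h0 = _mutate_germline(encode(seq), config.theta_within, rng, forb_l)
        h1 = _mutate_germline(encode(seq), config.theta_within, rng, forb_l)
        loci.append((decode(h0), decode(h1)))
    return TumourLineage(mito_haplotype=decode(mito), locus_haplotypes=loci,
                         private_mutations=private)


def simulate_cohort(pair: SpeciesPair, species: str, n: int,
                    config: SimulationConfig, stage: str = "N0",
                    id_prefix: str | None = None) -> list[SpecimenProfile]:
    """A cohort of specimens of one species, all at the given stage.

    Each specimen's germline differs from its species consensus at sites
    drawn with probability ``theta_within`` per site and per allele
    copy; nuclear genotypes are diploid, so pre-sequencing VAFs lie on
    {0, 0.5, 1.0} exactly.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if species not in ("host", "donor"):
        raise ValueError("species must be 'host' or 'donor'")
    mito_cons = encode(pair.host_mito if species == "host" else pair.donor_mito)
    loci_cons = [encode(s) for s in
                 (pair.host_loci if species == "host" else pair.donor_loci)]
    forb_m = pair.fixed_positions("mito")
    forb_l = [pair.fixed_positions(nm) for nm in pair.locus_names]
    prefix = id_prefix or f"{species}_{stage}"
    out = []
    fractions = dict(config.stage_fractions.get(stage, DEFAULT_STAGE_FRACTIONS[stage]))
    for i in range(n):
        rng = substream(config.seed, "cohort", species, stage, prefix, i)
        mito = _mutate_germline(mito_cons, config.theta_within, rng, forb_m)
        loci = []
        for cons, forb in zip(loci_cons, forb_l):
            h0 = _mutate_germline(cons, config.theta_within, rng, forb)
            h1 = _mutate_germline(cons, config.theta_within, rng, forb)
            loci.append((decode(h0), decode(h1)))
        out.append(SpecimenProfile(
            specimen_id=f"{prefix}_{i:03d}", species=species, stage=stage,
            tissue_tumour_fraction=dict(fractions),
            germline_mito=decode(mito), germline_loci=loci))
    return out


def simulate_neoplastic_cohort(pair: SpeciesPair, n: int, config: SimulationConfig,
                               stages: Sequence[str] | None = None) -> list[SpecimenProfile]:
    """Neoplastic host-species specimens at the given stages (default N2/N3 mix)."""
    stages = list(stages) if stages is not None else ["N2", "N3"] * ((n + 1) // 2)
    out = []
    for i in range(n):
        stage = stages[i]
        prof = simulate_cohort(pair, "host", 1, config, stage=stage,
                               id_prefix=f"neo_{stage}_{i}")[0]
        out.append(prof)
    return out


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def mixture_expected_fraction(cell_fraction: float, copy_ratio: float) -> float:
    """Expected donor-mtDNA *read* fraction given the tumour *cell* fraction.

    A tumour cell contributes ``copy_ratio`` mitogenome copies for every
    copy of a host cell, so the read-level fraction is
    f*c / (f*c + (1-f)).
    """
    if not 0.0 <= cell_fraction <= 1.0:
        raise ValueError("cell_fraction must lie in [0, 1]")
    if copy_ratio <= 0:
        raise ValueError("copy_ratio must be positive")
    fc = cell_fraction * copy_ratio
    return fc / (fc + (1.0 - cell_fraction))


@dataclass
class ReadBundle:
    """Paired reads of one library plus their ground-truth table.

    ``r1``/``r2`` are (n_pairs, read_length) code matrices; ``truth``
    has one row per emitted read (two per pair) with columns read_id,
    source, sequence, position, strand.
    """

    ids: list[str]
    r1: np.ndarray
    r2: np.ndarray
    truth: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.ids)

    def all_reads(self) -> tuple[list[str], np.ndarray]:
        """Interleave mates into one read list (ids get /1 /2 suffixes)."""
        if self.n_pairs == 0:
            return [], np.zeros((0, 0), dtype=np.uint8)
        ids = [f"{b}/{m}" for b in self.ids for m in (1, 2)]
        mat = np.empty((2 * self.n_pairs, self.r1.shape[1]), dtype=np.uint8)
        mat[0::2] = self.r1
        mat[1::2] = self.r2
        return ids, mat

    @staticmethod
    def concat(bundles: Sequence["ReadBundle"]) -> "ReadBundle":
        bundles = [b for b in bundles if b.n_pairs > 0]
        if not bundles:
            return ReadBundle([], np.zeros((0, 0), dtype=np.uint8),
                              np.zeros((0, 0), dtype=np.uint8), _empty_truth())
        return ReadBundle(
            ids=[i for b in bundles for i in b.ids],
            r1=np.vstack([b.r1 for b in bundles]),
            r2=np.vstack([b.r2 for b in bundles]),
            truth=pd.concat([b.truth for b in bundles], ignore_index=True))


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=["read_id", "source", "sequence", "position", "strand"])


def _add_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or mat.size == 0:
        return mat
    hit = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, size=mat.shape)
    return np.where(hit, (mat + shift) % 4, mat).astype(np.uint8)


def _draw_pairs(templates: np.ndarray, tidx: np.ndarray, n: int, L: int,
                circular: bool, config: SimulationConfig,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised fragment -> mate-pair sampling from a template stack."""
    rl = config.read_length
    ins = np.rint(rng.normal(config.insert_size, config.insert_sd, size=n)).astype(int)
    ins = np.clip(ins, rl, L)
    if circular:
        start = rng.integers(0, L, size=n)
    else:
        start = (rng.random(n) * (L - ins + 1)).astype(int)
    offs = np.arange(rl)
    p1 = start[:, None] + offs[None, :]
    p2 = (start + ins - 1)[:, None] - offs[None, :]
    if circular:
        p1 %= L
        p2 %= L
    r1 = templates[tidx[:, None], p1]
    r2 = complement(templates[tidx[:, None], p2])
    r2start = (start + ins - rl) % L if circular else start + ins - rl
    return r1, r2, start % L if circular else start, r2start


def simulate_specimen_reads(profile: SpecimenProfile, lineage: TumourLineage | None,
                            pair: SpeciesPair, config: SimulationConfig, tissue: str,
                            templates: Iterable[str] = ("mito", "nuclear")) -> ReadBundle:
    """Sequence one tissue of one specimen.

    Fragments are drawn from host-cell and tumour-cell templates with
    cell-fraction weights; for the mitochondrial library the tumour
    weight is additionally scaled by ``mito_copy_ratio`` (see
    :func:`mixture_expected_fraction`). The circular mitogenome is
    sampled with coordinate wrap-around. Each emitted base substitutes
    to a uniformly chosen different base with probability
    ``error_rate``; mate orientation is forward/reverse.
    """
    config.validate()
    if tissue not in profile.tissue_tumour_fraction:
        raise ValueError(f"unknown tissue: {tissue!r}")
    f = profile.tissue_tumour_fraction[tissue]
    if f > 0 and lineage is None:
        raise ValueError("tumour-bearing tissue needs a TumourLineage")
    rl = config.read_length
    bundles = []
    for template in templates:
        rng = substream(config.seed, "reads", profile.specimen_id, tissue, template)
        if template == "mito":
            L = len(profile.germline_mito)
            n = int(round(config.coverage_mito * L / (2.0 * rl)))
            if n == 0:
                continue
            stack = [encode(profile.germline_mito)]
            srcnames = ["host:mito"]
            p_t = mixture_expected_fraction(f, config.mito_copy_ratio)
            if lineage is not None:
                stack.append(encode(lineage.mito_haplotype))
                srcnames.append("tumour:mito")
            tidx = (rng.random(n) < p_t).astype(int) if len(stack) > 1 else np.zeros(n, dtype=int)
            r1, r2, s1, s2 = _draw_pairs(np.vstack(stack), tidx, n, L, True, config, rng)
            tumour_flag = tidx.astype(bool)
            seqnames = np.array(srcnames)[tidx]
            base = f"{profile.specimen_id}|{tissue}|mito"
            bundles.append(_bundle(base, r1, r2, s1, s2, tumour_flag, seqnames, config, rng))
        elif template == "nuclear":
            for li, name in enumerate(pair.locus_names):
                h0, h1 = profile.germline_loci[li]
                L = len(h0)
                n = int(round(config.coverage_nuclear * L / (2.0 * rl)))
                if n == 0:
                    continue
                stack = [encode(h0), encode(h1)]
                if lineage is not None:
                    t0, t1 = lineage.locus_haplotypes[li]
                    stack.append(encode(t0))
                    stack.append(encode(t1))
                is_t = (rng.random(n) < f) & (lineage is not None)
                hap = rng.integers(0, 2, size=n)
                tidx = np.where(is_t, 2 + hap, hap)
                r1, r2, s1, s2 = _draw_pairs(np.vstack(stack), tidx, n, L, False, config, rng)
                seqnames = np.array(
                    [f"host:{name}:h0", f"host:{name}:h1",
                     f"tumour:{name}:h0", f"tumour:{name}:h1"])[tidx]
                base = f"{profile.specimen_id}|{tissue}|{name}"
                bundles.append(_bundle(base, r1, r2, s1, s2, is_t, seqnames, config, rng))
        else:
            raise ValueError(f"unknown template class: {template!r}")
    return ReadBundle.concat(bundles)


def _bundle(base: str, r1, r2, s1, s2, tumour_flag, seqnames,
            config: SimulationConfig, rng: np.random.Generator) -> ReadBundle:
    n = r1.shape[0]
    r1 = _add_errors(r1, config.error_rate, rng)
    r2 = _add_errors(r2, config.error_rate, rng)
    ids = [f"{base}|{i}" for i in range(n)]
    source = np.where(tumour_flag, "tumour_cell", "host_cell")
    truth = pd.DataFrame({
        "read_id": [f"{b}/{m}" for b in ids for m in (1, 2)],
        "source": np.repeat(source, 2),
        "sequence": np.repeat(seqnames, 2),
        "position": np.stack([s1, s2], axis=1).ravel(),
        "strand": ["+", "-"] * n,
    })
    return ReadBundle(ids=ids, r1=r1, r2=r2, truth=truth)


def simulate_single_reads(template: str | np.ndarray, n: int,
                          rng: np.random.Generator, read_length: int = 150,
                          error_rate: float = 0.0, circular: bool = False,
                          id_prefix: str = "read") -> tuple[list[str], np.ndarray]:
    """Unpaired reads from one template, random strand — marker-panel fodder."""
    codes = template if isinstance(template, np.ndarray) else encode(template)
    L = codes.size
    if not circular and L < read_length:
        raise ValueError("template shorter than read length")
    start = rng.integers(0, L if circular else L - read_length + 1, size=n)
    offs = np.arange(read_length)
    pos = start[:, None] + offs[None, :]
    if circular:
        pos %= L
    mat = codes[pos]
    rev = rng.random(n) < 0.5
    mat[rev] = complement(mat[rev])[:, ::-1]
    mat = _add_errors(mat, error_rate, rng)
    ids = [f"{id_prefix}_{i}" for i in range(n)]
    return ids, mat
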