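"""Species-diagnostic nuclear SNVs and tumour/host genotype deconvolution.

The nuclear workflow mirrors the mitochondrial one but resolves the
*nuclear* origin of the tumour lineage, which is robust to
mitochondrial capture from transient hosts:

1. candidate single-copy loci are vetted by the diploid VAF criterion —
   in every healthy specimen every well-covered site must sit at a
   variant allele frequency of 0, 0.5 or 1.0 (a duplicated locus mixes
   paralogs and breaks the grid);
2. differentially fixed SNVs (within-species major allele frequency
   >= 95%, different major alleles) between the two species' healthy
   cohorts become diagnostic sites;
3. a neoplastic specimen's reads are partitioned into host-genotype,
   donor-genotype and ambiguous sets by the alleles they carry at the
   diagnostic sites they cover;
4. per-partition pileups yield tumour and host consensus haplotypes,
   emitting a base only where its frequency exceeds the fixation
   threshold (0.9) at sufficient depth, 'N' otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mapping import Pileup, ReadPlacement, build_pileup
from .seqcodes import BASES, complement, decode, encode
from .simulate import SpecimenProfile

__all__ = [
    "DiagnosticSite", "PartitionedReadSet", "ConsensusHaplotype",
    "cohort_allele_matrix", "diploid_locus_filter", "specimen_vaf",
    "find_diagnostic_sites", "partition_reads", "call_consensus",
]

DEFAULT_MIN_FREQ = 0.95
DEFAULT_FIXATION = 0.9
DEFAULT_MIN_DEPTH = 8
DEFAULT_VAF_TOLERANCE = 0.1


@dataclass(frozen=True)
class DiagnosticSite:
    """A position where the two species are fixed for different alleles."""

    locus: str
    position: int
    allele_a: str       # major allele of cohort A (the host species)
    allele_b: str       # major allele of cohort B (the donor species)
    freq_a: float       # allele_a frequency within cohort A (allele copies)
    freq_b: float

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("diagnostic alleles must differ")


@dataclass
class PartitionedReadSet:
    """Host/donor/ambiguous partition of reads overlapping diagnostic sites.

    ``observations`` maps read index -> list of (site position, observed
    base) for the diagnostic sites the read covers.
    """

    host_reads: list[int]
    donor_reads: list[int]
    ambiguous_reads: list[int]
    observations: dict[int, list[tuple[int, str]]] = field(default_factory=dict)


@dataclass
class ConsensusHaplotype:
    """Consensus sequence of one origin (tumour or host) at one locus."""

    locus: str
    origin: str                    # "tumour" | "host"
    sequence: str                  # 'N' at unresolved sites
    vaf: np.ndarray                # supporting major-allele frequency per site
    depth: np.ndarray

    def identity_to(self, other: str) -> float:
        """Identity over non-N sites against a same-length reference."""
        a = encode(self.sequence)
        b = encode(other)
        called = a < 4
        if not called.any():
            return float("nan")
        return float((a[called] == b[called]).mean())

    @property
    def n_called(self) -> int:
        return int((encode(self.sequence) < 4).sum())


# ---------------------------------------------------------------------------
# Cohort-level operations
# ---------------------------------------------------------------------------

def cohort_allele_matrix(specimens: Sequence[SpecimenProfile], locus_index: int) -> np.ndarray:
    """Stack both allele copies of every specimen: (2n, L) code matrix."""
    rows = []
    for sp in specimens:
        h0, h1 = sp.germline_loci[locus_index]
        rows.append(encode(h0))
        rows.append(encode(h1))
    return np.vstack(rows)


def specimen_vaf(pileup: Pileup, reference: str | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site variant allele frequency of one specimen vs a reference.

    VAF = 1 - (reference-allele count / depth); sites with zero depth
    get NaN. For a true diploid single-copy locus the VAF concentrates
    on {0, 0.5, 1.0} up to binomial sampling noise.
    """
    ref = reference if isinstance(reference, np.ndarray) else encode(reference)
    depth = pileup.depth
    ref_counts = pileup.counts[ref.astype(np.int64), np.arange(ref.size)]
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, 1.0 - ref_counts / np.maximum(depth, 1), np.nan)
    return vaf, depth


def diploid_locus_filter(
    vaf_tables: Mapping[str, Mapping[str, Sequence[tuple[np.ndarray, np.ndarray]]]],
    required_species: Sequence[str] = ("host", "donor"),
    tolerance: float = DEFAULT_VAF_TOLERANCE,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> dict[str, tuple[bool, str]]:
    """Accept loci whose healthy-specimen VAFs all sit on the diploid grid.

    ``vaf_tables`` maps locus -> species -> list of per-specimen
    (vaf, depth) pairs. A locus passes iff a cohort exists for every
    required species and every site with depth >= min_depth in every
    specimen has a VAF within ``tolerance`` of 0, 0.5 or 1.0.

    Returns locus -> (accepted, reason).
    """
    if not 0.0 <= tolerance < 0.25:
        raise ValueError("tolerance must lie in [0, 0.25)")
    grid = np.array([0.0, 0.5, 1.0])
    out: dict[str, tuple[bool, str]] = {}
    for locus, by_species in vaf_tables.items():
        missing = [sp for sp in required_species if not by_species.get(sp)]
        if missing:
            out[locus] = (False, "not present in all species")
            continue
        ok = True
        for sp, tables in by_species.items():
            for vaf, depth in tables:
                use = (depth >= min_depth) & ~np.isnan(vaf)
                if not use.any():
                    continue
                dist = np.abs(vaf[use, None] - grid[None, :]).min(axis=1)
                if (dist > tolerance).any():
                    ok = False
                    break
            if not ok:
                break
        out[locus] = (ok, "ok" if ok else "off-grid VAF")
    return out


def find_diagnostic_sites(cohort_a: np.ndarray, cohort_b: np.ndarray,
                          locus: str = "locus",
                          min_freq: float = DEFAULT_MIN_FREQ) -> list[DiagnosticSite]:
    """Differentially fixed SNVs between two cohorts of allele copies.

    A site is diagnostic iff each cohort's major allele reaches
    ``min_freq`` (inclusive) of its allele copies and the two major
    alleles differ. Frequencies count allele copies, i.e. each diploid
    specimen contributes two.
    """
    if cohort_a.size == 0 or cohort_b.size == 0:
        raise ValueError("empty cohort")
    if cohort_a.shape[1] != cohort_b.shape[1]:
        raise ValueError("cohorts are not aligned on common coordinates")
    sites = []
    for mat in (cohort_a, cohort_b):
        counts = np.stack([(mat == c).sum(axis=0) for c in range(4)])  # (4, L)
        covered = counts.sum(axis=0)
        major = counts.argmax(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(covered > 0, counts.max(axis=0) / np.maximum(covered, 1), 0.0)
        sites.append((major, freq, covered))
    (maj_a, frq_a, cov_a), (maj_b, frq_b, cov_b) = sites
    hit = ((frq_a >= min_freq) & (frq_b >= min_freq)
           & (maj_a != maj_b) & (cov_a > 0) & (cov_b > 0))
    return [DiagnosticSite(locus=locus, position=int(p),
                           allele_a=BASES[maj_a[p]], allele_b=BASES[maj_b[p]],
                           freq_a=float(frq_a[p]), freq_b=float(frq_b[p]))
            for p in np.nonzero(hit)[0]]


# ---------------------------------------------------------------------------
# Read partition and consensus
# ---------------------------------------------------------------------------

def partition_reads(placements: Sequence[ReadPlacement | None], reads: np.ndarray,
                    sites: Sequence[DiagnosticSite],
                    reference_id: str | None = None) -> PartitionedReadSet:
    """Partition reads by the species alleles they show at diagnostic sites.

    A read covering at least one diagnostic site goes to the host set
    if every covered site shows the host (A) allele, to the donor set
    if every covered site shows the donor (B) allele, and to the
    ambiguous set otherwise (mixed or off-grid alleles, e.g. sequencing
    error). Reads covering no site are left out entirely.
    """
    pos = np.array(sorted(s.position for s in sites), dtype=int)
    by_pos = {s.position: s for s in sites}
    res = PartitionedReadSet(host_reads=[], donor_reads=[], ambiguous_reads=[])
    if pos.size == 0:
        return res
    L = reads.shape[1] if reads.size else 0
    for i, p in enumerate(placements):
        if p is None or (reference_id is not None and p.reference_id != reference_id):
            continue
        lo = np.searchsorted(pos, p.position, side="left")
        hi = np.searchsorted(pos, p.position + L, side="left")
        if hi <= lo:
            continue
        row = reads[i]
        if p.strand == "-":
            row = complement(row)[::-1]
        obs: list[tuple[int, str]] = []
        verdicts = set()
        for sp in pos[lo:hi]:
            site = by_pos[int(sp)]
            base = decode(row[sp - p.position: sp - p.position + 1])
            obs.append((int(sp), base))
            if base == site.allele_a:
                verdicts.add("host")
            elif base == site.allele_b:
                verdicts.add("donor")
            else:
                verdicts.add("other")
        res.observations[i] = obs
        if verdicts == {"host"}:
            res.host_reads.append(i)
        elif verdicts == {"donor"}:
            res.donor_reads.append(i)
        else:
            res.ambiguous_reads.append(i)
    return res


def call_consensus(pileup: Pileup, locus: str, origin: str,
                   fixation_threshold: float = DEFAULT_FIXATION,
                   min_depth: int = DEFAULT_MIN_DEPTH) -> ConsensusHaplotype:
    """Majority consensus from one partition's pileup.

    A base is emitted only where its frequency exceeds the fixation
    threshold (strictly) and depth reaches ``min_depth``; every other
    site becomes 'N'. An empty pileup yields an all-N consensus.
    """
    import warnings

    allele, freq = pileup.major_allele()
    depth = pileup.depth
    callable_ = (depth >= min_depth) & (freq > fixation_threshold)
    seq = np.where(callable_, allele, np.uint8(255)).astype(np.uint8)
    if depth.sum() == 0:
        warnings.warn(f"empty partition for {locus}/{origin}: all-N consensus")
    return ConsensusHaplotype(locus=locus, origin=origin, sequence=decode(seq),
                              vaf=freq, depth=depth)


def consensus_from_partition(partition_rows: Sequence[int],
                             placements: Sequence[ReadPlacement | None],
                             reads: np.ndarray, reference_id: str,
                             reference: str, locus: str, origin: str,
                             fixation_threshold: float = DEFAULT_FIXATION,
                             min_depth: int = DEFAULT_MIN_DEPTH) -> ConsensusHaplotype:
    """Pileup of one partition's reads, then consensus call."""
    keep = set(partition_rows)
    chosen = [placements[i] if i in keep else None for i in range(len(placements))]
    pile = build_pileup(chosen, reads, reference_id, reference, circular=False)
    return call_consensus(pile, locus, origin, fixation_threshold, min_depth)
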