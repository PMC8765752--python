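"""Marker-gene (COI barcode) read classification.

A sample's reads are placed against a panel of species-diagnostic
mitochondrial marker sequences (one per species, emulating a
barcode-of-life COI panel) and the per-species proportions of
confidently assigned reads reported. In a neoplastic animal carrying a
transmissible cancer of foreign origin, the panel hit profile collapses
onto exactly two species — the host and the tumour's donor — which is
the primary contagion screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mapping import DEFAULT_MIN_MARGIN, SeedIndex, is_confident, place_reads
from .seqcodes import decode, encode
from .simulate import SimulationConfig, SpeciesPair, substream

__all__ = ["MarkerPanel", "CompositionReport", "build_marker_panel",
           "classify_reads", "two_species_test"]

#: default span of the mitogenome used as the COI-like marker
MARKER_OFFSET = 1000
MARKER_LENGTH = 650


@dataclass
class MarkerPanel:
    """Species name -> marker sequence, with the seeding k-mer size."""

    entries: dict[str, str]
    k: int = 21

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("marker panel must not be empty")
        for name, seq in self.entries.items():
            if not seq:
                raise ValueError(f"empty marker sequence for {name!r}")

    def index(self) -> SeedIndex:
        return SeedIndex(self.entries, k=self.k)


@dataclass
class CompositionReport:
    """Per-species confident read counts and proportions for one library."""

    counts: dict[str, int]
    total_reads: int
    unassigned: int

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        a = self.assigned
        if a == 0:
            return {}
        return {sp: c / a for sp, c in self.counts.items()}

    def top(self, n: int = 2) -> list[tuple[str, float]]:
        props = self.proportions
        return sorted(props.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def build_marker_panel(pair: SpeciesPair, config: SimulationConfig,
                       n_decoys: int = 116, decoy_divergence: float = 0.25,
                       host_name: str = "host_species",
                       donor_name: str = "donor_species",
                       offset: int = MARKER_OFFSET,
                       length: int = MARKER_LENGTH, k: int = 21) -> MarkerPanel:
    """Panel of the two focal species' markers plus decoy relatives.

    Decoys are derived from the ancestral marker region by substituting
    each site with probability ``decoy_divergence``, emulating a large
    family-wide barcode panel without any download. Default size 118
    entries (2 focal + 116 decoys).
    """
    rng = substream(config.seed, "marker_panel")
    entries = {
        host_name: pair.host_mito[offset:offset + length],
        donor_name: pair.donor_mito[offset:offset + length],
    }
    anc = encode(pair.ancestral_mito[offset:offset + length])
    for i in range(n_decoys):
        hit = rng.random(anc.size) < decoy_divergence
        shift = rng.integers(1, 4, size=anc.size)
        entries[f"decoy_{i:03d}"] = decode(
            np.where(hit, (anc + shift) % 4, anc).astype(np.uint8))
    return MarkerPanel(entries=entries, k=k)


DEFAULT_MIN_IDENTITY = 0.9


def classify_reads(reads: np.ndarray, ids: Sequence[str], panel: MarkerPanel,
                   min_margin: int = DEFAULT_MIN_MARGIN,
                   min_identity: float = DEFAULT_MIN_IDENTITY) -> CompositionReport:
    """Assign each read to its confident best-hit panel species.

    A read is assigned when its placement passes the margin filter and
    matches at least ``min_identity`` of its bases — the identity floor
    keeps reads of species absent from the panel (which can share a
    conserved stretch with one entry and thus seed a single mediocre
    hit) out of the composition. Proportions are computed over assigned
    reads only; everything else counts as unassigned.
    """
    total = len(ids)
    counts: dict[str, int] = {}
    if total == 0:
        return CompositionReport(counts={}, total_reads=0, unassigned=0)
    read_len = reads.shape[1]
    placements = place_reads(reads, ids, panel.index())
    unassigned = 0
    for p in placements:
        if is_confident(p, min_margin) and p.score >= min_identity * read_len:
            counts[p.reference_id] = counts.get(p.reference_id, 0) + 1
        else:
            unassigned += 1
    return CompositionReport(counts=counts, total_reads=total, unassigned=unassigned)


def two_species_test(report: CompositionReport,
                     threshold: float = 0.99) -> tuple[bool, tuple[str, ...]]:
    """Do the top two species jointly account for >= threshold of assigned reads?

    Returns the flag and the top-two species names (most frequent first).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    if report.assigned < 1:
        raise ValueError("insufficient data: no confidently assigned reads")
    top = report.top(2)
    joint = sum(p for _, p in top)
    return joint >= threshold, tuple(sp for sp, _ in top)
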