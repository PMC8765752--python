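"""Mitochondrial haplotype deconvolution from read depth.

A tissue's reads are competitively mapped against both species'
mitogenomes at once, so each read's confidence margin is computed
across species; confidently assigned reads are piled up per reference,
depth is summarised in 100-bp windows, and the donor-haplotype fraction
phi = D_donor / (D_donor + D_host) of mean depths is estimated with a
binomial interval from the assigned read counts. Coexistence of the two
haplotypes in one animal — the contagion signal — is called when the
minor haplotype's fraction and breadth of coverage both clear
detection floors.

phi estimates the mtDNA *read* fraction, not the tumour *cell*
fraction: converting between the two requires the per-cell mtDNA copy
ratio (see :func:`clamtc.simulate.mixture_expected_fraction`), which
real data rarely provides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .mapping import (DEFAULT_MIN_MARGIN, Pileup, ReadPlacement, SeedIndex,
                      build_pileup, is_confident, place_reads)

__all__ = ["CoverageProfile", "DeconvResult", "windowed_depth",
           "donor_fraction", "detect_coexistence", "deconvolve_tissue"]

DEFAULT_WINDOW = 100
DEFAULT_TAU = 0.01
DEFAULT_MIN_WINDOWS = 20


@dataclass
class CoverageProfile:
    """Mean read depth in fixed-size windows along one reference."""

    reference_id: str
    window_size: int
    window_means: np.ndarray
    reference_length: int

    @property
    def n_windows(self) -> int:
        return self.window_means.size

    @property
    def mean_depth(self) -> float:
        """Mean per-site depth over the whole reference."""
        # window means are per-site means, so weight by window width
        w = self.window_size
        widths = np.full(self.n_windows, w, dtype=float)
        widths[-1] = self.reference_length - w * (self.n_windows - 1)
        return float((self.window_means * widths).sum() / self.reference_length)

    def nonzero_windows(self) -> int:
        return int((self.window_means > 0).sum())


@dataclass
class DeconvResult:
    """Deconvolution summary for one library (one specimen tissue)."""

    host_profile: CoverageProfile
    donor_profile: CoverageProfile
    phi: float                      # donor-haplotype read-depth fraction
    phi_ci: tuple[float, float]     # binomial 95% interval
    n_host_reads: int
    n_donor_reads: int
    coexistence: bool | None = None


def windowed_depth(pileup: Pileup, window_size: int = DEFAULT_WINDOW) -> CoverageProfile:
    """Per-window mean of per-site depth; the last window may be short."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    L = pileup.length
    if L == 0:
        raise ValueError("empty reference")
    depth = pileup.depth.astype(float)
    edges = np.arange(0, L, window_size)
    sums = np.add.reduceat(depth, edges)
    widths = np.minimum(edges + window_size, L) - edges
    return CoverageProfile(reference_id=pileup.reference_id,
                           window_size=window_size,
                           window_means=sums / widths,
                           reference_length=L)


def donor_fraction(profile_host: CoverageProfile, profile_donor: CoverageProfile,
                   n_host_reads: int, n_donor_reads: int,
                   alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """phi = mean donor depth / (mean donor + mean host depth).

    The Clopper-Pearson interval is computed from the confident read
    counts on each reference, which carry the sampling noise.
    """
    dh = profile_host.mean_depth
    dd = profile_donor.mean_depth
    if dh + dd == 0:
        raise ValueError("no mitochondrial signal: zero depth on both references")
    phi = dd / (dd + dh)
    n = n_host_reads + n_donor_reads
    x = n_donor_reads
    lo = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return phi, (lo, hi)


def detect_coexistence(result: DeconvResult, tau: float = DEFAULT_TAU,
                       min_windows: int = DEFAULT_MIN_WINDOWS) -> bool:
    """Call two-haplotype coexistence for one library.

    Requires the minor haplotype fraction min(phi, 1-phi) >= tau and at
    least ``min_windows`` nonzero-depth windows on *both* references.
    The thresholds are sensitivity floors: a lightly infiltrated tissue
    sequenced shallowly can carry foreign reads below them and go
    undetected.
    """
    if not 0.0 < tau < 0.5:
        raise ValueError("tau must lie in (0, 0.5)")
    if min_windows < 1:
        raise ValueError("min_windows must be >= 1")
    minor = min(result.phi, 1.0 - result.phi)
    return (minor >= tau
            and result.host_profile.nonzero_windows() >= min_windows
            and result.donor_profile.nonzero_windows() >= min_windows)


def deconvolve_tissue(reads: np.ndarray, ids: Sequence[str],
                      host_mito: str, donor_mito: str,
                      min_margin: int = DEFAULT_MIN_MARGIN,
                      window_size: int = DEFAULT_WINDOW,
                      tau: float = DEFAULT_TAU,
                      min_windows: int = DEFAULT_MIN_WINDOWS,
                      k: int = 21) -> DeconvResult:
    """Full per-library deconvolution: map, pile up, window, estimate phi."""
    index = SeedIndex({"host_mito": host_mito, "donor_mito": donor_mito},
                      k=k, circular=("host_mito", "donor_mito"))
    placements = place_reads(reads, ids, index)
    confident = [p if is_confident(p, min_margin) else None for p in placements]
    piles = {name: build_pileup(confident, reads, name, seq, circular=True)
             for name, seq in (("host_mito", host_mito), ("donor_mito", donor_mito))}
    prof_h = windowed_depth(piles["host_mito"], window_size)
    prof_d = windowed_depth(piles["donor_mito"], window_size)
    n_h = sum(1 for p in confident if p is not None and p.reference_id == "host_mito")
    n_d = sum(1 for p in confident if p is not None and p.reference_id == "donor_mito")
    phi, ci = donor_fraction(prof_h, prof_d, n_h, n_d)
    result = DeconvResult(host_profile=prof_h, donor_profile=prof_d, phi=phi,
                          phi_ci=ci, n_host_reads=n_h, n_donor_reads=n_d)
    result.coexistence = detect_coexistence(result, tau, min_windows)
    return result
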