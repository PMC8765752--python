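"""Distance phylogenetics for mixed tumour/host haplotypes.

Implements Kimura's two-parameter (K2P) distance, neighbour joining
(Saitou & Nei's Q-criterion with the standard branch-length formulas),
nonparametric bootstrap over alignment columns, and the topological test
used to place a transmissible tumour lineage: do the tumour haplotypes
form a single clade, and is that clade sister to the putative donor
species rather than to the host species carrying the tumour?

Distance methods are used deliberately: the claims under test are
topological (monophyly and sister relationships), which neighbour
joining recovers reliably at the divergence levels involved, at a
fraction of the cost of likelihood or Bayesian reconstruction.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .seqcodes import encode

__all__ = [
    "SubstitutionCounts",
    "count_substitutions",
    "k2p",
    "k2p_matrix",
    "NJResult",
    "neighbor_joining",
    "nj_tree",
    "bootstrap_support",
    "PlacementVerdict",
    "tumour_placement_test",
    "k2p_between_fasta",
]


# ---------------------------------------------------------------------------
# K2P distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionCounts:
    """Transition/transversion tally over comparable alignment columns.

    Only columns where both sequences carry an unambiguous base (A, C, G
    or T) are compared; ``n`` is the number of such columns.
    """

    n: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.n

    @property
    def Q(self) -> float:
        return self.transversions / self.n


def _as_codes(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return encode(seq)


def count_substitutions(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> SubstitutionCounts:
    """Count transitions and transversions between two aligned sequences.

    Columns with a gap or ambiguity character in either sequence are
    skipped. A<->G and C<->T are transitions; every other differing pair
    is a transversion.
    """
    a = _as_codes(seq_a)
    b = _as_codes(seq_b)
    if a.shape != b.shape:
        raise ValueError("unaligned input: sequences differ in length")
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    diff = valid & (a != b)
    # with A=0,C=1,G=2,T=3 a transition (A<->G, C<->T) is exactly xor == 2
    transitions = int((diff & ((a ^ b) == 2)).sum())
    transversions = int(diff.sum()) - transitions
    return SubstitutionCounts(n=n, transitions=transitions, transversions=transversions)


def k2p(counts: SubstitutionCounts | None = None, *, P: float | None = None,
        Q: float | None = None) -> float:
    """Kimura two-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    ``P`` and ``Q`` are the observed proportions of transition- and
    transversion-differing sites. Pass either a
    :class:`SubstitutionCounts` or explicit proportions.
    """
    if counts is not None:
        P, Q = counts.P, counts.Q
    if P is None or Q is None:
        raise ValueError("provide SubstitutionCounts or both P and Q")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise ValueError("K2P undefined: saturated divergence")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_matrix(alignment: np.ndarray) -> np.ndarray:
    """Pairwise K2P distances for an alignment matrix (taxa x sites)."""
    t = alignment.shape[0]
    d = np.zeros((t, t))
    for i in range(t):
        for j in range(i + 1, t):
            c = count_substitutions(alignment[i], alignment[j])
            d[i, j] = d[j, i] = k2p(c)
    return d


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

@dataclass
class NJResult:
    """An unrooted NJ tree: newick text plus its internal bipartitions.

    Bipartitions are stored as frozensets of leaf labels, normalised to
    the side that does not contain the first taxon label.
    """

    newick: str
    leaf_labels: tuple[str, ...]
    bipartitions: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def tree(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick, schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
        )


def _normalise(side: frozenset[str], anchor: str, universe: frozenset[str]) -> frozenset[str]:
    return frozenset(universe - side) if anchor in side else side


def neighbor_joining(labels: Sequence[str], dmat: np.ndarray) -> NJResult:
    """Neighbour joining on a symmetric distance matrix.

    Negative branch lengths are clamped to zero. Ties in the Q-criterion
    are broken by smallest pairwise distance first, then row-major order
    — so clones (zero-distance duplicates, e.g. a clonal tumour sampled
    from several animals) coalesce into one clade instead of being
    resolved arbitrarily around it. The result is deterministic in the
    input ordering.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("insufficient taxa: neighbour joining needs >= 3")
    if dmat.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    universe = frozenset(labels)
    anchor = labels[0]

    D = np.asarray(dmat, dtype=float).copy()
    nodes = [f"{lab}" for lab in labels]          # newick fragment per active node
    leafsets = [frozenset([lab]) for lab in labels]
    biparts: set[frozenset[str]] = set()

    def record(ls: frozenset[str]) -> None:
        if 2 <= len(ls) <= len(universe) - 2:
            biparts.add(_normalise(ls, anchor, universe))

    while len(nodes) > 3:
        m = len(nodes)
        # coalesce coincident nodes (zero distance) before consulting the
        # Q-criterion: with duplicate taxa — e.g. one clonal haplotype
        # sampled from several animals — Q can otherwise pull a distant
        # node in between the clones and break their clade
        off = D + np.where(np.eye(m, dtype=bool), np.inf, 0.0)
        zi = np.argwhere(off <= 1e-12)
        if zi.size:
            i, j = (int(x) for x in zi[0])
        else:
            r = D.sum(axis=1)
            q = (m - 2) * D - r[:, None] - r[None, :]
            np.fill_diagonal(q, np.inf)
            qmin = q.min()
            tol = 1e-9 * max(1.0, abs(qmin))
            tied = np.argwhere(q <= qmin + tol)
            order = np.lexsort((tied[:, 1], tied[:, 0], D[tied[:, 0], tied[:, 1]]))
            i, j = (int(x) for x in tied[order[0]])
        if i > j:
            i, j = j, i
        r = D.sum(axis=1)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        newick = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        newset = leafsets[i] | leafsets[j]
        record(newset)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [newick]
        leafsets = [leafsets[x] for x in keep] + [newset]

    # final trifurcation: closed-form branch lengths
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    for ls in leafsets:
        record(ls)
    newick = (f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},{nodes[2]}:{lc:.10g});")
    return NJResult(newick=newick, leaf_labels=tuple(labels),
                    bipartitions=frozenset(biparts))


def nj_tree(labels: Sequence[str], dmat: np.ndarray,
            taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Neighbour-joining tree as a :class:`dendropy.Tree`."""
    return neighbor_joining(labels, dmat).tree(taxon_namespace)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    labels: Sequence[str],
    alignment: np.ndarray | Sequence[str],
    n_replicates: int = 500,
    seed: int | np.random.Generator = 0,
    builder: Callable[[Sequence[str], np.ndarray], NJResult] | None = None,
) -> tuple[NJResult, dict[frozenset[str], float]]:
    """Column-resampling bootstrap supports for the NJ tree of an alignment.

    Each replicate resamples alignment columns with replacement, rebuilds
    the tree, and every bipartition of the full-data tree is scored by
    the percentage of replicate trees containing it.

    Returns the full-data :class:`NJResult` (with supports baked into the
    newick as internal node labels) and a bipartition -> support mapping.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(alignment, np.ndarray):
        aln = alignment
    else:
        aln = np.vstack([_as_codes(s) for s in alignment])
    ncols = aln.shape[1]
    if ncols == 1:
        import warnings
        warnings.warn("single-column alignment: bootstrap is degenerate")
    if builder is None:
        builder = lambda lb, mat: neighbor_joining(lb, mat)  # noqa: E731

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    main = builder(labels, k2p_matrix(aln))
    counts = {bp: 0 for bp in main.bipartitions}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep = builder(labels, k2p_matrix(aln[:, cols]))
        for bp in rep.bipartitions:
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    annotated = _annotate_supports(main, supports)
    return annotated, supports


def _annotate_supports(result: NJResult, supports: Mapping[frozenset[str], float]) -> NJResult:
    tree = result.tree()
    tree.encode_bipartitions()
    universe = frozenset(result.leaf_labels)
    anchor = result.leaf_labels[0]
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _normalise(side, anchor, universe)
        if key in supports:
            node.label = f"{supports[key]:g}"
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return NJResult(newick=newick, leaf_labels=result.leaf_labels,
                    bipartitions=result.bipartitions)


# ---------------------------------------------------------------------------
# Tumour placement test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlacementVerdict:
    tumour_monophyletic: bool
    sister_is_donor: bool


LEAF_CLASSES = ("tumour", "host", "donor", "outgroup")


def _edge_sides(tree_or_result: dendropy.Tree | NJResult) -> tuple[frozenset[str], set[frozenset[str]]]:
    if isinstance(tree_or_result, NJResult):
        universe = frozenset(tree_or_result.leaf_labels)
        sides: set[frozenset[str]] = set()
        for bp in tree_or_result.bipartitions:
            sides.add(bp)
            sides.add(frozenset(universe - bp))
        return universe, sides
    tree = tree_or_result
    universe = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    sides = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= len(universe) - 2:
            sides.add(side)
            sides.add(frozenset(universe - side))
    return universe, sides


def tumour_placement_test(tree: dendropy.Tree | NJResult,
                          label_map: Mapping[str, str]) -> PlacementVerdict:
    """Test tumour monophyly and donor-sister placement on an unrooted tree.

    ``label_map`` assigns each leaf one of ``tumour``, ``host``,
    ``donor`` or ``outgroup``. Monophyly holds iff some edge separates
    exactly the tumour leaves from everything else; the tumour clade is
    sister to the donor iff the smallest edge-side containing all tumour
    and all donor leaves contains no host leaf.
    """
    universe, sides = _edge_sides(tree)
    missing = universe - set(label_map)
    bad = {v for k, v in label_map.items() if k in universe} - set(LEAF_CLASSES)
    if missing or bad:
        raise ValueError("incomplete labeling: every leaf needs a valid class")
    groups = {cls: frozenset(l for l in universe if label_map[l] == cls)
              for cls in LEAF_CLASSES}
    for cls in ("tumour", "host", "donor"):
        if not groups[cls]:
            raise ValueError(f"incomplete labeling: no leaf labelled {cls!r}")

    tum, host, donor = groups["tumour"], groups["host"], groups["donor"]
    monophyletic = len(tum) == 1 or tum in sides

    needed = tum | donor
    candidates = [s for s in sides if needed <= s] + [universe]
    minimal = min(candidates, key=len)
    sister = not (minimal & host)
    return PlacementVerdict(tumour_monophyletic=monophyletic, sister_is_donor=sister)


# ---------------------------------------------------------------------------
# Whole-mitogenome comparison via external alignment
# ---------------------------------------------------------------------------

def k2p_between_fasta(path_a: str | Path, path_b: str | Path,
                      aligner: str = "mafft") -> float:
    """K2P distance between the first records of two FASTA files.

    The two sequences are globally aligned with mafft (``--auto``) and
    the distance computed over ungapped, unambiguous columns — the
    procedure used to compare two complete mitogenomes that are not
    pre-aligned. Requires the aligner on PATH.
    """
    from Bio import SeqIO

    rec_a = next(SeqIO.parse(str(path_a), "fasta"))
    rec_b = next(SeqIO.parse(str(path_b), "fasta"))
    if shutil.which(aligner) is None:
        raise RuntimeError(f"aligner {aligner!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        merged = Path(tmp) / "pair.fasta"
        merged.write_text(f">{rec_a.id}\n{rec_a.seq}\n>{rec_b.id}\n{rec_b.seq}\n")
        out = subprocess.run(
            [aligner, "--auto", "--quiet", str(merged)],
            check=True, capture_output=True, text=True,
        ).stdout
        aligned_path = Path(tmp) / "aligned.fasta"
        aligned_path.write_text(out)
        aligned = list(SeqIO.parse(str(aligned_path), "fasta"))
    return k2p(count_substitutions(str(aligned[0].seq), str(aligned[1].seq)))
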