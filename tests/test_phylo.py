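"""K2P distances, neighbour joining, bootstrap and the placement test."""

import math

import dendropy
import numpy as np
import pytest

from clamtc.phylo import (NJResult, PlacementVerdict, SubstitutionCounts,
                          bootstrap_support, count_substitutions, k2p, k2p_matrix,
                          neighbor_joining, nj_tree, tumour_placement_test)
from clamtc.seqcodes import BASES, decode, encode

# ---------------------------------------------------------------------------
# substitution counting
# ---------------------------------------------------------------------------

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def classify_column(a: str, b: str) -> str:
    """Independent per-column classifier used as the counting oracle."""
    if a not in "ACGT" or b not in "ACGT":
        return "skip"
    if a == b:
        return "same"
    return "transition" if (a, b) in TRANSITIONS else "transversion"


def test_identical_sequences_have_no_substitutions():
    c = count_substitutions("ACGTACGT", "ACGTACGT")
    assert (c.transitions, c.transversions, c.n) == (0, 0, 8)


def test_hand_counted_example():
    c = count_substitutions("AAAA", "GAAT")
    assert c.n == 4
    assert c.transitions == 1 and c.transversions == 1
    assert c.P == 0.25 and c.Q == 0.25


def test_ambiguous_and_gap_columns_are_skipped():
    c = count_substitutions("ACGTN-", "ACTTAA")
    assert c.n == 4
    assert c.transversions == 1 and c.transitions == 0


def test_counts_match_column_oracle_on_random_pairs():
    rng = np.random.default_rng(5)
    for _ in range(5):
        a = "".join(rng.choice(list("ACGTN"), size=1000, p=[0.24] * 4 + [0.04]))
        b = "".join(rng.choice(list("ACGTN"), size=1000, p=[0.24] * 4 + [0.04]))
        kinds = [classify_column(x, y) for x, y in zip(a, b)]
        c = count_substitutions(a, b)
        assert c.n == sum(k != "skip" for k in kinds)
        assert c.transitions == kinds.count("transition")
        assert c.transversions == kinds.count("transversion")


def test_counting_is_symmetric():
    rng = np.random.default_rng(6)
    a = decode(rng.integers(0, 4, 500).astype(np.uint8))
    b = decode(rng.integers(0, 4, 500).astype(np.uint8))
    ca, cb = count_substitutions(a, b), count_substitutions(b, a)
    assert (ca.transitions, ca.transversions) == (cb.transitions, cb.transversions)


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError, match="unaligned"):
        count_substitutions("ACGT", "ACG")


def test_all_ambiguous_rejected():
    with pytest.raises(ValueError, match="no comparable sites"):
        count_substitutions("NNN", "ACG")


# ---------------------------------------------------------------------------
# K2P closed form
# ---------------------------------------------------------------------------

def test_k2p_zero_distance():
    assert k2p(P=0.0, Q=0.0) == 0.0


def test_k2p_closed_form_value():
    # independent evaluation of -1/2 ln((1-2P-Q) sqrt(1-2Q))
    expected = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
    assert k2p(P=0.1, Q=0.05) == pytest.approx(expected, abs=1e-15)


def test_k2p_matches_independent_evaluation_on_grid():
    rng = np.random.default_rng(1)
    n = 0
    while n < 1000:
        P, Q = rng.uniform(0, 0.5, 2)
        if 1 - 2 * P - Q <= 1e-6 or 1 - 2 * Q <= 1e-6:
            continue
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert abs(k2p(P=P, Q=Q) - expected) < 1e-12
        n += 1


def test_k2p_saturation_raises():
    with pytest.raises(ValueError, match="saturated"):
        k2p(P=0.5, Q=0.1)
    with pytest.raises(ValueError, match="saturated"):
        k2p(P=0.05, Q=0.5)


def test_k2p_first_order_taylor_limit():
    # for small divergence d ~ P + Q
    for p, q in [(0.004, 0.002), (0.001, 0.0005), (0.006, 0.001)]:
        d = k2p(P=p, Q=q)
        assert d == pytest.approx(p + q, rel=0.01)


def test_k2p_of_counts_is_symmetric():
    rng = np.random.default_rng(2)
    a = decode(rng.integers(0, 4, 2000).astype(np.uint8))
    b = decode(rng.integers(0, 4, 2000).astype(np.uint8))
    # random 2-kb pairs sit near 75% mismatch, beyond K2P saturation; mix instead
    a = "ACGT" * 500
    bl = list(a)
    for i in rng.choice(2000, 100, replace=False):
        bl[i] = "ACGT"[(("ACGT".index(bl[i])) + int(rng.integers(1, 4))) % 4]
    b = "".join(bl)
    assert k2p(count_substitutions(a, b)) == pytest.approx(
        k2p(count_substitutions(b, a)), abs=1e-15)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def _tree_distances_from_newick(newick: str, labels) -> np.ndarray:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


def _random_additive_matrix(rng, labels):
    """Distances realised on a random unrooted binary tree (hand-rolled oracle).

    Builds the tree by attaching each new leaf to a random edge, then
    reads off path-length distances and internal-edge bipartitions.
    """
    taxa = list(labels)
    # adjacency: node -> {neighbour: branch length}; leaves are taxon names
    adj: dict = {t: {} for t in taxa[:3]}
    adj["i0"] = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    for t in taxa[:3]:
        connect(t, "i0", float(rng.uniform(0.05, 1.0)))
    next_internal = 1
    for t in taxa[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = f"i{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        connect(u, mid, w * split)
        connect(mid, v, w * (1 - split))
        connect(mid, t, float(rng.uniform(0.05, 1.0)))

    def path_lengths(src):
        dist, stack = {src: 0.0}, [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        return dist

    n = len(taxa)
    d = np.zeros((n, n))
    for i, t in enumerate(taxa):
        dist = path_lengths(t)
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist[taxa[j]]

    universe = frozenset(taxa)
    biparts = set()
    for u in adj:
        for v in adj[u]:
            if not (str(u).startswith("i") and str(v).startswith("i") and str(u) < str(v)):
                continue
            # leaves reachable from u without crossing (u, v)
            seen, stack = {u, v}, [u]
            side = set()
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
                        if y in universe:
                            side.add(y)
            side = frozenset(side)
            if 2 <= len(side) <= n - 2:
                biparts.add(side if taxa[0] not in side
                            else frozenset(universe - side))
    return d, biparts


def test_three_taxon_closed_form():
    labels = ["A", "B", "C"]
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    res = neighbor_joining(labels, d)
    recovered = _tree_distances_from_newick(res.newick, labels)
    assert np.allclose(recovered, d, atol=1e-9)


def test_fewer_than_three_taxa_rejected():
    with pytest.raises(ValueError, match="insufficient taxa"):
        neighbor_joining(["A", "B"], np.zeros((2, 2)))


@pytest.mark.parametrize("n_taxa", [4, 5])
def test_nj_recovers_random_additive_trees(n_taxa):
    """On additive matrices NJ returns the generating topology and lengths."""
    rng = np.random.default_rng(100 + n_taxa)
    labels = [f"t{i}" for i in range(n_taxa)]
    for _ in range(100):
        d, true_biparts = _random_additive_matrix(rng, labels)
        res = neighbor_joining(labels, d)
        assert res.bipartitions == frozenset(true_biparts)
        recovered = _tree_distances_from_newick(res.newick, labels)
        assert np.allclose(recovered, d, atol=1e-8)


def test_nj_matches_dendropy_on_random_noisy_matrix():
    """Cross-check topology against dendropy's independent NJ."""
    rng = np.random.default_rng(9)
    labels = [f"t{i}" for i in range(8)]
    d, _ = _random_additive_matrix(rng, labels)
    noise = rng.uniform(0, 0.01, size=d.shape)
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0.0)
    d = d + noise
    mine = neighbor_joining(labels, d)

    pdm_csv = "," + ",".join(labels) + "\n" + "\n".join(
        labels[i] + "," + ",".join(f"{d[i, j]:.10f}" for j in range(len(labels)))
        for i in range(len(labels)))
    import io
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(pdm_csv))
    their = pdm.nj_tree()
    their.encode_bipartitions()
    universe = frozenset(labels)
    their_biparts = set()
    for node in their.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= len(labels) - 2:
            their_biparts.add(side if labels[0] not in side
                              else frozenset(universe - side))
    assert mine.bipartitions == frozenset(their_biparts)


def test_nj_tree_returns_dendropy_tree():
    labels = ["A", "B", "C", "D"]
    d = np.array([[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], dtype=float)
    tree = nj_tree(labels, d)
    assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(labels)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_full_signal_alignment_gets_full_support():
    # two clear groups; every variable column supports the same split
    rng = np.random.default_rng(3)
    base = rng.integers(0, 4, 100).astype(np.uint8)
    other = base.copy()
    other[rng.choice(100, 30, replace=False)] ^= 2  # transitions at 30% of sites
    aln = np.vstack([base, base, other, other])
    labels = ["a1", "a2", "b1", "b2"]
    res, supports = bootstrap_support(labels, aln, n_replicates=50, seed=1)
    key = frozenset({"b1", "b2"})
    assert supports[key] == 100.0


def test_bootstrap_requires_at_least_one_replicate():
    with pytest.raises(ValueError, match="n_replicates"):
        bootstrap_support(["a", "b", "c"], np.zeros((3, 10), dtype=np.uint8),
                          n_replicates=0, seed=1)


def test_bootstrap_reproducible_and_order_invariant(species_pair, small_config):
    from clamtc.simulate import simulate_cohort
    cohA = simulate_cohort(species_pair, "host", 2, small_config)
    cohB = simulate_cohort(species_pair, "donor", 2, small_config)
    labels = [s.specimen_id for s in cohA + cohB]
    aln = np.vstack([encode(s.germline_mito) for s in cohA + cohB])
    _, sup1 = bootstrap_support(labels, aln, n_replicates=30, seed=7)
    _, sup2 = bootstrap_support(labels, aln, n_replicates=30, seed=7)
    assert sup1 == sup2
    # taxon order invariance of the supported split
    order = [2, 3, 0, 1]
    labels_r = [labels[i] for i in order]
    _, sup3 = bootstrap_support(labels_r, aln[order], n_replicates=30, seed=7)
    key = frozenset(labels[2:])
    key3 = frozenset(labels[:2])  # normalisation anchors on the first taxon
    assert sup1[key] == 100.0 and sup3[key3] == 100.0


# ---------------------------------------------------------------------------
# placement test
# ---------------------------------------------------------------------------

def _verdict_from_newick(newick: str, classes) -> PlacementVerdict:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tumour_placement_test(tree, classes)


def test_clean_separation_gives_both_true():
    classes = {"T1": "tumour", "T2": "tumour", "D1": "donor", "D2": "donor",
               "H1": "host", "H2": "host"}
    v = _verdict_from_newick("((T1:1,T2:1):1,(D1:1,D2:1):1,(H1:1,H2:1):1);", classes)
    assert v.tumour_monophyletic and v.sister_is_donor


def test_interleaved_tumour_breaks_monophyly():
    classes = {"T1": "tumour", "T2": "tumour", "D1": "donor",
               "H1": "host", "H2": "host"}
    v = _verdict_from_newick("((T1:1,H1:1):1,(T2:1,D1:1):1,H2:1);", classes)
    assert not v.tumour_monophyletic


def test_tumour_nested_in_host_fails_sister_test():
    classes = {"T1": "tumour", "T2": "tumour", "D1": "donor", "D2": "donor",
               "H1": "host", "H2": "host"}
    v = _verdict_from_newick("(((T1:1,T2:1):1,H1:1):1,(D1:1,D2:1):1,H2:1);", classes)
    assert v.tumour_monophyletic and not v.sister_is_donor


def test_missing_class_rejected():
    classes = {"T1": "tumour", "T2": "tumour", "H1": "host", "H2": "host"}
    with pytest.raises(ValueError, match="incomplete labeling"):
        _verdict_from_newick("((T1:1,T2:1):1,H1:1,H2:1);", classes)
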