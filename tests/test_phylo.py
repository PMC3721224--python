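"""p-distances, neighbor joining and phylogroup delineation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chemotype_map.phylo import (
    PhyloError,
    assign_phylogroups,
    distance_matrix,
    divergence_report,
    jc_distance,
    neighbor_joining,
    p_distance,
    read_alignment,
)


def matrix_from(pairs, ids):
    m = np.zeros((len(ids), len(ids)))
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=ids, columns=ids)


def random_additive_tree(n_leaves, rng):
    """A random binary tree as (edges dict, leaf path-length matrix).

    Built by sequentially attaching leaves to a random existing edge, so every
    topology on the leaf set is reachable; branch lengths are uniform(0.5, 2),
    guaranteeing strictly positive internal edges (NJ-identifiable).
    """
    leaves = [f"L{i}" for i in range(n_leaves)]
    edges = {frozenset(("L0", "L1")): float(rng.uniform(0.5, 2.0))}
    counter = itertools.count()
    for leaf in leaves[2:]:
        edge = list(edges)[rng.integers(len(edges))]
        a, b = sorted(edge, key=str)
        length = edges.pop(edge)
        mid = f"I{next(counter)}"
        split = float(rng.uniform(0.25, 0.75))
        edges[frozenset((a, mid))] = length * split
        edges[frozenset((mid, b))] = length * (1 - split)
        edges[frozenset((mid, leaf))] = float(rng.uniform(0.5, 2.0))
    # path lengths by BFS
    nodes = {n for e in edges for n in e}
    adj = {n: [] for n in nodes}
    for e, l in edges.items():
        a, b = tuple(e)
        adj[a].append((b, l))
        adj[b].append((a, l))
    dist = {}
    for src in leaves:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, l in adj[node]:
                if nxt not in seen:
                    seen[nxt] = seen[node] + l
                    stack.append(nxt)
        for dst in leaves:
            dist[(src, dst)] = seen[dst]
    m = pd.DataFrame(
        [[dist[(a, b)] for b in leaves] for a in leaves], index=leaves, columns=leaves
    )
    return edges, m


def canonical_split(side, leafset):
    # a bipartition is identified by either side; keep the lexicographically
    # smaller one so even splits compare deterministically
    other = leafset - side
    return min(frozenset(side), frozenset(other), key=lambda s: sorted(s))


def splits_of(tree):
    leafset = frozenset(tree.leaves)
    return {
        canonical_split(min(tree.split(e), key=sorted), leafset)
        for e in tree.internal_edges()
    }


def splits_of_edge_dict(edges, leaves):
    # brute-force splits of the generating tree
    out = set()
    leafset = frozenset(leaves)
    for e in edges:
        if any(n in leaves for n in e):
            continue
        a, _ = tuple(e)
        seen = {a}
        stack = [a]
        while stack:
            node = stack.pop()
            for e2 in edges:
                if node in e2 and e2 != e:
                    other = next(iter(e2 - {node}))
                    if other not in seen:
                        seen.add(other)
                        stack.append(other)
        side = frozenset(s for s in seen if s in leafset)
        out.add(canonical_split(side, leafset))
    return out


class TestPDistance:
    def test_identical_sequences(self):
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_single_mismatch(self):
        assert p_distance("ACGT", "ACGA") == 0.25

    def test_pairwise_deletion_of_gaps(self):
        assert p_distance("AC-T", "ACGT") == 0.0

    def test_ambiguity_codes_excluded(self):
        assert p_distance("ACRT", "ACGT") == 0.0  # R treated as missing

    def test_symmetry(self):
        assert p_distance("ACGTAC", "ATGTAA") == p_distance("ATGTAA", "ACGTAC")

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(PhyloError):
            p_distance("--", "AC")

    def test_length_mismatch_rejected(self):
        with pytest.raises(PhyloError):
            p_distance("ACG", "ACGT")


class TestJcDistance:
    def test_zero_maps_to_zero(self):
        assert jc_distance(0.0) == 0.0

    def test_divergence_bound_value(self):
        assert jc_distance(0.0210) == pytest.approx(0.02130, abs=1e-4)

    def test_saturation_rejected(self):
        with pytest.raises(PhyloError):
            jc_distance(0.75)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        m = matrix_from(
            {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7},
            list("ABCD"),
        )
        tree = neighbor_joining(m)
        lengths = {
            frozenset(k & {"A", "B", "C", "D"}): v
            for k, v in tree.edges.items()
            if k & {"A", "B", "C", "D"}
        }
        assert lengths[frozenset({"A"})] == pytest.approx(1.0)
        assert lengths[frozenset({"B"})] == pytest.approx(2.0)
        assert lengths[frozenset({"C"})] == pytest.approx(3.0)
        assert lengths[frozenset({"D"})] == pytest.approx(4.0)
        internal = tree.internal_edges()
        assert len(internal) == 1
        assert tree.edges[internal[0]] == pytest.approx(1.0)
        assert set(map(frozenset, tree.split(internal[0]))) == {
            frozenset({"A", "B"}),
            frozenset({"C", "D"}),
        }

    def test_three_taxon_closed_form(self):
        m = matrix_from({("A", "B"): 0.2, ("A", "C"): 0.3, ("B", "C"): 0.5}, list("ABC"))
        tree = neighbor_joining(m)
        # l_A = (dAB + dAC - dBC)/2 = 0, l_B = 0.2, l_C = 0.3
        get = lambda leaf: next(v for k, v in tree.edges.items() if leaf in k)
        assert get("A") == pytest.approx(0.0)
        assert get("B") == pytest.approx(0.2)
        assert get("C") == pytest.approx(0.3)

    def test_identical_rows_join_at_zero_length(self):
        m = matrix_from(
            {("A", "B"): 0.0, ("A", "C"): 0.4, ("B", "C"): 0.4, ("A", "D"): 0.6,
             ("B", "D"): 0.6, ("C", "D"): 0.5},
            list("ABCD"),
        )
        tree = neighbor_joining(m)
        get = lambda leaf: next(v for k, v in tree.edges.items() if leaf in k)
        assert get("A") == pytest.approx(0.0)
        assert get("B") == pytest.approx(0.0)

    def test_too_few_taxa_rejected(self):
        m = matrix_from({("A", "B"): 0.1}, list("AB"))
        with pytest.raises(PhyloError):
            neighbor_joining(m)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            edges, m = random_additive_tree(n, rng)
            tree = neighbor_joining(m)
            assert splits_of(tree) == splits_of_edge_dict(edges, set(m.index))
            # additivity: NJ path lengths reproduce the input distances
            for a, b in itertools.combinations(m.index, 2):
                path = _path_length(tree, a, b)
                assert path == pytest.approx(m.loc[a, b], abs=1e-9)

    def test_agrees_with_skbio_topology(self, default_bundle):
        import skbio

        seqs = default_bundle.sequences["cox1"]
        dm = distance_matrix(seqs)
        ours = neighbor_joining(dm)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index)))
        ours_groups = set(map(frozenset, ours.split(max(ours.internal_edges(), key=lambda e: ours.edges[e]))))
        labels = assign_phylogroups(ours, k=2)
        # the deepest split found by our NJ matches a bipartition present in
        # scikit-bio's NJ tree
        sk_splits = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            sk_splits.add(side)
            sk_splits.add(frozenset(dm.index) - side)
        assert all(g in sk_splits for g in ours_groups)


def _path_length(tree, a, b):
    adj = {}
    for e, l in tree.edges.items():
        x, y = tuple(e)
        adj.setdefault(x, []).append((y, l))
        adj.setdefault(y, []).append((x, l))
    seen = {a: 0.0}
    stack = [a]
    while stack:
        node = stack.pop()
        for nxt, l in adj[node]:
            if nxt not in seen:
                seen[nxt] = seen[node] + l
                stack.append(nxt)
    return seen[b]


class TestAssignPhylogroups:
    def test_k_one_is_a_single_group(self):
        m = matrix_from({("A", "B"): 0.2, ("A", "C"): 0.3, ("B", "C"): 0.5}, list("ABC"))
        tree = neighbor_joining(m)
        assert set(assign_phylogroups(tree, k=1).values()) == {"A"}

    def test_star_tree_cannot_be_split(self):
        m = matrix_from({("A", "B"): 0.2, ("A", "C"): 0.2, ("B", "C"): 0.2}, list("ABC"))
        tree = neighbor_joining(m)
        with pytest.raises(PhyloError):
            assign_phylogroups(tree, k=2)

    def test_four_taxon_split(self):
        m = matrix_from(
            {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7},
            list("ABCD"),
        )
        labels = assign_phylogroups(neighbor_joining(m), k=2)
        assert labels["A"] == labels["B"] != labels["C"]
        assert labels["C"] == labels["D"]

    def test_two_clade_sequences_recovered(self, default_bundle):
        truth = default_bundle.ground_truth
        for marker, seqs in default_bundle.sequences.items():
            labels = assign_phylogroups(neighbor_joining(distance_matrix(seqs)), k=2)
            want = truth.phylogroups(marker)
            groups = lambda lab: set(
                frozenset(s for s in lab if lab[s] == g) for g in set(lab.values())
            )
            assert groups(labels) == groups(want)

    def test_labels_sorted_by_group_size(self, default_bundle):
        seqs = default_bundle.sequences["cox1"]
        labels = assign_phylogroups(neighbor_joining(distance_matrix(seqs)), k=2)
        sizes = {g: sum(1 for v in labels.values() if v == g) for g in set(labels.values())}
        assert sizes["A"] >= sizes["B"]


class TestDivergenceReport:
    def test_identical_sequences_have_zero_divergence(self):
        dm = distance_matrix({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        rep = divergence_report(dm, marker="cox1")
        assert rep["max_overall_pct"] == 0.0
        assert rep["conspecific"]

    def test_synthetic_bounds_respected(self, default_bundle):
        bounds = {"cox1": 2.1, "rbcL": 1.1}
        for marker, seqs in default_bundle.sequences.items():
            dm = distance_matrix(seqs)
            labels = assign_phylogroups(neighbor_joining(dm), k=2)
            rep = divergence_report(dm, labels, marker=marker)
            assert rep["max_overall_pct"] <= bounds[marker]
            assert rep["conspecific"]
            for g, entry in rep["phylogroups"].items():
                assert entry["max_within_pct"] <= rep["max_overall_pct"]

    def test_report_counts_marker_coverage(self):
        dm = distance_matrix({"a": "ACGT", "b": "ACCT", "c": "ACGA"})
        rep = divergence_report(dm, assignment={"a": "A", "b": "A"}, marker="rbcL")
        assert rep["n_samples"] == 3
        assert rep["unassigned"] == ["c"]


class TestReadAlignment:
    def test_unaligned_input_rejected_loudly(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(PhyloError, match="not aligned"):
            read_alignment(path)

    def test_round_trip_from_bundle(self, bundle_dir):
        seqs = read_alignment(bundle_dir / "cox1.fasta")
        assert len(seqs) == 21
        assert {len(s) for s in seqs.values()} == {660}
        seqs = read_alignment(bundle_dir / "rbcL.fasta")
        assert {len(s) for s in seqs.values()} == {890}
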