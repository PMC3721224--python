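"""Pairwise divergence, neighbor joining and phylogroup assignment.

DNA barcodes (mitochondrial cox1, plastid rbcL) of the sampled individuals are
compared by uncorrected p-distance with pairwise deletion of gaps and
ambiguous sites; a Jukes-Cantor correction is available for reporting.  A
neighbor-joining tree is built from the distance matrix and phylogroups are
delineated by removing the longest internal edges — for the two-clade case of
conspecific lineages, the single deepest split.  Divergence summaries flag
conspecificity when the maximum pairwise divergence stays below marker-typical
intraspecific bounds (2.1% for cox1, 1.1% for rbcL in this system).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PhyloError",
    "DIVERGENCE_THRESHOLDS_PCT",
    "read_alignment",
    "p_distance",
    "jc_distance",
    "distance_matrix",
    "PhyloTree",
    "neighbor_joining",
    "assign_phylogroups",
    "divergence_report",
]

#: default conspecificity bounds (max overall p-distance, %) per marker
DIVERGENCE_THRESHOLDS_PCT: dict[str, float] = {"cox1": 2.1, "rbcL": 1.1}

_UNAMBIGUOUS = frozenset("ACGT")


class PhyloError(ValueError):
    """Raised for invalid alignments, distances or trees."""


def read_alignment(path) -> dict[str, str]:
    """Read a pre-aligned FASTA into an id -> sequence mapping.

    All sequences must have equal length (the pipeline consumes alignments,
    it does not build them); a length mismatch is a loud error, never silent
    trimming.  Ambiguity codes other than N are treated as N downstream.
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise PhyloError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise PhyloError(f"{path}: no FASTA records found")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise PhyloError(
            f"{path}: sequences are not aligned (lengths {sorted(lengths)}); "
            "align them before running the pipeline"
        )
    return records


def p_distance(seq1: str, seq2: str) -> float:
    """Uncorrected proportion of differing sites, with pairwise deletion.

    Sites where either sequence has a gap or any non-ACGT symbol are excluded
    from the comparison.
    """
    if len(seq1) != len(seq2):
        raise PhyloError("sequences must be aligned to equal length")
    compared = 0
    mismatches = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a in _UNAMBIGUOUS and b in _UNAMBIGUOUS:
            compared += 1
            if a != b:
                mismatches += 1
    if compared == 0:
        raise PhyloError("no comparable sites after pairwise deletion")
    return mismatches / compared


def jc_distance(p: float) -> float:
    """Jukes-Cantor corrected distance -(3/4) ln(1 - 4p/3) in substitutions/site."""
    if not 0 <= p < 0.75:
        raise PhyloError(f"p-distance {p} is saturated (must be < 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def distance_matrix(seqs: Mapping[str, str], corrected: bool = False) -> pd.DataFrame:
    """Pairwise p-distances (or Jukes-Cantor distances) for an alignment."""
    ids = list(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p = p_distance(seqs[ids[i]], seqs[ids[j]])
        d[i, j] = d[j, i] = jc_distance(p) if corrected else p
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class PhyloTree:
    """An unrooted tree as an undirected edge-weighted graph.

    Leaves carry sample ids; internal nodes are numbered ``_nj<k>``.
    """

    leaves: list[str]
    edges: dict[frozenset, float] = field(default_factory=dict)

    def neighbors(self, node) -> list:
        return sorted(
            (next(iter(e - {node})) for e in self.edges if node in e), key=str
        )

    def internal_edges(self) -> list[frozenset]:
        leafset = set(self.leaves)
        return [e for e in self.edges if not (e & leafset)]

    def split(self, edge: frozenset) -> tuple[set, set]:
        """Leaf sets on either side of an edge."""
        a, b = sorted(edge, key=str)
        side_a = self._reachable(a, edge)
        side_b = self._reachable(b, edge)
        return (side_a & set(self.leaves), side_b & set(self.leaves))

    def _reachable(self, start, blocked: frozenset) -> set:
        seen = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for e in self.edges:
                if node in e and e != blocked:
                    other = next(iter(e - {node}))
                    if other not in seen:
                        seen.add(other)
                        stack.append(other)
        return seen

    def newick(self) -> str:
        """Newick string rooted arbitrarily at the first internal node."""
        internal = sorted({n for e in self.edges for n in e if n not in set(self.leaves)}, key=str)
        root = internal[0] if internal else self.leaves[0]

        def render(node, parent) -> str:
            kids = [k for k in self.neighbors(node) if k != parent]
            if not kids:
                return str(node)
            inner = ",".join(
                f"{render(k, node)}:{self.edges[frozenset((node, k))]:.6f}" for k in kids
            )
            return f"({inner})"

        return render(root, None) + ";"


def neighbor_joining(matrix: pd.DataFrame) -> PhyloTree:
    """Standard neighbor joining (Q-criterion) on a distance matrix.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sibling edge so the joined pair's distance is preserved.  Ties in
    the Q criterion are broken by the smallest (row, column) index pair.
    """
    ids = [str(i) for i in matrix.index]
    n = len(ids)
    if n < 3:
        raise PhyloError("neighbor joining needs at least three taxa")
    dm = matrix.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T, atol=1e-12) or np.any(np.diag(dm) != 0):
        raise PhyloError("distance matrix must be symmetric with zero diagonal")

    nodes: list = list(ids)
    d: dict[frozenset, float] = {
        frozenset((ids[i], ids[j])): float(dm[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    tree = PhyloTree(leaves=list(ids))
    counter = itertools.count(1)

    def dist(a, b) -> float:
        return 0.0 if a == b else d[frozenset((a, b))]

    while len(nodes) > 3:
        m = len(nodes)
        r = {a: sum(dist(a, b) for b in nodes) for a in nodes}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = nodes[i], nodes[j]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, i, j)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        # clamp negatives, preserving la + lb = d(a, b)
        if la < 0:
            la, lb = 0.0, dab
        elif lb < 0:
            la, lb = dab, 0.0
        u = f"_nj{next(counter)}"
        tree.edges[frozenset((a, u))] = la
        tree.edges[frozenset((b, u))] = lb
        for c in nodes:
            if c in (a, b):
                continue
            d[frozenset((u, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        nodes = [c for c in nodes if c not in (a, b)] + [u]

    a, b, c = nodes
    u = f"_nj{next(counter)}"
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
        tree.edges[frozenset((x, u))] = max(lx, 0.0)
    return tree


def assign_phylogroups(tree: PhyloTree, k: int = 2) -> dict[str, str]:
    """Label leaves by cutting the k-1 longest internal edges of an NJ tree.

    Groups are lettered A, B, ... by decreasing size, ties broken by smallest
    leaf id.  A star tree (no internal edge) cannot be split.
    """
    if k < 1 or k > len(tree.leaves):
        raise PhyloError(f"k must be in [1, {len(tree.leaves)}]")
    if k == 1:
        return {leaf: "A" for leaf in tree.leaves}
    internal = tree.internal_edges()
    if len(internal) < k - 1:
        raise PhyloError(
            f"tree has {len(internal)} internal edge(s); cannot delineate {k} phylogroups"
        )
    # deterministic: longest edge first, ties by the smaller side's sorted leaf ids
    internal.sort(key=lambda e: (-tree.edges[e], sorted(min(tree.split(e), key=sorted))))
    cut = set(internal[: k - 1])

    groups: list[set] = []
    unassigned = set(tree.leaves)
    leafset = set(tree.leaves)
    seen_nodes: set = set()
    all_nodes = {n for e in tree.edges for n in e}
    for start in sorted(all_nodes, key=str):
        if start in seen_nodes:
            continue
        comp = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for e in tree.edges:
                if node in e and e not in cut:
                    other = next(iter(e - {node}))
                    if other not in comp:
                        comp.add(other)
                        stack.append(other)
        seen_nodes |= comp
        leaves = comp & leafset
        if leaves:
            groups.append(leaves)
    groups.sort(key=lambda g: (-len(g), sorted(g)))
    labels = {}
    for gi, group in enumerate(groups):
        letter = chr(ord("A") + gi)
        for leaf in group:
            labels[leaf] = letter
    unassigned -= set(labels)
    if unassigned:
        raise PhyloError(f"leaves not reachable in tree: {sorted(unassigned)}")
    return labels


def divergence_report(
    matrix: pd.DataFrame,
    assignment: Mapping[str, str] | None = None,
    marker: str | None = None,
    threshold_pct: float | None = None,
) -> dict:
    """Summarise pairwise divergence (%) overall and within phylogroups.

    Flags conspecificity when the maximum overall p-distance does not exceed
    the marker's threshold.  Reports per-marker sample coverage so that
    partially sequenced studies are visible rather than assumed complete.
    """
    ids = [str(i) for i in matrix.index]
    d = matrix.to_numpy(dtype=float)
    iu = np.triu_indices(len(ids), k=1)
    max_overall = float(d[iu].max()) * 100.0 if iu[0].size else 0.0
    report: dict = {
        "marker": marker,
        "n_samples": len(ids),
        "sample_ids": ids,
        "max_overall_pct": max_overall,
    }
    if assignment is not None:
        within = {}
        for group in sorted(set(assignment.values())):
            members = [i for i in ids if assignment.get(i) == group]
            idx = [ids.index(m) for m in members]
            sub = d[np.ix_(idx, idx)]
            within[group] = {
                "n": len(members),
                "max_within_pct": float(sub.max()) * 100.0 if len(members) > 1 else 0.0,
            }
        report["phylogroups"] = within
        report["unassigned"] = sorted(set(ids) - set(assignment))
    if threshold_pct is None and marker is not None:
        threshold_pct = DIVERGENCE_THRESHOLDS_PCT.get(marker)
    if threshold_pct is not None:
        report["threshold_pct"] = threshold_pct
        report["conspecific"] = max_overall <= threshold_pct
    return report
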