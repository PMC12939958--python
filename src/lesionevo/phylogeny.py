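"""Per-case lesion phylogenies from binary presence/absence characters.

With at most a handful of samples per case (myometrium Nm, normal gland N,
precursor L, carcinoma G) the space of unrooted binary topologies is tiny
(3 trees for 4 taxa, 15 for 5, 105 for 6), so the search is exhaustive and
exact: every topology is scored by Fitch small parsimony per character and
the minimum-score tree returned, with ties reported as unresolved.  A
two-state symmetric-model maximum-likelihood scorer over the same topology
space is provided as a concordance cross-check.  Trees are rooted at Nm for
display and Newick output, with branch lengths equal to the number of
characters whose minimal change placement falls on that branch.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .records import TopologyType, interval_overlap
from .stats import TestResult, wilcoxon_rank_sum

__all__ = [
    "BinaryCharacterMatrix",
    "LesionTree",
    "build_matrix",
    "enumerate_topologies",
    "fitch_score",
    "parsimony_tree",
    "classify_topology",
    "cna_event_tree",
    "shared_vaf_comparison",
    "ml_cross_check",
]

MAX_TAXA = 6


@dataclass
class BinaryCharacterMatrix:
    """Taxa x characters 0/1 matrix; characters are variant or event keys."""

    taxa: tuple[str, ...]
    characters: tuple[str, ...]
    matrix: np.ndarray  # shape (n_taxa, n_characters)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("matrix shape does not match taxa/characters")

    @property
    def uninformative(self) -> np.ndarray:
        """Mask of characters that cannot discriminate between topologies
        (present in <= 1 or >= n-1 taxa); they are retained and still count
        on terminal/root branches."""
        ones = self.matrix.sum(axis=0)
        return (ones <= 1) | (ones >= len(self.taxa) - 1)


@dataclass
class LesionTree:
    taxa: tuple[str, ...]
    topology: tuple | None  # nested-tuple unrooted representation; None if empty
    score: int
    branch_counts: dict[frozenset, int] = field(default_factory=dict)
    tied_topologies: list[tuple] = field(default_factory=list)
    newick: str = ""

    @property
    def unresolved(self) -> bool:
        return self.topology is None or len(self.tied_topologies) > 1


def build_matrix(
    variants_by_sample: Mapping[str, pd.DataFrame], include_nm: str | None = "Nm"
) -> BinaryCharacterMatrix:
    """Binary presence/absence matrix over distinct (chrom, pos, ref, alt)
    keys.  The Nm taxon, if requested, is an all-zero outgroup row (its
    variants were already subtracted as germline)."""
    keys: dict[tuple, None] = {}
    presence: dict[str, set] = {}
    for sample, df in variants_by_sample.items():
        if len(df):
            sample_keys = set(
                map(tuple, df[["chrom", "pos", "ref", "alt"]].itertuples(index=False))
            )
        else:
            sample_keys = set()
        presence[sample] = sample_keys
        for k in sorted(sample_keys):
            keys.setdefault(k, None)
    taxa = list(variants_by_sample)
    if include_nm and include_nm not in taxa:
        taxa = [include_nm] + taxa
        presence[include_nm] = set()
    characters = tuple("{}:{}:{}>{}".format(*k) for k in keys)
    mat = np.zeros((len(taxa), len(keys)), dtype=np.int8)
    for i, t in enumerate(taxa):
        for j, k in enumerate(keys):
            if k in presence[t]:
                mat[i, j] = 1
    return BinaryCharacterMatrix(tuple(taxa), characters, mat)


# ---------------------------------------------------------------------------
# topology enumeration and Fitch machinery
#
# An unrooted tree is a nested tuple whose top level is the trifurcating
# "center"; every other internal node is binary.


def enumerate_topologies(taxa: Sequence[str]) -> list[tuple]:
    """All unrooted binary topologies over the taxa (3 for 4 taxa, 15 for 5,
    105 for 6), generated by leaf insertion into every edge."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    if len(taxa) > MAX_TAXA:
        raise ValueError(f"exhaustive search limited to {MAX_TAXA} taxa")

    def insert_everywhere(node: tuple, leaf):
        for i, child in enumerate(node):
            yield node[:i] + ((child, leaf),) + node[i + 1 :]
            if isinstance(child, tuple):
                for sub in insert_everywhere(child, leaf):
                    yield node[:i] + (sub,) + node[i + 1 :]

    trees = [tuple(taxa[:3])]
    for leaf in taxa[3:]:
        trees = [t for base in trees for t in insert_everywhere(base, leaf)]
    return trees


def _edges_and_children(topology: tuple):
    """Flatten a nested-tuple topology into integer node ids.

    Returns (edges as (parent, child) pairs, leaf labels by node id,
    children lists by node id)."""
    edges: list[tuple[int, int]] = []
    labels: dict[int, str] = {}
    children: dict[int, list[int]] = {}
    counter = [0]

    def walk(node) -> int:
        nid = counter[0]
        counter[0] += 1
        children[nid] = []
        if isinstance(node, tuple):
            for ch in node:
                cid = walk(ch)
                children[nid].append(cid)
                edges.append((nid, cid))
        else:
            labels[nid] = node
        return nid

    walk(topology)
    return edges, labels, children


def _leafset_below(nid: int, labels, children) -> frozenset:
    if nid in labels:
        return frozenset([labels[nid]])
    out: set = set()
    for c in children[nid]:
        out |= _leafset_below(c, labels, children)
    return frozenset(out)


def fitch_score(topology: tuple, states: Mapping[str, int]) -> int:
    """Fitch small-parsimony change count for one character (any arity)."""
    _, labels, children = _edges_and_children(topology)

    def score(nid) -> tuple[frozenset, int]:
        if nid in labels:
            return frozenset([states[labels[nid]]]), 0
        total = 0
        cur: frozenset | None = None
        for c in children[nid]:
            s, t = score(c)
            total += t
            if cur is None:
                cur = s
            else:
                inter = cur & s
                if inter:
                    cur = inter
                else:
                    cur = cur | s
                    total += 1
        return cur, total

    return score(0)[1]


def _canonical_edge_key(below: frozenset, all_leaves: frozenset) -> frozenset:
    comp = all_leaves - below
    return min(below, comp, key=lambda s: (len(s), tuple(sorted(s))))


def _min_assignment_changes(topology: tuple, states: Mapping[str, int]) -> dict[frozenset, int]:
    """Minimal-change state assignment with changes deferred toward leaves.

    The unrooted tree is re-rooted at a leaf (Nm when present) so every
    internal node is binary; bottom-up Fitch sets are then refined top-down,
    keeping the parent state whenever the node's set allows it — which places
    each change on the most terminal admissible branch.  Returns changes per
    edge, keyed by the smaller-side leaf set of the edge's split.
    """
    edges, labels, _ = _edges_and_children(topology)
    adj: dict[int, list[int]] = defaultdict(list)
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    leaf_nodes = {v: k for k, v in labels.items()}
    root = leaf_nodes.get("Nm", leaf_nodes[min(leaf_nodes)])
    all_leaves = frozenset(labels.values())
    sets: dict[int, frozenset] = {}

    def down(nid, parent) -> None:
        kids = [c for c in adj[nid] if c != parent]
        if not kids:
            sets[nid] = frozenset([states[labels[nid]]])
            return
        cur: frozenset | None = None
        for c in kids:
            down(c, nid)
            s = sets[c]
            cur = s if cur is None else ((cur & s) or (cur | s))
        sets[nid] = cur

    def leafset(nid, parent) -> frozenset:
        out, stack = set(), [(nid, parent)]
        while stack:
            n, p = stack.pop()
            if n in labels:
                out.add(labels[n])
            stack.extend((nb, n) for nb in adj[n] if nb != p)
        return frozenset(out)

    nb = adj[root][0]
    down(nb, root)
    per_edge: dict[frozenset, int] = {}

    def up(nid, parent, parent_state) -> None:
        st = parent_state if parent_state in sets[nid] else min(sets[nid])
        if st != parent_state:
            key = _canonical_edge_key(leafset(nid, parent), all_leaves)
            per_edge[key] = per_edge.get(key, 0) + 1
        for c in adj[nid]:
            if c != parent:
                up(c, nid, st)

    up(nb, root, states[labels[root]])
    return per_edge


def _splits_of(topology: tuple) -> set[frozenset]:
    """Non-trivial splits, each as its lexicographically-least smaller side."""
    edges, labels, children = _edges_and_children(topology)
    all_leaves = _leafset_below(0, labels, children)
    splits = set()
    for _, child in edges:
        below = _leafset_below(child, labels, children)
        if 1 < len(below) < len(all_leaves) - 1:
            comp = all_leaves - below
            splits.add(min(below, comp, key=lambda s: (len(s), sorted(s))))
    return splits


def _to_newick(topology: tuple, branch_counts: dict[frozenset, int], root_taxon: str = "Nm") -> str:
    """Newick rooted at ``root_taxon`` (when present) with branch lengths
    equal to per-branch character counts."""
    edges, labels, children = _edges_and_children(topology)
    adj: dict[int, list[int]] = defaultdict(list)
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    all_leaves = frozenset(labels.values())

    def leafset(nid, parent) -> frozenset:
        out, stack = set(), [(nid, parent)]
        while stack:
            n, p = stack.pop()
            if n in labels:
                out.add(labels[n])
            stack.extend((nb, n) for nb in adj[n] if nb != p)
        return frozenset(out)

    def count_for(below: frozenset) -> int:
        return branch_counts.get(below, branch_counts.get(all_leaves - below, 0))

    def render(nid, parent) -> str:
        below = leafset(nid, parent)
        if nid in labels and not [k for k in adj[nid] if k != parent]:
            return f"{labels[nid]}:{count_for(below)}"
        inner = ",".join(render(k, nid) for k in adj[nid] if k != parent)
        return f"({inner}):{count_for(below)}"

    leaf_nodes = {v: k for k, v in labels.items()}
    if root_taxon in leaf_nodes:
        r = leaf_nodes[root_taxon]
        nb = adj[r][0]
        inner = ",".join(render(k, nb) for k in adj[nb] if k != r)
        return f"({root_taxon}:{count_for(frozenset([root_taxon]))},({inner}):0);"
    inner = ",".join(render(k, 0) for k in adj[0])
    return f"({inner});"


def parsimony_tree(matrix: BinaryCharacterMatrix) -> LesionTree:
    """Exhaustive-search maximum-parsimony tree over the matrix's taxa.

    All unrooted binary topologies are scored (sum of Fitch change counts
    over characters); the minimum-score tree is returned with per-branch
    change counts, and score ties are reported via ``tied_topologies``.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa for a tree")
    if n > MAX_TAXA:
        raise ValueError(f"exhaustive search limited to {MAX_TAXA} taxa")
    if len(matrix.characters) == 0:
        return LesionTree(matrix.taxa, None, 0, {}, [], "")
    topologies = enumerate_topologies(matrix.taxa)
    chars = [
        {t: int(matrix.matrix[i, j]) for i, t in enumerate(matrix.taxa)}
        for j in range(len(matrix.characters))
    ]
    scores = [sum(fitch_score(topo, c) for c in chars) for topo in topologies]
    best = min(scores)
    tied = [t for t, s in zip(topologies, scores) if s == best]
    chosen = tied[0]
    branch_counts: dict[frozenset, int] = {}
    for c in chars:
        for key, cnt in _min_assignment_changes(chosen, c).items():
            branch_counts[key] = branch_counts.get(key, 0) + cnt
    return LesionTree(
        matrix.taxa, chosen, int(best), branch_counts, tied, _to_newick(chosen, branch_counts)
    )


def classify_topology(tree: LesionTree) -> TopologyType:
    """Map a lesion tree onto the Type 1/2/3 patterns.

    Type 1: L and G share a common branch (cherry against {N, Nm}),
    consistent with a precursor-to-carcinoma transition; Type 2: N and L
    cherry; Type 3: N and G cherry.  Cases without an N sample, empty trees
    and parsimony ties with conflicting splits are unresolved.
    """
    taxa = set(tree.taxa)
    if tree.topology is None or not {"N", "L", "G"} <= taxa:
        return TopologyType.UNRESOLVED
    if tree.unresolved:
        split_sets = [_splits_of(t) for t in tree.tied_topologies]
        if not all(s == split_sets[0] for s in split_sets):
            return TopologyType.UNRESOLVED
    mapping = {
        frozenset({"L", "G"}): TopologyType.TYPE1,
        frozenset({"N", "L"}): TopologyType.TYPE2,
        frozenset({"N", "G"}): TopologyType.TYPE3,
    }
    for split in _splits_of(tree.topology):
        if split in mapping:
            return mapping[split]
        comp = frozenset(taxa) - split
        if comp in mapping:
            return mapping[comp]
    return TopologyType.UNRESOLVED


def cna_event_tree(
    events_by_sample: Mapping[str, pd.DataFrame],
    min_reciprocal_overlap: float = 0.5,
    include_nm: str = "Nm",
) -> LesionTree:
    """Parsimony tree over copy-number events.

    Events of the same type from different samples are clustered into one
    binary character when their intervals reciprocally overlap by at least
    the given fraction (single linkage); presence/absence per sample then
    feeds the same exhaustive Fitch machinery as the short-variant tree.
    """
    samples = list(events_by_sample)
    records = []
    for s in samples:
        for row in events_by_sample[s].itertuples(index=False):
            records.append((s, row.chrom, int(row.start), int(row.end), row.event_type))
    taxa = [include_nm] + samples if include_nm not in samples else samples
    if not records:
        return LesionTree(tuple(taxa), None, 0, {}, [], "")

    def reciprocal(i: int, j: int) -> bool:
        si, ci, sti, eni, ti = records[i]
        sj, cj, stj, enj, tj = records[j]
        if ti != tj or ci != cj:
            return False
        ov = interval_overlap(sti, eni, stj, enj)
        return (
            ov / (eni - sti + 1) >= min_reciprocal_overlap
            and ov / (enj - stj + 1) >= min_reciprocal_overlap
        )

    clusters: list[list[int]] = []
    for i in range(len(records)):
        hit = next(
            (cl for cl in clusters if any(reciprocal(i, j) for j in cl)), None
        )
        (hit.append(i) if hit is not None else clusters.append([i]))
    characters = []
    mat = np.zeros((len(taxa), len(clusters)), dtype=np.int8)
    for j, cl in enumerate(clusters):
        _, c0, st0, en0, t0 = records[cl[0]]
        characters.append(f"{c0}:{st0}-{en0}:{t0}")
        for i in cl:
            mat[taxa.index(records[i][0]), j] = 1
    return parsimony_tree(BinaryCharacterMatrix(tuple(taxa), tuple(characters), mat))


def shared_vaf_comparison(
    vaf_a: Sequence[float], vaf_b: Sequence[float], labels: Sequence[str] = ("L", "G")
) -> dict:
    """Compare VAFs of mutations shared between two lesions (per case or
    pooled): per-lesion means and a two-sided Wilcoxon rank-sum test."""
    if len(vaf_a) == 0 or len(vaf_b) == 0:
        raise ValueError("shared-variant VAF collections must be non-empty")
    res: TestResult = wilcoxon_rank_sum(vaf_a, vaf_b, labels=labels)
    return {
        "mean_" + labels[0]: float(np.mean(vaf_a)),
        "mean_" + labels[1]: float(np.mean(vaf_b)),
        "mean_difference": float(np.mean(vaf_b) - np.mean(vaf_a)),
        "statistic": res.statistic,
        "p_value": res.p_value,
        "test": res,
    }


# ---------------------------------------------------------------------------
# maximum-likelihood concordance check (binary symmetric model)


def _topology_loglik(topology: tuple, chars: list[dict], t: float) -> float:
    """Log-likelihood under a 2-state symmetric model with one common branch
    length, via Felsenstein pruning with uniform root frequencies."""
    p_stay = 0.5 * (1.0 + np.exp(-2.0 * t))
    trans = np.array([[p_stay, 1 - p_stay], [1 - p_stay, p_stay]])
    _, labels, children = _edges_and_children(topology)

    def partial(nid, states) -> np.ndarray:
        if nid in labels:
            v = np.zeros(2)
            v[states[labels[nid]]] = 1.0
            return v
        out = np.ones(2)
        for c in children[nid]:
            out *= trans @ partial(c, states)
        return out

    return float(
        sum(np.log(max(0.5 * partial(0, c).sum(), 1e-300)) for c in chars)
    )


def ml_cross_check(matrix: BinaryCharacterMatrix) -> dict:
    """Score every topology by maximum likelihood (branch length optimized
    per topology) and report concordance with the parsimony tree.  The
    concordance is informational; it is not used to pick the reported tree."""
    topologies = enumerate_topologies(matrix.taxa)
    chars = [
        {t: int(matrix.matrix[i, j]) for i, t in enumerate(matrix.taxa)}
        for j in range(len(matrix.characters))
    ]
    logliks = []
    for topo in topologies:
        res = minimize_scalar(
            lambda t: -_topology_loglik(topo, chars, t),
            bounds=(1e-6, 10.0),
            method="bounded",
        )
        logliks.append(-res.fun)
    best_ml = topologies[int(np.argmax(logliks))]
    pt = parsimony_tree(matrix)
    concordant = pt.topology is not None and _splits_of(best_ml) == _splits_of(pt.topology)
    return {
        "ml_topology": best_ml,
        "logliks": logliks,
        "parsimony_topology": pt.topology,
        "concordant": bool(concordant),
    }
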