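"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use the most naive possible implementations
(character loops, exhaustive search) so they stay independent of the
vectorized / indexed code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def brute_dinucleotide_counts(seq: str) -> tuple[dict[str, int], int, dict[str, int]]:
    """Naive overlapping-pair count; pairs containing N skipped."""
    counts = {a + b: 0 for a in "ACGT" for b in "ACGT"}
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if "N" not in pair:
            counts[pair] += 1
    bases = {b: seq.count(b) for b in "ACGT"}
    return counts, sum(counts.values()), bases


def brute_rip_indices(seq: str):
    """(product, substrate, at_content) with None for zero denominators."""
    c, _, b = brute_dinucleotide_counts(seq)
    product = c["TA"] / c["AT"] if c["AT"] else None
    sub_den = c["AC"] + c["GT"]
    substrate = (c["CA"] + c["TG"]) / sub_den if sub_den else None
    tot = sum(b.values())
    at = (b["A"] + b["T"]) / tot if tot else None
    return product, substrate, at


def random_sequence(rng: np.random.Generator, length: int, gc: float, n_frac: float = 0.0) -> str:
    probs = [
        (1 - gc) / 2 * (1 - n_frac),
        gc / 2 * (1 - n_frac),
        gc / 2 * (1 - n_frac),
        (1 - gc) / 2 * (1 - n_frac),
        n_frac,
    ]
    return "".join(rng.choice(list("ACGTN"), size=length, p=probs))


def brute_connected_components(pairs) -> list[set[str]]:
    """Transitive closure by repeated merging (quadratic, obviously correct)."""
    comps: list[set[str]] = [set(p) for p in pairs]
    changed = True
    while changed:
        changed = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if comps[i] & comps[j]:
                    comps[i] |= comps.pop(j)
                    changed = True
                    break
            if changed:
                break
    return [c for c in comps if len(c) >= 2]


def brute_bbh(hits, genome_a: str, genome_b: str) -> set[frozenset]:
    """Exhaustive reciprocal-best search over symmetrized hit records."""
    directed = []
    for h in hits:
        directed.append((h.query_id, h.subject_id, h.query_genome, h.subject_genome, h))
        directed.append((h.subject_id, h.query_id, h.subject_genome, h.query_genome, h))

    def best(gene, from_g, to_g):
        # min over (-bitscore, evalue, -identity, id): best score, smallest id
        cands = [
            (-h.bitscore, h.evalue, -h.pct_identity, sid)
            for qid, sid, qg, sg, h in directed
            if qid == gene and qg == from_g and sg == to_g and qid != sid
        ]
        return min(cands)[3] if cands else None

    genes_a = {q for q, s, qg, sg, _ in directed if qg == genome_a}
    out = set()
    for g in genes_a:
        b = best(g, genome_a, genome_b)
        if b is not None and best(b, genome_b, genome_a) == g:
            out.add(frozenset((g, b)))
    return out


# ---------------------------------------------------------------------------
# Random additive trees for NJ checks
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree as an adjacency map with branch lengths.

    Returns (adjacency, taxa).  Built by attaching each new leaf to a random
    existing edge, so topology is uniform over attachment histories.
    """
    taxa = [f"t{i}" for i in range(n_taxa)]
    adj: dict[str, dict[str, float]] = {}
    next_internal = [0]

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def new_internal():
        next_internal[0] += 1
        return f"i{next_internal[0]}"

    def blen():
        return float(rng.uniform(0.1, 1.0))

    center = new_internal()
    for t in taxa[:3]:
        add_edge(center, t, blen())
    for t in taxa[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[int(rng.integers(len(edges)))]
        w = adj[a][b]
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8)) * w
        del adj[a][b], adj[b][a]
        add_edge(a, mid, split)
        add_edge(mid, b, w - split)
        add_edge(mid, t, blen())
    return adj, taxa


def tree_path_distances(adj, taxa) -> np.ndarray:
    """All-pairs leaf path lengths by per-source traversal."""
    n = len(taxa)
    out = np.zeros((n, n))
    for i, src in enumerate(taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node].items():
                if nxt not in dist:
                    dist[nxt] = dist[node] + w
                    stack.append(nxt)
        for j, dst in enumerate(taxa):
            out[i, j] = dist[dst]
    return out


def tree_splits(adj, taxa) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, as smaller-side leaf sets."""
    taxa_set = set(taxa)
    splits = set()
    for a in adj:
        for b in adj[a]:
            if a < b:
                # leaves reachable from a without crossing edge (a, b)
                seen = {a}
                stack = [a]
                while stack:
                    node = stack.pop()
                    for nxt in adj[node]:
                        if nxt not in seen and not (node == a and nxt == b):
                            seen.add(nxt)
                            stack.append(nxt)
                side = frozenset(seen & taxa_set)
                if 2 <= len(side) <= len(taxa) - 2:
                    splits.add(min(side, frozenset(taxa_set - side), key=sorted))
    return splits


def dendropy_tree_splits(tree) -> set[frozenset]:
    """Bipartitions of a dendropy tree in the same canonical form."""
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(min(side, frozenset(taxa - side), key=sorted))
    return splits


def dendropy_patristic(tree, taxa) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
    return out


def exact_threshold_sequence(ta=89, at=100, ca=103, ac=100) -> str:
    """A sequence whose RIP indices are exact rationals.

    Dinucleotide blocks separated by N contribute exactly one counted pair
    each (pairs containing N are skipped), so product = ta/at and
    substrate = ca/ac by construction.
    """
    blocks = ["TA"] * ta + ["AT"] * at + ["CA"] * ca + ["AC"] * ac
    return "N".join(blocks)


@pytest.fixture
def five_genome_groups() -> dict[str, str]:
    return {
        "ao": "focal",
        "pat1": "pathogen",
        "pat2": "pathogen",
        "non1": "nonpathogen",
        "non2": "nonpathogen",
    }
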