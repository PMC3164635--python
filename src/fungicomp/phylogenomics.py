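"""Single-copy ortholog selection, supermatrix concatenation, and NJ trees.

The phylogenomic workflow: from pairwise BBH ortholog sets over every genome
pair, find *universal single-copy ortholog groups* — one gene per genome,
every pair of members a BBH (a clique across genomes, which guards against
paralog chaining).  Their pre-aligned protein sequences are concatenated
into a supermatrix, pairwise p-distances are computed with pairwise deletion
of gap/ambiguous columns, and a neighbor-joining (Saitou–Nei) tree is built
with deterministic tie-breaking.

Multiple sequence alignment itself is out of scope: per-group alignments are
consumed as FASTA whose record ids are genome labels.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

from .homology import BbhPair

__all__ = [
    "OrthologGroup",
    "Supermatrix",
    "DistanceMatrix",
    "universal_single_copy_groups",
    "read_alignment_fasta",
    "concatenate_alignments",
    "p_distance_matrix",
    "neighbor_joining",
    "write_phylip",
    "read_phylip",
]

logger = logging.getLogger(__name__)

#: Characters excluded pairwise from p-distance comparisons (gaps and
#: ambiguous residues; protein alignments use X, nucleotide users may add N).
DEFAULT_IGNORE_CHARS = frozenset("-.?*X")


@dataclass(frozen=True)
class OrthologGroup:
    """One gene per genome, pairwise connected by BBH edges."""

    group_id: str
    members: Mapping[str, str]  # genome label -> gene id


@dataclass
class Supermatrix:
    """Concatenated alignment over a fixed taxon set.

    ``rows`` maps genome label → concatenated aligned sequence;
    ``group_boundaries`` maps group id → half-open column span.
    """

    taxa: list[str]
    rows: dict[str, str]
    group_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class DistanceMatrix:
    """A symmetric non-negative distance matrix with labeled taxa."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.values < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal is not zero")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


# ---------------------------------------------------------------------------
# Universal single-copy groups
# ---------------------------------------------------------------------------

def universal_single_copy_groups(
    bbh_sets: Mapping[tuple[str, str], set[BbhPair]] | Iterable[BbhPair],
    genomes: Sequence[str],
) -> list[OrthologGroup]:
    """Ortholog groups present exactly once in every genome.

    A group is a set of genes, one per genome, such that *every* pair of
    members is a BBH in its genome pair (clique criterion).  Because BBH is
    a matching within each genome pair, groups are maximal and disjoint.
    """
    genomes = sorted(genomes)
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    pairs: list[BbhPair] = []
    if isinstance(bbh_sets, Mapping):
        for s in bbh_sets.values():
            pairs.extend(s)
    else:
        pairs = list(bbh_sets)

    # partner[(genome_a, genome_b)][gene in a] = its BBH partner in b
    partner: dict[tuple[str, str], dict[str, str]] = {}
    for p in pairs:
        partner.setdefault((p.genome_a, p.genome_b), {})[p.gene_a] = p.gene_b
        partner.setdefault((p.genome_b, p.genome_a), {})[p.gene_b] = p.gene_a

    ref = genomes[0]
    groups: list[OrthologGroup] = []
    ref_genes = sorted(partner.get((ref, genomes[1]), {}))
    for gene in ref_genes:
        members = {ref: gene}
        for other in genomes[1:]:
            mate = partner.get((ref, other), {}).get(gene)
            if mate is None:
                break
            members[other] = mate
        if len(members) != len(genomes):
            continue
        # verify the clique: every non-ref pair must also be a BBH
        ok = True
        for i, ga in enumerate(genomes[1:], 1):
            for gb in genomes[i + 1 :]:
                if partner.get((ga, gb), {}).get(members[ga]) != members[gb]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            groups.append(
                OrthologGroup(group_id=f"og{len(groups) + 1:05d}", members=members)
            )
    return groups


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------

def read_alignment_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read an aligned FASTA keyed by record id (genome label)."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise ValueError(f"no records in alignment {path}")
    return rows


def concatenate_alignments(
    group_alignments: Mapping[str, Mapping[str, str]],
) -> Supermatrix:
    """Concatenate per-group alignments in sorted group-id order.

    Every group must contain every genome exactly once, with equal-length
    rows within a group; violations raise ``ValueError`` naming the group.
    """
    if not group_alignments:
        raise ValueError("no alignments supplied")
    group_ids = sorted(group_alignments)
    taxa = sorted(group_alignments[group_ids[0]])
    rows = {t: [] for t in taxa}
    boundaries: dict[str, tuple[int, int]] = {}
    offset = 0
    for gid in group_ids:
        aln = group_alignments[gid]
        missing = set(taxa) - set(aln)
        extra = set(aln) - set(taxa)
        if missing or extra:
            raise ValueError(
                f"group {gid!r}: genome set mismatch "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"group {gid!r}: ragged alignment (row lengths {sorted(lengths)})")
        (length,) = lengths
        for t in taxa:
            rows[t].append(aln[t])
        boundaries[gid] = (offset, offset + length)
        offset += length
    return Supermatrix(
        taxa=taxa,
        rows={t: "".join(parts) for t, parts in rows.items()},
        group_boundaries=boundaries,
    )


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------

def p_distance_matrix(
    supermatrix: Supermatrix,
    deletion: str = "pairwise",
    ignore_chars: frozenset[str] = DEFAULT_IGNORE_CHARS,
) -> DistanceMatrix:
    """Uncorrected p-distances (mismatches / compared columns).

    Columns containing a gap or ambiguous character in either row
    (``deletion="pairwise"``) or in any row (``deletion="complete"``) are
    excluded.  A taxon pair with zero comparable columns raises
    ``ValueError``.
    """
    taxa = supermatrix.taxa
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    arrays = {
        t: np.frombuffer(supermatrix.rows[t].encode("ascii"), dtype=np.uint8)
        for t in taxa
    }
    bad_codes = np.array([ord(c) for c in ignore_chars], dtype=np.uint8)
    masks = {t: ~np.isin(arrays[t], bad_codes) for t in taxa}
    if deletion == "complete":
        common = np.logical_and.reduce([masks[t] for t in taxa])
        masks = {t: common for t in taxa}
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = masks[taxa[i]] & masks[taxa[j]]
            n_cols = int(usable.sum())
            if n_cols == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            mism = int((arrays[taxa[i]][usable] != arrays[taxa[j]][usable]).sum())
            values[i, j] = values[j, i] = mism / n_cols
    return DistanceMatrix(taxa=list(taxa), values=values)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou–Nei neighbor joining.

    Agglomerates on the Q-criterion with deterministic tie-breaking (among
    minimal-Q pairs, the lexicographically smallest pair of cluster
    representative labels is chosen; a cluster is represented by its
    smallest leaf label).  Branch lengths come from the standard two-point
    formulas; negative estimates are clamped to zero with a logged warning.
    Returns an unrooted :class:`dendropy.Tree`.
    """
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    tns = dendropy.TaxonNamespace(sorted(dm.taxa))
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for t in dm.taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(t))
        nodes.append(nd)
        reps.append(t)
    D = dm.values.astype(float).copy()
    active = list(range(n0))
    next_index = n0
    dist: dict[tuple[int, int], float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            dist[(i, j)] = D[i, j]

    def d(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))] if i != j else 0.0

    rep_of: dict[int, str] = {i: reps[i] for i in range(n0)}
    node_of: dict[int, dendropy.Node] = {i: nodes[i] for i in range(n0)}

    def clamp(length: float, context: str) -> float:
        if length < 0:
            logger.warning("negative NJ branch length %.6g at %s clamped to 0", length, context)
            return 0.0
        return length

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best_pair: tuple[int, int] | None = None
        best_key: tuple[float, tuple[str, str]] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                label_key = tuple(sorted((rep_of[i], rep_of[j])))
                key = (q, label_key)
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair  # type: ignore[misc]
        dij = d(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, f"join({rep_of[i]},{rep_of[j]})")
        lj = clamp(lj, f"join({rep_of[i]},{rep_of[j]})")

        parent = dendropy.Node()
        parent.add_child(node_of[i])
        node_of[i].edge.length = li
        parent.add_child(node_of[j])
        node_of[j].edge.length = lj

        u = next_index
        next_index += 1
        for k in active:
            if k in (i, j):
                continue
            duk = (d(i, k) + d(j, k) - dij) / 2
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        node_of[u] = parent
        rep_of[u] = min(rep_of[i], rep_of[j])
        active = [k for k in active if k not in (i, j)] + [u]

    a, b = active
    # attach the remaining pair through the last internal node
    if node_of[a].is_leaf() and not node_of[b].is_leaf():
        a, b = b, a
    tree.seed_node = node_of[a]
    tree.seed_node.add_child(node_of[b])
    node_of[b].edge.length = clamp(d(a, b), "final join")
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# PHYLIP square-matrix I/O
# ---------------------------------------------------------------------------

def write_phylip(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write(f"{len(dm.taxa)}\n")
        for i, t in enumerate(dm.taxa):
            row = " ".join(f"{x:.9f}" for x in dm.values[i])
            handle.write(f"{t} {row}\n")


def read_phylip(path: str | os.PathLike) -> DistanceMatrix:
    with open(path) as handle:
        tokens = handle.read().split()
    n = int(tokens[0])
    taxa: list[str] = []
    values = np.zeros((n, n))
    pos = 1
    for i in range(n):
        taxa.append(tokens[pos])
        pos += 1
        for j in range(n):
            values[i, j] = float(tokens[pos])
            pos += 1
    return DistanceMatrix(taxa=taxa, values=values)
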