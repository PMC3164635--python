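"""Protein homology filtering, BBH orthology, families, and gene categories.

Input is an all-vs-all protein search result in BLAST tabular (outfmt-6)
dialect extended with query and subject lengths.  Hits pass the homology
filter when E ≤ 1e-5, identity ≥ 30%, and the alignment covers ≥ 60% of
*both* protein lengths (all bounds inclusive).  From the filtered hits:

* **BBH** (bidirectional best hit): a cross-genome gene pair where each gene
  is the other's best-scoring partner — the operational ortholog definition.
* **Families**: connected components (size ≥ 2) of the within-proteome
  homology graph under single-linkage transitive closure.
* **Categories**: each focal-genome gene is classified by where its BBH
  orthologs lie — nowhere (``specific``), only in pathogen genomes
  (``with_pathogen``), only in non-pathogen genomes (``with_nonpathogen``),
  or in both groups (``shared_both_groups``).  The four categories always
  partition the focal proteome.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HomologyHit",
    "HomologyFilter",
    "BbhPair",
    "Family",
    "CategoryAssignment",
    "CATEGORIES",
    "read_hit_table",
    "read_genome_map",
    "filter_hits",
    "filter_homologs",
    "bidirectional_best_hits",
    "single_linkage_families",
    "expand_family_by_linkage",
    "classify_categories",
    "annotate_by_reference",
]

CATEGORIES = ("specific", "with_pathogen", "shared_both_groups", "with_nonpathogen")

_OUTFMT6_COLUMNS = (
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class HomologyHit:
    """One row of the extended tabular search output."""

    query_id: str
    subject_id: str
    query_genome: str
    subject_genome: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    query_length: int
    subject_length: int


@dataclass(frozen=True)
class HomologyFilter:
    """Homology acceptance thresholds (all inclusive)."""

    max_evalue: float = 1e-5
    min_identity_pct: float = 30.0
    min_coverage_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage_fraction <= 1):
            raise ValueError("min_coverage_fraction must be in (0, 1]")

    def passes(self, hit: HomologyHit) -> bool:
        return (
            hit.evalue <= self.max_evalue
            and hit.pct_identity >= self.min_identity_pct
            and hit.aln_length >= self.min_coverage_fraction * hit.query_length
            and hit.aln_length >= self.min_coverage_fraction * hit.subject_length
        )


@dataclass(frozen=True)
class BbhPair:
    """An unordered reciprocal-best-hit gene pair across two genomes."""

    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise ValueError("BBH pair must span two distinct genomes")

    def canonical(self) -> "BbhPair":
        if (self.genome_a, self.gene_a) <= (self.genome_b, self.gene_b):
            return self
        return BbhPair(self.gene_b, self.gene_a, self.genome_b, self.genome_a)


@dataclass(frozen=True)
class Family:
    """A single-linkage multigene family (≥ 2 members)."""

    family_id: int
    member_ids: frozenset[str]


@dataclass(frozen=True)
class CategoryAssignment:
    gene_id: str
    category: str


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genome_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV mapping gene_id → genome label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "genome"], dtype=str)
    return dict(zip(df["gene_id"], df["genome"]))


def read_hit_table(
    path: str | os.PathLike,
    genome_map: Mapping[str, str],
    lengths: Mapping[str, int] | None = None,
) -> list[HomologyHit]:
    """Parse an extended outfmt-6 hit table.

    Expects 14 tab-separated columns (the 12 standard ones plus qlen, slen),
    or the 12 standard columns with protein lengths supplied separately via
    ``lengths``.  Genome labels are resolved through ``genome_map``; ids
    missing from it raise ``ValueError`` naming the id.
    """
    hits: list[HomologyHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 14):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 14 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                row = dict(zip(_OUTFMT6_COLUMNS, parts[:12]))
                qid, sid = row["query_id"], row["subject_id"]
                if len(parts) == 14:
                    qlen, slen = int(parts[12]), int(parts[13])
                elif lengths is not None:
                    qlen, slen = lengths[qid], lengths[sid]
                else:
                    raise ValueError(
                        f"{path}:{lineno}: no qlen/slen columns and no length "
                        "table supplied; provide lengths="
                    )
                for gid in (qid, sid):
                    if gid not in genome_map:
                        raise ValueError(
                            f"{path}:{lineno}: id {gid!r} absent from genome map"
                        )
                hits.append(
                    HomologyHit(
                        query_id=qid,
                        subject_id=sid,
                        query_genome=genome_map[qid],
                        subject_genome=genome_map[sid],
                        pct_identity=float(row["pct_identity"]),
                        aln_length=int(row["aln_length"]),
                        evalue=float(row["evalue"]),
                        bitscore=float(row["bitscore"]),
                        query_length=qlen,
                        subject_length=slen,
                    )
                )
            except (ValueError, KeyError) as exc:
                if isinstance(exc, ValueError) and str(exc).startswith(str(path)):
                    raise
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return hits


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Iterable[HomologyHit], filt: HomologyFilter = HomologyFilter()
) -> list[HomologyHit]:
    """Directional hits surviving the filter, self-hits removed."""
    return [h for h in hits if h.query_id != h.subject_id and filt.passes(h)]


def _hit_rank_key(hit: HomologyHit) -> tuple:
    # higher bitscore, then lower evalue, then higher identity wins
    return (-hit.bitscore, hit.evalue, -hit.pct_identity)


def filter_homologs(
    hits: Iterable[HomologyHit], filt: HomologyFilter = HomologyFilter()
) -> dict[tuple[str, str], HomologyHit]:
    """Filtered homologous pairs as unordered (sorted-id) pairs.

    Reciprocal duplicates collapse to one record, keeping the best-scoring
    presentation (bitscore, then evalue, then identity).
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for hit in filter_hits(hits, filt):
        key = tuple(sorted((hit.query_id, hit.subject_id)))
        if key not in best or _hit_rank_key(hit) < _hit_rank_key(best[key]):
            best[key] = hit
    return best


# ---------------------------------------------------------------------------
# BBH orthology
# ---------------------------------------------------------------------------

def _symmetrize(hit: HomologyHit) -> HomologyHit:
    return replace(
        hit,
        query_id=hit.subject_id,
        subject_id=hit.query_id,
        query_genome=hit.subject_genome,
        subject_genome=hit.query_genome,
        query_length=hit.subject_length,
        subject_length=hit.query_length,
    )


def bidirectional_best_hits(
    hits: Iterable[HomologyHit],
    genome_a: str,
    genome_b: str,
    filt: HomologyFilter | None = HomologyFilter(),
) -> set[BbhPair]:
    """Reciprocal best hits between two genomes.

    Each alignment record counts as evidence in both directions, so the
    result is invariant to which side was presented as the query.  A gene's
    best partner maximizes bitscore with ties broken by lower evalue, higher
    identity, then lexicographically smaller partner id.  Pass
    ``filt=None`` to rank unfiltered hits.
    """
    if genome_a == genome_b:
        raise ValueError("BBH requires two distinct genomes")
    pool = filter_hits(hits, filt) if filt is not None else [
        h for h in hits if h.query_id != h.subject_id
    ]
    best: dict[str, tuple[tuple, str]] = {}
    for h in pool:
        for d in (h, _symmetrize(h)):
            if (d.query_genome, d.subject_genome) != (genome_a, genome_b) and (
                d.query_genome,
                d.subject_genome,
            ) != (genome_b, genome_a):
                continue
            key = _hit_rank_key(d) + (d.subject_id,)
            if d.query_id not in best or key < best[d.query_id][0]:
                best[d.query_id] = (key, d.subject_id)
    genome_of: dict[str, str] = {}
    for h in pool:
        genome_of[h.query_id] = h.query_genome
        genome_of[h.subject_id] = h.subject_genome
    pairs: set[BbhPair] = set()
    for gene, (_, partner) in best.items():
        if genome_of.get(gene) != genome_a:
            continue
        if best.get(partner, (None, None))[1] == gene:
            pairs.add(
                BbhPair(gene, partner, genome_a, genome_b).canonical()
            )
    return pairs


# ---------------------------------------------------------------------------
# Single-linkage families
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def single_linkage_families(
    pairs: Iterable[tuple[str, str]],
    universe: Iterable[str] | None = None,
) -> tuple[list[Family], set[str]]:
    """Families as connected components of the homology-pair graph.

    Components of size ≥ 2 become :class:`Family` records with ids assigned
    in order of smallest member id.  Returns ``(families, singletons)``;
    singletons are genes of ``universe`` (if given) in no family.
    """
    uf = _UnionFind()
    members: set[str] = set()
    for a, b in pairs:
        uf.union(a, b)
        members.update((a, b))
    components: dict[str, set[str]] = {}
    for gene in members:
        components.setdefault(uf.find(gene), set()).add(gene)
    big = sorted(
        (c for c in components.values() if len(c) >= 2), key=lambda c: min(c)
    )
    families = [
        Family(family_id=i, member_ids=frozenset(c)) for i, c in enumerate(big, 1)
    ]
    in_family = set().union(*(f.member_ids for f in families)) if families else set()
    universe_set = set(universe) if universe is not None else members
    singletons = universe_set - in_family
    return families, singletons


def expand_family_by_linkage(
    seed_ids: Iterable[str],
    pairs: Iterable[tuple[str, str]],
    universe: Iterable[str] | None = None,
) -> set[str]:
    """Union of the connected components containing any seed id.

    A seed absent from every pair is its own (singleton) component.  With a
    ``universe`` given, seeds outside it raise ``KeyError``.
    """
    seeds = set(seed_ids)
    if universe is not None:
        unknown = seeds - set(universe)
        if unknown:
            raise KeyError(f"unknown seed id(s): {sorted(unknown)}")
    uf = _UnionFind()
    for a, b in pairs:
        uf.union(a, b)
    seed_roots = {uf.find(s) for s in seeds}
    expanded = set(seeds)
    for gene in list(uf.parent):
        if uf.find(gene) in seed_roots:
            expanded.add(gene)
    return expanded


# ---------------------------------------------------------------------------
# Four-way categories
# ---------------------------------------------------------------------------

def classify_categories(
    focal_genes: Iterable[str],
    bbh_by_genome: Mapping[str, set[BbhPair]],
    genome_groups: Mapping[str, str],
) -> list[CategoryAssignment]:
    """Assign every focal gene one of the four ortholog-distribution classes.

    ``bbh_by_genome`` maps each non-focal genome label to its BBH pair set
    against the focal genome.  ``genome_groups`` maps genome label →
    ``focal`` / ``pathogen`` / ``nonpathogen`` and must contain exactly one
    focal genome and at least one genome in each other group.
    """
    groups = dict(genome_groups)
    focal = [g for g, grp in groups.items() if grp == "focal"]
    if len(focal) != 1:
        raise ValueError("genome groups must name exactly one focal genome")
    for required in ("pathogen", "nonpathogen"):
        if required not in groups.values():
            raise ValueError(f"genome groups lack a {required} genome")
    focal_label = focal[0]

    with_pathogen: set[str] = set()
    with_nonpathogen: set[str] = set()
    for genome, pairs in bbh_by_genome.items():
        group = groups.get(genome)
        if group is None:
            raise ValueError(f"genome {genome!r} absent from group map")
        if group == "focal":
            continue
        target = with_pathogen if group == "pathogen" else with_nonpathogen
        for pair in pairs:
            if pair.genome_a == focal_label:
                target.add(pair.gene_a)
            elif pair.genome_b == focal_label:
                target.add(pair.gene_b)

    out: list[CategoryAssignment] = []
    for gene in focal_genes:
        has_p, has_n = gene in with_pathogen, gene in with_nonpathogen
        if has_p and has_n:
            cat = "shared_both_groups"
        elif has_p:
            cat = "with_pathogen"
        elif has_n:
            cat = "with_nonpathogen"
        else:
            cat = "specific"
        out.append(CategoryAssignment(gene_id=gene, category=cat))
    return out


def category_counts(assignments: Sequence[CategoryAssignment]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    return counts


# ---------------------------------------------------------------------------
# Best-hit annotation against a reference set (PHI-style)
# ---------------------------------------------------------------------------

def annotate_by_reference(
    hits: Iterable[HomologyHit],
    focal_genome: str,
    reference_genome: str,
    filt: HomologyFilter = HomologyFilter(),
) -> dict[str, HomologyHit]:
    """Best surviving reference match per focal gene.

    Hits are filtered, then for each focal-genome gene the best-scoring hit
    to the reference set is kept (bitscore, evalue, identity, then smaller
    reference id).  Genes with no surviving hit are absent from the result.
    """
    best: dict[str, HomologyHit] = {}
    for h in filter_hits(hits, filt):
        for d in (h, _symmetrize(h)):
            if d.query_genome != focal_genome or d.subject_genome != reference_genome:
                continue
            cur = best.get(d.query_id)
            if cur is None or _hit_rank_key(d) + (d.subject_id,) < _hit_rank_key(cur) + (
                cur.subject_id,
            ):
                best[d.query_id] = d
    return best
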