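"""Synthetic data generators with known ground truth.

Every downstream analysis in this package can be exercised on data produced
here: random genomes of chosen GC content, planted repeat copies subjected
to RIP-style C→T mutation at CpA context (both strands), all-vs-all protein
hit tables with planted ortholog/paralog structure and filter-violating
decoys, and replicated qPCR Ct / gel-spot intensity tables with known fold
changes and Gaussian noise.

All generators are pure functions of their arguments including a mandatory
integer seed; identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import BbhPair, HomologyHit
from .seq_features import Contig, Interval

__all__ = [
    "SimulationConfig",
    "SimulatedHomology",
    "random_genome",
    "plant_repeats",
    "simulate_rip",
    "simulate_hit_table",
    "hits_to_frame",
    "write_hit_table",
    "simulate_ct",
    "simulate_spots",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of generator settings; loadable from TOML.

    Defaults describe the standard demonstration scenario: a 100 kb random
    genome of 50% GC carrying 5 planted copies of a 2 kb repeat, RIP-mutated
    at rate 0.3; a 5-genome hit table (1 focal, 2 pathogen, 2 non-pathogen)
    with 40 focal genes; and triplicate measurement tables with 0.2-cycle /
    0.1-log noise.
    """

    seed: int
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    repeat_length: int = 2_000
    repeat_copies: int = 5
    rip_rate: float = 0.3
    genome_groups: Mapping[str, str] = field(
        default_factory=lambda: {
            "ao": "focal",
            "pat1": "pathogen",
            "pat2": "pathogen",
            "non1": "nonpathogen",
            "non2": "nonpathogen",
        }
    )
    n_focal_genes: int = 40
    family_sizes: Sequence[int] = (3, 2, 4)
    ct_noise_sd: float = 0.2
    ct_replicates: int = 3
    spot_noise_sd: float = 0.1
    spot_replicates: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must be in (0, 1)")
        if not (0 <= self.rip_rate <= 1):
            raise ValueError("rip_rate must be in [0, 1]")

    @classmethod
    def from_toml(cls, path: str) -> "SimulationConfig":
        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome_groups"] = dict(self.genome_groups)
        d["family_sizes"] = list(self.family_sizes)
        return d


# ---------------------------------------------------------------------------
# Genomes and RIP
# ---------------------------------------------------------------------------

def random_genome(
    length: int, gc_fraction: float, seed: int, contig_id: str = "sim_contig"
) -> Contig:
    """I.i.d. random genome: P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2."""
    if length < 0:
        raise ValueError("length must be non-negative")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    draws = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return Contig(id=contig_id, residues=draws.tobytes().decode("ascii"))


def plant_repeats(
    genome: Contig,
    repeat_length: int,
    copies: int,
    seed: int,
    gc_fraction: float = 0.5,
) -> tuple[Contig, list[Interval]]:
    """Overwrite ``copies`` non-overlapping windows with one master repeat.

    Returns the modified contig and the ground-truth repeat intervals
    (sorted).  Infeasible packing (too many/large copies) raises
    ``ValueError``.
    """
    if copies == 0:
        return genome, []
    if copies * repeat_length >= genome.length:
        raise ValueError("repeat copies do not fit in the genome")
    rng = np.random.default_rng(seed)
    master = random_genome(repeat_length, gc_fraction, int(rng.integers(2**31)), "master")
    positions: list[int] = []
    for _ in range(10_000):
        if len(positions) == copies:
            break
        cand = int(rng.integers(0, genome.length - repeat_length + 1))
        if all(
            cand + repeat_length <= p or p + repeat_length <= cand for p in positions
        ):
            positions.append(cand)
    if len(positions) < copies:
        raise ValueError("could not place repeat copies without overlap")
    positions.sort()
    residues = list(genome.residues)
    for pos in positions:
        residues[pos : pos + repeat_length] = master.residues
    intervals = [Interval(genome.id, p, p + repeat_length) for p in positions]
    return Contig(id=genome.id, residues="".join(residues)), intervals


def simulate_rip(
    contig: Contig,
    targets: Iterable[Interval],
    rate: float,
    seed: int,
) -> Contig:
    """RIP-style mutagenesis restricted to target intervals.

    Within each target, every forward-strand CpA has its C→T with
    probability ``rate``, and every forward-strand TpG (CpA on the reverse
    strand) has its G→A with probability ``rate``.  Sites are identified on
    the pre-mutation sequence in a single pass, so overlapping contexts do
    not cascade; bases outside targets are untouched.
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    original = contig.residues
    mutated = list(original)
    for iv in sorted(set(targets)):
        if iv.contig_id != contig.id:
            raise ValueError(f"target on {iv.contig_id!r}, not {contig.id!r}")
        if iv.end > contig.length:
            raise ValueError("target interval out of contig bounds")
        for i in range(iv.start, iv.end - 1):
            pair = original[i : i + 2]
            if pair == "CA" and rng.random() < rate:
                mutated[i] = "T"
            elif pair == "TG" and rng.random() < rate:
                mutated[i + 1] = "A"
    return Contig(id=contig.id, residues="".join(mutated))


# ---------------------------------------------------------------------------
# Hit tables with planted orthology
# ---------------------------------------------------------------------------

@dataclass
class SimulatedHomology:
    """A planted all-vs-all hit table plus its ground truth."""

    hits: list[HomologyHit]
    genome_map: dict[str, str]
    protein_lengths: dict[str, int]
    focal_genes: list[str]
    true_categories: dict[str, str]
    true_bbh: dict[tuple[str, str], set[BbhPair]]
    true_families: list[set[str]]
    true_universal_groups: list[dict[str, str]]


def _ortholog_id(genome: str, index: int) -> str:
    return f"{genome}_g{index:03d}"


def simulate_hit_table(
    genome_groups: Mapping[str, str],
    n_focal_genes: int = 40,
    family_sizes: Sequence[int] = (3, 2, 4),
    seed: int = 0,
    n_decoys: int = 12,
    n_confounders: int = 6,
) -> SimulatedHomology:
    """Plant ortholog structure across genomes and emit a realistic hit table.

    Each focal gene receives a random presence pattern over the non-focal
    genomes (cycling through the four category archetypes, then random), and
    every present pair of orthologs emits reciprocal high-scoring hits well
    above the homology thresholds.  Within the focal proteome,
    ``family_sizes`` extra paralog chains are planted (linked consecutively,
    so transitive closure is required to recover them).  ``n_decoys`` decoy
    hits each violate exactly one filter (E-value, identity, or coverage);
    ``n_confounders`` filtered-in but lower-scoring cross-group hits
    exercise best-hit selection.
    """
    rng = np.random.default_rng(seed)
    groups = dict(genome_groups)
    focal = [g for g, grp in groups.items() if grp == "focal"]
    if len(focal) != 1:
        raise ValueError("genome groups must name exactly one focal genome")
    focal_genome = focal[0]
    others = sorted(g for g in groups if g != focal_genome)
    pathogens = [g for g in others if groups[g] == "pathogen"]
    nonpathogens = [g for g in others if groups[g] == "nonpathogen"]
    if not pathogens or not nonpathogens:
        raise ValueError("need at least one pathogen and one non-pathogen genome")

    lengths: dict[str, int] = {}
    genome_map: dict[str, str] = {}
    hits: list[HomologyHit] = []
    archetypes = ["none", "pathogen", "both", "nonpathogen"]

    presence: dict[int, list[str]] = {}
    focal_genes: list[str] = []
    true_categories: dict[str, str] = {}
    for i in range(n_focal_genes):
        gene = _ortholog_id(focal_genome, i)
        focal_genes.append(gene)
        genome_map[gene] = focal_genome
        lengths[gene] = int(rng.integers(100, 500))
        arch = archetypes[i % 4] if i < 8 else archetypes[int(rng.integers(4))]
        if arch == "none":
            present: list[str] = []
        elif arch == "pathogen":
            k = int(rng.integers(1, len(pathogens) + 1))
            present = list(rng.choice(pathogens, size=k, replace=False))
        elif arch == "nonpathogen":
            k = int(rng.integers(1, len(nonpathogens) + 1))
            present = list(rng.choice(nonpathogens, size=k, replace=False))
        else:
            kp = int(rng.integers(1, len(pathogens) + 1))
            kn = int(rng.integers(1, len(nonpathogens) + 1))
            present = list(rng.choice(pathogens, size=kp, replace=False)) + list(
                rng.choice(nonpathogens, size=kn, replace=False)
            )
        presence[i] = sorted(present)
        true_categories[gene] = {
            "none": "specific",
            "pathogen": "with_pathogen",
            "nonpathogen": "with_nonpathogen",
            "both": "shared_both_groups",
        }[arch]

    def strong_hit(qid: str, sid: str, bitscore: float) -> None:
        qlen, slen = lengths[qid], lengths[sid]
        aln = max(qlen, slen)  # full mutual coverage
        ident = float(rng.uniform(70, 95))
        ev = 10.0 ** float(rng.uniform(-120, -40))
        for a, b, la, lb in ((qid, sid, qlen, slen), (sid, qid, slen, qlen)):
            hits.append(
                HomologyHit(
                    query_id=a,
                    subject_id=b,
                    query_genome=genome_map[a],
                    subject_genome=genome_map[b],
                    pct_identity=ident,
                    aln_length=aln,
                    evalue=ev,
                    bitscore=bitscore,
                    query_length=la,
                    subject_length=lb,
                )
            )

    true_bbh: dict[tuple[str, str], set[BbhPair]] = {}
    true_universal: list[dict[str, str]] = []
    for i in range(n_focal_genes):
        members = {focal_genome: _ortholog_id(focal_genome, i)}
        for g in presence[i]:
            gid = _ortholog_id(g, i)
            members[g] = gid
            genome_map[gid] = g
            lengths[gid] = lengths[members[focal_genome]]
        labels = sorted(members)
        base_score = float(rng.uniform(300, 800))
        for ai, ga in enumerate(labels):
            for gb in labels[ai + 1 :]:
                strong_hit(members[ga], members[gb], base_score)
                key = tuple(sorted((ga, gb)))
                true_bbh.setdefault(key, set()).add(
                    BbhPair(members[key[0]], members[key[1]], key[0], key[1]).canonical()
                )
        if set(labels) == set(groups):
            true_universal.append(dict(members))

    # paralog chains within the focal proteome (single-linkage families)
    true_families: list[set[str]] = []
    for fam_idx, size in enumerate(family_sizes):
        members = [f"{focal_genome}_fam{fam_idx}_m{j}" for j in range(size)]
        for m in members:
            genome_map[m] = focal_genome
            lengths[m] = int(rng.integers(150, 400))
            focal_genes.append(m)
            true_categories[m] = "specific"
        for a, b in zip(members, members[1:]):
            lengths[b] = lengths[a]  # chain partners share length for full coverage
            strong_hit(a, b, float(rng.uniform(200, 400)))
        true_families.append(set(members))

    # confounders: survive the filter but score below the true ortholog hit
    all_pairs = [
        (i, g)
        for i in range(n_focal_genes)
        for g in presence[i]
        if presence.get(i + 1) and g in presence[i + 1]
    ]
    for i, g in all_pairs[:n_confounders]:
        qid = _ortholog_id(focal_genome, i)
        sid = _ortholog_id(g, i + 1)
        aln = max(lengths[qid], lengths[sid])
        hits.append(
            HomologyHit(
                query_id=qid,
                subject_id=sid,
                query_genome=focal_genome,
                subject_genome=g,
                pct_identity=45.0,
                aln_length=aln,
                evalue=1e-20,
                bitscore=80.0,
                query_length=lengths[qid],
                subject_length=lengths[sid],
            )
        )

    # decoys: each violates exactly one filter
    gene_ids = sorted(genome_map)
    for d in range(n_decoys):
        qid, sid = rng.choice(gene_ids, size=2, replace=False)
        qid, sid = str(qid), str(sid)
        mode = ("evalue", "identity", "coverage")[d % 3]
        aln = max(lengths[qid], lengths[sid])
        ident, ev = 60.0, 1e-30
        if mode == "evalue":
            ev = 1e-3
        elif mode == "identity":
            ident = 20.0
        else:
            aln = int(0.5 * min(lengths[qid], lengths[sid]))
        hits.append(
            HomologyHit(
                query_id=qid,
                subject_id=sid,
                query_genome=genome_map[qid],
                subject_genome=genome_map[sid],
                pct_identity=ident,
                aln_length=max(aln, 1),
                evalue=ev,
                bitscore=float(rng.uniform(40, 60)),
                query_length=lengths[qid],
                subject_length=lengths[sid],
            )
        )

    return SimulatedHomology(
        hits=hits,
        genome_map=genome_map,
        protein_lengths=lengths,
        focal_genes=sorted(focal_genes),
        true_categories=true_categories,
        true_bbh=true_bbh,
        true_families=true_families,
        true_universal_groups=true_universal,
    )


def hits_to_frame(hits: Iterable[HomologyHit]) -> pd.DataFrame:
    """Hits as a 14-column extended outfmt-6 table (dummy coordinate columns)."""
    rows = []
    for h in hits:
        rows.append(
            (
                h.query_id,
                h.subject_id,
                h.pct_identity,
                h.aln_length,
                0,
                0,
                1,
                h.aln_length,
                1,
                h.aln_length,
                h.evalue,
                h.bitscore,
                h.query_length,
                h.subject_length,
            )
        )
    return pd.DataFrame(rows)


def write_hit_table(hits: Iterable[HomologyHit], path: str) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Ct and spot tables
# ---------------------------------------------------------------------------

def simulate_ct(
    true_fold: float,
    replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    target_gene: str = "target",
    control_gene: str = "18S",
    base_target_ct: float = 24.0,
    control_gene_ct: float = 15.0,
) -> pd.DataFrame:
    """Replicated Ct table with a planted fold change.

    Construction inverts the 2^(−ΔΔCt) formula: the treatment target Ct is
    lowered by log2(fold) relative to the control condition while the
    control gene is flat, so at ``noise_sd=0`` the computed fold equals
    ``true_fold`` exactly.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    means = {
        (target_gene, "control"): base_target_ct,
        (target_gene, "treatment"): base_target_ct - float(np.log2(true_fold)),
        (control_gene, "control"): control_gene_ct,
        (control_gene, "treatment"): control_gene_ct,
    }
    rows = []
    for (gene, condition), mean in means.items():
        for rep in range(1, replicates + 1):
            ct = mean + rng.normal(0.0, noise_sd) if noise_sd > 0 else mean
            rows.append({"id": gene, "condition": condition, "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)


def simulate_spots(
    n_spots: int,
    planted_folds: Mapping[str, float] | None = None,
    noise_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Replicated spot-intensity table with planted fold changes.

    Spots are named ``spot001``…; ``planted_folds`` maps spot names to their
    true treatment/control intensity ratio (all others have fold 1).
    Intensities are log-normal around condition means (``noise_sd`` on the
    natural-log scale).  Returns the table and the full truth map.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    planted = dict(planted_folds or {})
    truth: dict[str, float] = {}
    rows = []
    for i in range(1, n_spots + 1):
        spot = f"spot{i:03d}"
        fold = float(planted.get(spot, 1.0))
        truth[spot] = fold
        base = float(rng.uniform(500, 5000))
        for condition, mean in (("control", base), ("treatment", base * fold)):
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "id": spot,
                        "condition": condition,
                        "replicate": rep,
                        "intensity": mean * float(np.exp(noise)),
                    }
                )
    return pd.DataFrame(rows), truth
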