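# Methods

## RIP index scanning

Dinucleotides are counted as overlapping pairs read left to right; any pair
containing N is excluded from every numerator and denominator (positions
still advance by one), so assembly gaps near a window do not bias the
ratios. The two indices are

- product index `TpA/ApT`, and
- substrate index `(CpA+TpG)/(ApC+GpT)`,

with AT content computed over unambiguous bases only. Both index numerator
and denominator sets are closed under reverse complementation
(TA↔TA, AT↔AT, {CA,TG}↔{CA,TG}, {AC,GT}↔{AC,GT}), so the scan is
strand-agnostic and gene/repeat strand is ignored throughout.

A ratio whose denominator is zero is carried as an explicit *undefined*
(`None`), never as 0 or ∞, and an undefined index can never satisfy a
threshold: a 0/0 window is evidence of nothing.

Sliding windows start at 0, shift, 2·shift, …, and only full-length windows
are scored — index variance explodes on short trailing fragments, and fixed
window sizes keep windows comparable. Defaults are 200 bp windows with
100 bp shifts for RIP calling (thresholds product ≥ 0.89, substrate ≤ 1.03,
both inclusive at the printed boundary), with a 500/100 setting additionally
reported in the per-class summary. The RIP-positive *fraction* of a
sequence is, by default, the number of bases covered by the union of
positive windows divided by total length (windows overlap, so this is not
the positive-window rate; that alternative is exposed via `mode="windows"`).
Per-genome aggregation sums covered bases over contigs before dividing, so
long contigs carry proportionally more weight.

Per-feature-class summaries extract each class's intervals and pool
dinucleotide *counts* across the extracted sequences rather than
concatenating the sequences, so no artificial junction dinucleotides are
created; windows are scanned within each interval independently and
re-anchored to parent-contig coordinates. "Coding" means CDS (not whole
transcripts) and "non-coding" means intergenic (complement of gene spans) —
introns are tracked as their own class, which only makes sense if
non-coding excludes them. Both choices are flagged here because annotation
conventions vary.

Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted at the boundary and BED passes through unshifted.

## Homology, orthology, families, categories

The homology filter keeps a hit iff E ≤ 1e-5, identity ≥ 30%, and the
reported alignment length covers ≥ 60% of both protein lengths. Coverage
uses the outfmt-6 alignment length (including gap columns) — the
reproducible choice given only tabular output. All bounds are inclusive.

Best hits maximize bitscore with ties broken by lower E-value, higher
identity, then lexicographically smaller partner id, so output is
deterministic across hash orders and input row order. Every alignment
record is treated as evidence in both directions, making BBH output
invariant to which side was the query. BBH pairs are the operational
ortholog definition; category assignment deliberately uses BBHs, not the
looser homology relation.

Families are connected components of the filtered within-proteome pair
graph (union-find), size ≥ 2; singletons are reported separately. Family
ids are assigned in order of smallest member id. Seed-set expansion
(`expand_family_by_linkage`) returns the union of components touching any
seed.

The four-way categorization is a partition by construction: a focal gene
with BBHs in ≥ 1 pathogen and ≥ 1 non-pathogen genome is `shared_both_groups`
("found in all genomes" is read as both groups represented, the only
reading under which the four categories partition the proteome); with only
one side, `with_pathogen`/`with_nonpathogen`; with neither, `specific`.

Reference annotation (e.g. against a pathogen-host-interaction gene set) is
the same filter followed by best-hit selection per focal gene.

## Phylogenomics

Universal single-copy groups use the BBH *clique* criterion: one gene per
genome with every pair a BBH. Since BBH is a matching within each genome
pair, groups are maximal and disjoint; the clique requirement (rather than
connected components) guards against paralog chaining. A relaxed
component-based mode is deliberately not the default.

Alignment is consumed, not produced: per-group aligned FASTAs keyed by
genome label are concatenated in sorted group-id order with recorded column
spans. p-distances use pairwise deletion of columns containing a gap or
ambiguity character (`-.?*X` by default; nucleotide users may add `N`);
complete deletion is available. A taxon pair with zero comparable columns
is an error rather than a silent 0.

Neighbor joining is the classic Saitou–Nei agglomeration on the
Q-criterion. Ties on Q are broken by the lexicographically smallest pair of
cluster representative labels (a cluster is represented by its smallest
leaf label), making output deterministic even on degenerate equidistant
input. Branch lengths come from the standard two-point formulas; negative
estimates — a normal consequence of distance noise — are clamped to zero
with a logged warning. Trees are dendropy objects, so Newick round-trips
are exact. Model-corrected distances (Poisson/JTT) are out of scope;
p-distance is the documented extension point.

## Expression quantification

ΔΔCt is computed on replicate-mean Cts (the form the instrument manual
writes); a per-replicate paired mode is available and agrees exactly on
balanced designs. Fold = 2^(−ΔΔCt). Swapping condition labels yields the
exact reciprocal; adding a constant to all Cts of one condition (target and
control gene alike) cancels — the control-gene normalization property.

Differential spots: fold = mean(treatment)/mean(control); significance from
a two-sided Welch (unequal-variance) t-test on natural-log intensities —
the underlying test is unstated in typical 2-D gel reports, so this is an
explicit, parameterized choice. Thresholds default to fold ≥ 1.5 (or
≤ 1/1.5) and raw P < 0.05 with no multiple-testing correction, mirroring
common proteomics practice; Benjamini–Hochberg adjustment is available
behind a flag. Degenerate zero-variance comparisons short-circuit (P = 0
when means differ, 1 otherwise) rather than emitting NaNs.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated:

- **Genomes**: i.i.d. residues at a chosen GC fraction; default scenario
  100 kb at GC 0.5.
- **Repeats**: one master sequence overwritten at 5 non-overlapping
  positions, 2 kb each — enough fully-interior 200 bp windows per copy for
  stable rate estimates.
- **RIP mutagenesis**: single pass over the pre-mutation sequence; each
  forward-strand CpA has C→T and each TpG (CpA on the reverse strand) has
  G→A with probability r (rates 0.1–0.5 exercised; 0.3 default). Reading
  the pre-mutation sequence means overlapping contexts cannot cascade
  within a pass. Only the strongest RIP context is modeled — exactly what
  the substrate index measures — with no iteration over sexual cycles and
  no indels or transposon structure.
- **Hit tables**: 5 genomes (1 focal, 2 pathogen, 2 non-pathogen), 40 focal
  genes whose presence patterns cycle through the four category archetypes
  before randomizing, orthologs emitted as reciprocal hits far above all
  thresholds (identity 70–95%, E ≤ 1e-40, full mutual coverage); paralog
  chains planted within the focal proteome so that family recovery requires
  transitive closure; decoys each violate exactly one filter (E-value,
  identity, or coverage) to unit-test each branch; confounder hits survive
  the filter at low bitscore to exercise best-hit selection.
- **Measurement tables**: Ct construction inverts the 2^(−ΔΔCt) formula so
  a noise-free table round-trips the planted fold (5.9 and 23.4 — the
  protease-induction magnitudes the pipeline is designed to quantify — are
  used as canonical values); spot intensities are log-normal around
  condition means with 0.1 log-noise, 10 of 100 spots planted at 4-fold.

All generators are pure functions of their arguments including a mandatory
seed. What passing recovery tests on these data do **not** show: behavior
on real genomes with compositional heterogeneity, repeat families of
varying age, partial RIP, fragmentary alignments, or proteome-scale hit
tables with promiscuous domains — the synthetic decoy/confounder structure
is far cleaner than real BLAST output. Notably, on i.i.d. 50%-GC sequence
the 0.89/1.03 thresholds flag ≈ 48% of windows; the validated signal is the
repeat-versus-background contrast, not the absolute background rate.

## Problem sizes

The test suite and the acceptance script run on deliberately modest sizes
chosen to estimate each quantity stably: 100 kb genomes (≈ 1,000 windows;
10–20 seeded replicates), 5-genome / ~50-protein hit tables (5 seeds),
100 random additive matrices of 4–8 taxa, 100-spot tables. All recoveries
asserted are exact at these sizes, so larger instances would add runtime,
not information, for the structural guarantees being checked.

## Known limitations

- RIP detection is composition-based only; no alignment-based (RIPCAL-style)
  comparison of repeat copies to a consensus.
- Orthology is pairwise BBH; no graph-clustering orthogroups (MCL etc.).
- NJ only; likelihood/parsimony tree inference and bootstrap support are
  delegated to external tools.
- qPCR assumes perfect amplification efficiency (the textbook 2^(−ΔΔCt)
  model); no standard-curve correction.
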