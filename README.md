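# fungicomp

Comparative-genomics toolkit built around the analyses used to characterize
nematode-trapping fungi such as *Arthrobotrys oligospora*: detection of
repeat-induced point mutation (RIP) relics, reciprocal-best-hit orthology
with pathogen/non-pathogen gene categorization, single-linkage multigene
families, concatenated single-copy-ortholog neighbor-joining phylogenomics,
and qPCR / 2-D gel quantification. Every stage can be exercised on synthetic
data with known ground truth, generated in-package.

## The statistics at the core

**RIP indices.** RIP is a fungal genome-defense process that mutates C→T in
duplicated sequences, preferentially at CpA dinucleotides (TpG on the
reverse strand). It leaves relics detectable from dinucleotide composition:

- product index = TpA/ApT — elevated by RIP (CpA→TpA creates TpA),
- substrate index = (CpA+TpG)/(ApC+GpT) — depleted by RIP.

Sequences are scanned in sliding windows (defaults 200 bp / 100 bp shift; a
500/100 setting is used for summaries); a window is RIP-positive when
product ≥ 0.89 **and** substrate ≤ 1.03 (inclusive). Both indices are
reverse-complement symmetric, so scanning is strand-agnostic. Pairs
containing N are excluded from numerator and denominator; a ratio with zero
denominator is *undefined* and can never satisfy a threshold.

**Orthology.** All-vs-all protein hits (BLAST outfmt-6 plus qlen/slen) are
filtered at E ≤ 1e-5, identity ≥ 30%, alignment covering ≥ 60% of *both*
proteins. Orthologs are bidirectional best hits (BBH); multigene families
are connected components (≥ 2 members) of the within-proteome homology graph
under single-linkage transitive closure; each focal-genome gene is
categorized by where its BBH orthologs lie (nowhere / pathogen genomes only
/ both groups / non-pathogen genomes only — always a partition of the
proteome).

**Phylogenomics.** Universal single-copy ortholog groups are BBH *cliques*
with exactly one gene per genome; their pre-computed alignments are
concatenated into a supermatrix, pairwise p-distances are taken with
pairwise deletion, and a Saitou–Nei neighbor-joining tree is built with
deterministic tie-breaking.

**Quantification.** qPCR fold change = 2^(−ΔΔCt) with
ΔCt = Ct(target) − Ct(18S control) and ΔΔCt = ΔCt(treatment) − ΔCt(control).
Gel spots are called up/down at fold ≥ 1.5 (or ≤ 1/1.5) with Welch-test
P < 0.05 on log intensities.

## Worked example

Simulate a 100 kb genome (GC 0.5) carrying five 2 kb repeat copies
RIP-mutagenized at rate 0.3, then scan it:

```bash
$ fungicomp simulate --preset rip-demo --seed 7 --out demo
wrote 2 file(s) to demo
$ fungicomp rip-scan demo/genome.fasta --out demo/scan
999 windows, RIP-positive base fraction 0.6690
```

`demo/scan/rip_windows.tsv` holds per-window AT content, both indices, and
the positive flag; the mutated repeat copies flag at a far higher rate than
background (on i.i.d. 50%-GC sequence the thresholds are permissive, so the
background itself sits near 0.48 — the signal is the contrast, which the
test suite asserts across seeds).

Quantify a planted 5.9-fold induction from a noisy triplicate Ct table:

```bash
$ fungicomp qpcr demo/ct.tsv --target target --out demo/qpcr
target: ddCt=-2.673 fold=6.377
```

i.e. the target amplifies 2.67 cycles earlier (relative to 18S) after
treatment, an estimated 6.4-fold induction — consistent with the planted
5.9-fold given 0.2-cycle Gaussian noise on each Ct.

The same operations are available as library calls
(`fungicomp.rip_scan.scan_windows`, `fungicomp.homology.bidirectional_best_hits`,
`fungicomp.phylogenomics.neighbor_joining`,
`fungicomp.expression.ddct_fold_change`, …).

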