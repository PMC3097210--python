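# Methods

This note documents the models, heuristics and numerical choices behind
`chitfam`, what the synthetic benchmark does and does not demonstrate, and
the design decisions taken where the published description of the analysis
left the procedure open.

## Candidate screening

A protein is a candidate chitinase/chitinase-like family member when it
carries at least one of the four GH18 catalytic-domain signatures
(`FDGXDLDWEYP`, `KXXXXXGGW`, `MXYDXXG`, `GXXXWXXDXD`). `X` is a wildcard
over the 20 standard residues and also matches an `X` in the sequence;
fixed pattern positions must match exactly and are never satisfied by a
sequence `X` (conservative in both directions). All overlapping matches are
reported, 1-based, sorted by position then motif name.

The screen's "and/or" between the primary signature and the other three is
resolved as an inclusive OR with evidence tiers: *primary* requires the
full `FDGXDLDWEYP` (catalytic E intact), *secondary* covers proteins
matching only the remaining signatures **or** only a relaxed `DW?YP` site.
The relaxed site exists so that catalytically dead chitinase-like proteins
(IDGFs), whose catalytic glutamate is substituted and which therefore fail
the primary signature as printed, are still detected and flagged
`substituted` rather than discarded. A `DW?YP` window with E at the center
anywhere in the sequence yields `active`; windows exist but none with E
yields `substituted`; no window yields `absent`. Whole sequences are
screened; co-occurrence of signatures within one domain is not required
(the source analysis does not state such a constraint).

## Domain architecture

**Catalytic (GH18) domains.** Signature hits are single-linkage clustered:
a hit starting more than G = 250 residues after the running cluster's end
opens a new cluster. Each cluster becomes one domain spanning
[first hit − 60, last hit end + 150], clipped to the protein and merged if
extents collide. The margins and gap are free parameters with no published
boundary truth behind them; the defaults separate tandem multi-domain
architectures (2-, 2- and 4-catalytic-domain proteins exist in the mosquito
family) while keeping the four signatures of one domain in one cluster.

**Chitin-binding domains.** ChtBD2/peritrophin-A domains are detected by
their six-cysteine spacing C-X(8..25)-C-X(5..6)-C-X(9..19)-C-X(10..16)-
C-X(4..14)-C (ranges configurable). The chain is extended greedily,
shortest compliant gap first, and overlapping candidates are resolved
leftmost-first. The published analysis names the ChtBD2 family but no
pattern; these ranges follow the peritrophin-A consensus.

**Signal peptides and transmembrane segments** are transparent
Kyte–Doolittle hydropathy heuristics, *not* SignalP/TMHMM
re-implementations: a signal requires an initial M plus a 9-residue window
within the first 30 residues with mean hydropathy ≥ 1.6 (annotation spans
residue 1 to window end + 5); TM segments are merged maximal runs of
19-residue windows with mean ≥ 1.8, suppressed when they overlap a called
signal. Real-sequence signal/TM counts are deliberately not benchmarked —
the original predictions themselves carried SignalP caveats — and these
callers are validated only on the synthetic generator, where the truth is
planted. Proteins shorter than 25 residues return "no signal" rather than
erroring, so architecture summaries work on arbitrary inputs.

## Alignment and phylogeny

Pairwise global alignment uses BLOSUM62 with affine gaps (open −10,
extend −1; a length-k gap costs open + (k−1)·extend). Residues outside the
matrix alphabet score 0 against everything. The multiple aligner is
progressive: a UPGMA (average-linkage) guide tree on pairwise p-distances,
then profile–profile Gotoh alignment under average sum-of-pairs scoring in
guide-tree merge order. No iterative refinement is attempted: the
classification target is group-level membership, which is robust to
alignment detail; node-by-node reproduction of any particular published
tree is explicitly not claimed.

Distances use pairwise deletion (columns gapped in either row of a pair are
skipped for that pair); p is the mismatch proportion and the default model
is the Poisson correction d = −ln(1−p). Pairwise deletion keeps short
domains informative; saturated pairs (p = 1) are an error under the Poisson
model rather than silently truncated.

Neighbor joining is the Saitou–Nei algorithm: join the pair minimizing
Q(i,j) = (n−2)·d(i,j) − Σd(i,·) − Σd(j,·), branch lengths
l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2)), distance update
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2, terminating in a trifurcating root with
closed-form lengths. Negative branch lengths are clamped to 0 with the raw
value retained on the node (`raw_length`). Q-ties are broken by the
lexicographically smallest pair of cluster labels (a cluster is labeled by
its smallest leaf name), which makes the output invariant to input taxon
order. On additive matrices the algorithm provably recovers the generating
tree; the test suite checks this against an exhaustive-topology
least-squares oracle for n ≤ 6 and against an independent NJ
implementation.

Bootstrap supports resample alignment columns with replacement (gapped
columns included), rebuild the tree per replicate, and report the
percentage of replicates containing each internal bipartition of the
full-data tree. Replicates whose resampled matrix is undefined (a pair
left with no comparable sites) are skipped with the denominator reduced.
Tests default to 100 replicates; 5000 is supported to mirror
publication-scale analyses. All randomness is seeded.

**Group assignment.** Queries and labeled anchors (all eight groups
required) are jointly aligned and placed on one NJ tree. A query takes the
group of the anchor set whose smallest enclosing clade (LCA of that
group's anchors) contains it; the smallest containing clade wins, ties go
to the lower group numeral, and queries contained in no proper anchor
clade fall back to the nearest anchor by patristic distance. The reported
support is the patristic distance to the nearest anchor of the assigned
group.

## Genome structure

Coordinates are 1-based inclusive throughout (genome-browser locus strings
such as `chr2R:21,584,333–21,587,318` parse to arm/start/end; both en-dash
and hyphen are accepted and commas stripped). Gene models hold sorted,
non-overlapping exons; introns are the inter-exon gaps, so n_introns =
n_exons − 1. Tandem clusters chain genes on one arm whose intergenic gap
(next.start − prev.end − 1) is at most the threshold; 20 kb by default,
chosen because the known five-gene chitinase-5 cluster spans ~14 kb in
total while the next-nearest genes sit far beyond. Everything is
strand-agnostic: the published locus table carries no strand.

## qPCR statistics

Primer efficiency comes from the least-squares slope m of Ct against
log10(input): E = 10^(−1/m) − 1, accepted at E ≥ 0.9 (perfect doubling is
m = −3.3219, E = 1). Relative expression follows 2^−ΔΔCt: technical
replicates are averaged to one Ct upstream; biological replicates are
carried into the ANOVA. In *normalized* mode ΔCt = Ct_target − Ct_reference
per sample and ΔΔCt subtracts the calibrator's ΔCt; the REV
(relative expression value) 2^−ΔCt is the target/reference quantity ratio.
The *total_rna* mode computes ΔΔCt from target Ct alone against the
calibrator, for stage series where no reference gene is stable and input
RNA is standardized by quantification instead — the calibrator sample is a
required user input since the published analysis does not state one.

Letter displays: arcsine-square-root requires proportions, so values are
rescaled by the per-set maximum before transform (the source applies the
transform to relative expression without stating a rescaling — this choice
is flagged here deliberately). One-way ANOVA supplies the pooled error
term; pairwise Fisher's LSD at α = 0.05 uses
t_{1−α/2,dfE}·sqrt(MSE·(1/n_i + 1/n_j)); the compact letter display is the
insert-and-absorb construction, so sharing a letter is exactly pairwise
non-significance. Zero within-group variance degenerates to comparing
means directly.

## Synthetic generator

The generator emits the structures the pipeline consumes with a complete
truth manifest: a 200-residue ancestral catalytic domain with the four
signatures planted at fixed offsets; group ancestors evolved from it at
0.30 expected substitutions/site and members at 0.05 by default (the
benchmark family is 8 groups × 3 members); proteins assembled per
architecture plans that mirror the real family's layouts (including a
4-catalytic/4-CBD giant and a 2-TM membrane-anchored form); gene models
with exon counts up to 19 and intron sizes 80–2200 bp, including a
five-gene tandem cluster; and Ct tables generated as
Ct = baseline − log2(fold)/log2(1+E) + N(0, σ).

Substitutions are i.i.d. per site, drawn uniformly from a
hydropathy-neutral, C- and M-free residue pool, with signature non-X
positions protected (so the motif channel stays a valid truth signal unless
`ablate_motifs` deliberately substitutes the catalytic E). This is
documented as non-biological: no rate matrix, no indels beyond alignment
tests, no compositional realism. Passing the recovery benchmarks therefore
shows the *algorithms* are correct against a known truth — it does not
certify performance on real proteomes, where domain boundaries, hydropathy
signals and alignment difficulty are all harsher. Identical seeds give
byte-identical output.

## Problem sizes

The shipped benchmarks use desk-scale sizes chosen as the package's
standard configurations: 24-sequence families (8 × 3) plus 8 anchors for
the end-to-end recovery run, a 20-member catalogue-shaped family for the
classification check, 100 random additive matrices (n ≤ 6) for the NJ
oracle, 1000 fuzzed sequences for the motif oracle, and 100-replicate
bootstraps in tests.

## Known limitations

- The progressive aligner is a baseline (no iterative refinement, no
  position-specific gap penalties); it is sufficient for group-level
  classification of conserved catalytic domains, not a ClustalW/MAFFT
  replacement.
- Signal/TM heuristics trade sensitivity for transparency; they are
  benchmark instruments, not annotation tools.
- Catalytic-domain boundaries are motif-anchored extents, not structural
  domain boundaries.
- The group assignment depends on anchor quality; paraphyletic anchor sets
  degrade to the nearest-anchor fallback.
- Bootstrap values of any particular published tree are not reproducible
  (the underlying alignment and distance model are not published) and are
  not targeted.
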