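# Methods

This note documents the models and procedures implemented in `pcfam`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not demonstrate about real data.

## Architecture typing

A protein's architecture is resolved to the 4-tuple
(has_sp, pcld_count, has_alr, has_gas) and looked up in a total decision
table over all 2×3×2×2 = 24 tuples. The anchor assignments are: type I =
(SP, 1 PCLD, ALR, GAS); II = I without the GAS; V = any 3-PCLD protein;
VI/VII = single-PCLD proteins with an SP but no ALR (VII keeps the GAS);
VIII = (SP, 2 PCLDs, no ALR); III/IV = 2-PCLD proteins with an ALR (IV
lacks the GAS); IX and X = the SP-less types with 1 and 2 PCLDs
respectively. The III/IV/X and VI/IX boundaries are not fully constrained
by the published verbal descriptions, so the table is a constructor
argument: callers can swap in their own mapping without touching the
classifier. Proteins with zero or more than three PCLDs are labelled
`unclassified` rather than being forced into a nearest type.

Upstream predictions (secretion signal, GPI-anchor signal, domain spans)
are consumed from a feature table, never recomputed: signal-peptide and
GPI predictors are heavyweight models in their own right and reimplementing
them would add unverifiable behaviour. Only the synthetic generator
fabricates these flags.

ALR detection slides a 10-residue window and keeps windows with ≥50%
P/A/S/T, merging overlapping or adjacent qualifying windows into maximal
intervals. AG glycomodules are counted as non-overlapping occurrences of
the dipeptides {AP, PA, SP, TP, GP, VP} inside an ALR, with ≥2 needed to
qualify; all four parameters are configurable since published criteria for
these motifs vary between studies.

## Ka/Ks: Nei–Gojobori with Jukes–Cantor correction

Site counting assigns each codon position s = (synonymous changes)/3
synonymous sites. Mutations creating a stop codon count toward neither
class by default, so S+N falls short of 3×(codons) by the excluded
fraction; setting `stop_policy="nonsynonymous"` restores the
classic "everything non-synonymous" convention. Multi-hit codons average
Sd/Nd over all shortest substitution pathways; pathways passing through a
stop are excluded, and in the (rare) case where every pathway is blocked
the average falls back to all orderings with the stop steps counted as
nonsynonymous. Proportions pS = Sd/S and pN = Nd/N are corrected with
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 sets a saturation flag and leaves the
corrected rate undefined instead of reporting a number.

The counting method was chosen over maximum-likelihood (GY94-style)
estimation because the downstream uses — dating and a coarse
purifying/positive call — only need a consistent pairwise estimate, and
the counting estimator admits an exact brute-force oracle (exhaustive
neighbor and pathway enumeration) that the test suite runs on hundreds of
short alignments.

## Dating and selection

T = Ks/(2λ) converts synonymous divergence into time since duplication
under a molecular clock; λ defaults to 1.5×10⁻⁸ (Arabidopsis) and
6.5×10⁻⁹ (maize) synonymous substitutions per site per year. Ages are
rounded half-up to two decimals for reporting. Saturated Ks values are
never dated. Selection calls are purifying (Ka/Ks < 1), positive (> 1) or
neutral (equal within 10⁻⁹); pairs with Ks = 0 are left unclassified since
the ratio is undefined.

## Mechanism classification

Classification is a strict precedence partition:

1. **tandem** — both genes in one single-linkage cluster of family genes
   on the same chromosome with ≤ `max_intervening` (default 5) non-family
   genes between consecutive members;
2. **segmental** — the pair is an anchor of, or falls within the ordinal
   span of, a collinear block: blocks are greedy monotone chains of
   within-genome paralog anchors with per-step ordinal gaps ≤20 on both
   chromosomes and ≥3 anchors;
3. **retrotransposition** — any remaining dispersed pair. Intron
   presence/absence is recorded as supporting evidence (exactly one
   intronless member is the classic retrogene signature) but is not
   required, since intron loss can also occur by other routes.

The window and chaining defaults are package choices — the published
analyses used interactive synteny browsers whose thresholds are not
stated — and all are exposed in the API and CLI. Gene ordinals count all
genes of the genome (not just family members) because "intervening genes"
is only meaningful against the full gene complement.

## Trees and reconciliation

Protein distances are p-distances over shared non-gap columns, corrected
with Kimura's approximation d = −ln(1 − p − p²/5); pairs beyond the
correction's domain give ∞ and are rejected by the joiner. Neighbor
joining follows Saitou–Nei with the standard Q criterion; ties are broken
toward the lowest-index pair (taxa in sorted order), and negative branch
lengths are clamped to zero with the deficit moved to the sibling branch.
Bootstrap replicate r resamples columns with a generator seeded
`seed + r`, making runs reproducible and taxon-order invariant; replicate
distance matrices pushed past saturation are capped at twice the largest
finite distance in that replicate rather than discarded, which keeps the
replicate count honest at the cost of slightly conservative support on
near-saturated data.

Reconciliation uses LCA mapping on rooted trees: M(leaf) is the species
of the gene; M(g) is the LCA of the children's images; g is a duplication
iff M(g) equals the image of one of its children. Losses follow the
standard duplication–loss parsimony count (per gene edge,
depth(M(child)) − depth(M(parent)), minus one for speciation parents) and
are placed on the species branches skipped along each path. Ancestral
copy number at species node s counts gene lineages entering the
divergence at s, with duplications mapped to s treated as preceding the
divergence — this convention makes leaf counts equal observed per-species
gene numbers. The test suite verifies the LCA totals against a
brute-force minimum over *all* valid mappings, exhaustively for every
gene-tree topology up to 4 leaves on 3- and 4-taxon species trees and on
a seeded sample of 5–6-leaf trees; the fully exhaustive 6-leaf space is
astronomically larger with no additional structural coverage, so the
sampled check is the package's chosen problem size.

Gene-tree rooting for reconciliation is the caller's responsibility
(simulated trees are rooted by construction); no rearrangement of
weakly-supported edges is attempted.

## Retrogene donor inference

Within a rooted clade, maximal subclades whose leaves all lack the
conserved intron are labelled retroposition events. The donor for each is
the intron-bearing gene nearest the subclade stem, walking rootward and
taking the lexicographically smallest id on ties; a clade with no
intron-bearing member yields no call rather than a guess. When a retro
clade's members also sit in one tandem cluster the internal expansion is
additionally marked as tandem. An intron-bearing gene can never be
labelled a retrocopy.

## Expression and qPCR

Microarray matrices are normalized gene-wise, by z-score by default
((x − row mean)/row sd, population sd so the operation is idempotent);
min–max scaling is available since the normalization used by interactive
expression browsers is often unspecified. Constant rows are zeroed and
flagged. ΔCt is computed per replicate (target − reference within the
same replicate), so any per-replicate additive shift in Ct cancels
exactly; ΔΔCt subtracts the calibrator-condition mean and RQ = 2^−ΔΔCt.
Significance uses a two-sided Welch t-test on the replicate ΔCt values
against the calibrator (the published figures star differences without
naming a test; Welch is the conservative default), with stars at 0.05 and
0.01, and a zero-variance fallback to exact mean equality.

## Synthetic data generator

Families evolve by a birth–death process (defaults: birth 0.25, loss 0.05
per lineage per time unit) along a fixed ultrametric 10-taxon species
tree of depth 3 time units whose internal nodes carry the labels V, E, T,
A, G, Eu, R; the topology mirrors the accepted plant phylogeny (algae
basal, then moss, lycophyte, and angiosperms split into grasses and
eudicots with a rosid clade) and branch lengths are arbitrary fixed
values, since no calibrated lengths are required by any consumer. Each
birth is tagged tandem/segmental/retro with probabilities 0.15/0.40/0.45,
approximating the relative frequencies reported for dated paralog pairs
in the family. Retrocopies and their descendants lose the conserved
phase-1 intron.

Sequence divergence uses direct substitution placement rather than a
continuous-time codon model: target Ks is converted to an expected
proportion of synonymous differences through the Jukes–Cantor inverse,
a Poisson-distributed number of single-nucleotide synonymous (and,
scaled by the target Ka/Ks, nonsynonymous) changes is placed one per
codon, and stops are never created. Realized change counts are therefore
exact truth. The genome layout realizes each mechanism geometrically:
tandem copies at adjacent ordinals, segmental copies on a fresh
chromosome wrapped in a 3-anchor collinear block, retrocopies spaced 50
ordinals apart on a scatter chromosome, with filler genes occupying every
other ordinal. qPCR tables place ΔΔCt = −log₂(RQ) in expectation with
independent Gaussian noise (default sd 0.15 cycles, 3 replicates,
conditions control/salt/drought).

What this does *not* emulate: alignment error, rate variation among
sites and lineages, gene conversion between paralogs, overlapping or
nested duplication geometries, incomplete genome assemblies, and probe
cross-hybridization. Passing recovery tests therefore demonstrate
correctness of the inference machinery under its own model assumptions,
not robustness to these real-data complications.

## Numerical choices and degenerate inputs

- Ages and percentages round half-up (two decimals for Myr, one for
  percent) to match conventional table formatting.
- Ks = 0 pairs date to 0 Myr and get no selection call.
- Single-exon genes have no introns by construction; intron phases are
  computed on the spliced coding orientation for minus-strand genes.
- NJ requires ≥3 taxa and finite distances; 3 taxa use the closed-form
  three-point formulas.
- The qPCR significance fallback for zero variance in both groups calls
  `ns` unless the means differ exactly.
- The family simulator retries up to 50 times if the family goes extinct
  (or leaves fewer than two genes) and then raises.

## Problem sizes used in validation

Short-alignment Ka/Ks oracle: 500 random 1–3-codon pairs. Ks recovery:
200 replicates × 300 codons at targets 0.1/0.3/0.7 (observed mean within
~2% of target, bound 10%). Reconciliation oracle: ~5,400 exhaustive plus
20 sampled larger cases. NJ consistency: 50 random 4–8-taxon additive
trees. Mechanism recovery: 50 seeded families (hundreds of event pairs).
Donor recovery: 50 simulated clades. These sizes were chosen to exercise
every code path and tie-break while keeping the full validation run in
tens of seconds.

## Known limitations

- Collinearity chaining is greedy, not an optimal longest-chain DP; on
  adversarial anchor sets it can split a block the DP would keep. The
  tests compare it against an exhaustive longest-monotone-subsequence
  oracle on the geometries the classifier is specified for.
- The architecture table's III/IV/X and VI/IX boundaries are assumptions
  (configurable, see above).
- Reconciliation reports parsimony counts; it does not model
  incomplete lineage sorting or horizontal transfer.
- The Kimura protein-distance correction degrades near saturation;
  deep, fast-evolving families should be interpreted with care.
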