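# Methods

This note documents the models and procedures implemented in
`carrierphylo`, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that make runs deterministic.

## Domain harvest

Family membership is decided by a position-specific scoring matrix built
from a user-supplied seed alignment of the carrier domain. Per column
(gap-majority columns dropped), the log-odds score of residue *a* is

    score(a) = log2( ((count_a + pc · bg_a) / (N + pc)) / bg_a )

with pseudocount `pc = 1` and uniform background by default. Scanning is
Smith–Waterman of the profile against each protein with affine gaps
(open 8, extend 1, in bits), ties broken toward the smallest start
coordinate. `X` residues score zero everywhere and are excluded from all
counts.

The bit-score threshold is calibrated empirically: null sequences are
drawn i.i.d. from the scanned proteome's pooled residue composition with
lengths resampled from the proteome's length distribution, and the
threshold is the `1 − FPR` quantile (conservative interpolation) plus a
one-bit margin, at FPR 1e-3 by default. Length matching matters because
local-alignment score maxima grow with sequence length; a
composition-only null built from ~300-residue family sequences
under-estimates the tail for 450-residue decoys. The seed alignment
should span the family's diversity — a seed drawn from a narrow slice of
taxa leaves deep paralog lineages scoring near the threshold. An adapter
for HMMER `--tblout` tables lets users substitute a genuine profile-HMM
scan at this stage boundary.

This PSSM stage is a deliberate simplification of a Plan7 profile HMM:
adequate for a ~300-residue, three-repeat domain family at desk scale,
and fully testable against a brute-force interval oracle.

## Redundancy removal

Greedy clustering in decreasing length order; a sequence joins the first
representative whose identity is at or above the threshold (default
0.9), else founds a cluster. Identity is identical aligned pairs in an
optimal global alignment divided by the *shorter* sequence length, which
is what lets an exact fragment or transcript variant be absorbed by its
full-length representative. Length ties break lexicographically by id.
No k-mer prefilter is used — post-scan input sets are small, and
exactness is preferred over speed.

## Alignment

Pairwise: affine-gap Needleman–Wunsch (BLOSUM62, open −10, extend −1).
Multiple: a progressive scheme — UPGMA guide tree on cosine distances
between 3-mer count vectors, profile–profile merging leaf-to-root with
expected-score columns. Columns once established are never reordered.
This is intentionally simpler than MUSCLE/ClustalW; the pipeline accepts
an externally produced aligned FASTA (`alignment:` config key) at this
stage boundary, so the internal aligner is swappable. Its known
limitation: columns in fast-evolving regions can be misaligned relative
to the true homology, which dilutes apparent per-column conservation
(the end-to-end demo recovers roughly two-thirds of planted
specificity sites through the internal aligner, versus ≥0.9 precision
and ~1.0 recall when the conservation module is given the true
alignment).

## Distance phylogenetics

Poisson-corrected distances `d = −ln(1 − p)` with pairwise gap deletion;
`X` counts as missing. Saturated pairs (`p ≥ 0.95`) are capped at
`−ln(0.05) ≈ 3.0` and flagged rather than returned infinite, because
neighbor joining needs finite input; deep outgroup pairs routinely
saturate at this family's divergences. Neighbor joining follows
Saitou–Nei with the standard Q criterion; negative branch-length
estimates are clamped to zero with the deficit moved to the sister
branch, preserving the pair's summed length. A pair with zero usable
sites is an error naming the pair.

Bootstrap supports resample columns with replacement; the support of
each internal bipartition of the point tree is the percentage of
replicate trees containing it. In the pipeline the replicates use the
distance builder even when the point tree was likelihood-refined — full
ML per replicate is beyond desk scale; the support semantics are
unchanged.

## Likelihood phylogenetics

Felsenstein pruning over 20 states; gaps and `X` contribute partial
likelihood 1. Models: equal-rates ("Poisson") or LG (exchangeabilities
and frequencies embedded verbatim from the published matrix); `+F`
replaces frequencies with alignment counts plus a pseudocount of 1.
Rate heterogeneity is FreeRate: k `(rate, weight)` pairs, weights on a
simplex, mean rate normalized to 1; initialization places rates at the
quantile-bin means of an exponential (Gamma shape 1) and equal weights.
Transition matrices come from a symmetrized eigendecomposition of the
normalized rate matrix, so `P(t)` is exact for any branch length.

Optimization is coordinate ascent: bounded scalar search per branch
length (bounds 1e-9..20, xatol 1e-7), then a Nelder–Mead move over
log-rates and weight logits when k > 1; sweeps stop when the
log-likelihood improves by less than 1e-4 (at most 100 sweeps). Tree
search is hill-climbing NNI in deterministic preorder, accepting only
strict improvements. Correctness of the likelihood is asserted against
exhaustive ancestral-state enumeration on small trees (|Δ| < 1e-8), and
against the pulley principle (rerooting invariance).

## Clade classification

References are a tagged FASTA: one `anchor_A` (the PIC2 representative),
one `anchor_B` (MIR1), and one or more `outgroup` carriers. Trees are
rooted on the branch best separating outgroup from ingroup. The A clade
is the *largest* clade containing anchor A — excluding anchor B and all
outgroup leaves — whose defining node meets the support threshold
(default 75, the lower of the study's two annotation tiers); largest
rather than smallest so that lineage-specific duplicates nested deep in
the clade are captured. Candidates in the smallest clade spanning both
anchors but in neither subclade are `other_family`; everything else is
`non_family`. Nodes without a recorded support (no bootstrap was run)
count as supported — the threshold filters weak splits when support
values exist, it does not demand that they exist.

The screen is two-stage, mirroring the study design: per-taxon NJ trees
retain plausible subfamily members cheaply; the pooled candidates plus
the full reference complement get the final tree and labels.

## Duplication/loss reconciliation

Per-taxon counts of A-like / B-like / other-family labels are reconciled
on the fixed species tree by exact Sankoff DP over copy numbers
`{0..c_max}` (default 4) with branch cost
`w_gain·max(0, child−parent) + w_loss·max(0, parent−child)`, defaults
`w_gain = 2, w_loss = 1`. Gains costlier than losses encodes a
Dollo-like prior — a subfamily present across supergroups arose once.
Backtrace ties prefer the larger ancestral count (pushes gains
rootward). Events are reported per branch (child-node id), not in
absolute time.

One design point deserves emphasis: with a free root, asymmetric costs
*misdate* deep duplications — a two-copy root plus losses is always
cheaper than a single gain below the root. Because the founding A/B
duplication predates the species-tree root by construction of the
analysis, the pipeline pins the root state of the two focal classes at
one copy (configurable; a pinned class absent from every leaf is left
free, and `other_family` is always free). On simulated data this raises
correct branch placement of observable copy-number changes from ~77% to
~96% (per-replicate mean).

## Conservation and specificity sites

Shannon entropy per column, base 2, gaps and `X` excluded from the
frequency counts (a gap-as-21st-symbol policy is available behind
`gap_policy`; excluded is the default because indel columns otherwise
read as "variable" wherever coverage is partial). Columns are mapped to
1-based positions of the ungapped reference (anchor A — the yeast PIC2
numbering convention); the map is a bijection between reference residues
and reference-non-gap columns.

Categories, with strict `H < t` at `t = 0.5` bits and minimum per-clade
non-gap coverage 0.5: `shared_conserved` (both clades conserved, same
consensus), `A_specific` / `B_specific` (conserved in one clade while
the other is variable **or** fixed for a different residue — both clades
fixed for different residues is the clearest specificity signal),
`variable`, `low_coverage`. Rows are unweighted. A site-state extractor
reports each sequence's residue at named reference positions (a default
panel of 16 positions of interest in PIC2 numbering ships as
convenience configuration).

## Structure projection

Finished model coordinates are inputs — the pipeline never builds
models. Annotation writes a per-residue scalar into the B-factor column
of one chain (unannotated residues get the sentinel 99.99); a single
integer offset per chain maps reference numbering onto model numbering.
Geometry helpers give minimum inter-residue atom distances (all-atom or
side-chain scope) and radius neighborhoods.

## Synthetic data generator

The generator emulates the generative structure the pipeline assumes:

* A species tree (random rooted binary by sequential attachment, branch
  lengths uniform on 0.1–0.3 substitutions/site — deep-eukaryote scale)
  or any supplied Newick.
* The focal subfamily: a stem (0.3), a founding duplication, two class
  stems (0.4 each), then per-branch birth–death per lineage at
  duplication/loss rates λ = μ = 0.05 per unit branch length
  (Gillespie within branches, uniform event placement; events recorded
  against the species branch). Reference conditions: 12 taxa, 300 sites.
* Other-family lineages (3 by default) branching off a deeper stem
  (1.2), one copy per taxon — the rest of the carrier family, which the
  domain scan must find and the classifier must exclude.
* Sequence evolution under the same Poisson/LG machinery as the
  likelihood module. Site classes: 15% family-invariant (rate 0
  everywhere), 10% A-specific and 10% B-specific (rate 0 inside the
  frozen clade including its stem, elevated rate 3 elsewhere —
  subfunctionalization after the duplication), the rest neutral at rate
  1.5. Neutral sites run above 1 because a third of sites are frozen:
  the family-wide mean rate then stays near the branch-length scale.
* Indels at 0.02 events per unit branch length (mean length 3),
  realized as gap columns in the true alignment and missing residues in
  the unaligned view; inserted columns are labeled so site-truth
  comparisons can exclude them.
* Decoys: 20 per proteome, i.i.d. from the family's residue
  composition, lengths 250–450.

All randomness flows from the mandatory seed; identical configurations
give byte-identical outputs.

What passing tests show — and do not. The generator plants exactly the
structure the methods assume: clean site classes, a correct species
tree, a single founding duplication, composition-only decoys. Passing
recovery tests therefore demonstrates internal correctness and
calibration, not robustness to the hazards of real proteomes:
misannotated gene models, heterotachy, alignment ambiguity in loop
regions, incomplete assemblies masquerading as gene loss, and domain
families with genuinely borderline members. The per-replicate spread of
the recovery metrics is informative: replicates where stochastic loss
collapses a clade to a few survivors show sharply lower specificity-site
precision — with three sequences, chance conservation is common — which
is equally true of real clades that small.

## Reference study conditions and problem sizes

Simulation benchmarks use 12 taxa, 300 sites, λ = μ = 0.05, with 50
replicates for clade-assignment accuracy and specificity-site recovery,
100 for event placement (reported as per-replicate means, each dataset
weighted equally), 10,000 sites for the two-taxon branch-length
recovery, and 100 bootstrap replicates on the diagnostic-split check.
The demo bundle runs the full pipeline, including the domain scan with
its 400-sequence calibration null, in well under a minute.

## Determinism

Every stochastic step takes an explicit seed derived from the single
configured seed. Log output carries no timestamps; tables are written
with fixed float formats; the manifest lists a SHA-256 per artifact.
Two runs of the same configuration are byte-identical — asserted in the
test suite.
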