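# Methods

This package annotates nuclear copies of mitochondrial DNA (numts), dates
their insertion on a calibrated species tree, separates duplication-derived
copies from independent insertions, and estimates insertion, duplication
and deletion rates. A synthetic-genome simulator generates datasets with
complete event-level ground truth, so every stage is validated against
known answers without external downloads. This note records the models,
the numerical choices, and the limits of what the synthetic validation
shows.

## Detection

**Masking.** A+T-rich mitochondrial genomes produce large numbers of
spurious similarity hits; low-complexity segments are softmasked before
searching. The masker is a two-threshold entropy segmentation: a window
(default 21 b) whose Shannon entropy falls to `locut` (1.4 bits) triggers a
segment that extends over adjacent windows up to `hicut` (1.6 bits).
Masking lowercases residues (identity untouched) and is idempotent. Masked
positions never seed alignments but may be crossed by extension.

**Seed-and-extend search.** Exact 11-mers shared between the mitochondrial
query and a nuclear scaffold (both strands) are extended ungapped in both
directions under X-drop termination (default 30). HSPs are ungapped by
design: the simulator applies no indel process within un-rearranged numt
bodies, and real indel structure at larger scales is handled by HSP
linking and by the merge grammar. Scores use match +2 / mismatch −3.
This ratio (60% break-even identity) was chosen for boundary sharpness:
milder schemes (+5/−4, 44% break-even) let extensions wander 10–30 b past
numt boundaries in A+T-rich background, where chance local identity is
~60%; harsher schemes erode divergent ends. With +2/−3, ≥95% of planted
copies at ≤15% divergence are recovered with both boundaries within ±10 b.

**E-values.** Karlin–Altschul statistics: λ is solved exactly for the
two-valued score distribution under the observed background compositions
of query and subject; K is estimated by a deterministic Monte Carlo
calibration (Gumbel-location fit to exact maximal-segment scores of random
sequence pairs), cached per scoring scheme and composition. The pipeline
keeps HSPs down to a weak floor (E ≤ 0.1) and filters after linking: a
chain is reported only if its combined E-value *and* its best member pass
the configured threshold (default 1e−6). This "anchored chain" rule lets
short terminal fragments ride along with a significant anchor — filtering
each HSP alone systematically truncates numt ends — while chains made only
of weak HSPs are discarded. On random 100-kb scaffolds the search reports
nothing at the default threshold.

**Linking.** Same-strand colinear HSPs separated by at most 50 b on both
query and subject are chained; overlaps beyond a 25-b jitter tolerance
break the chain (a large query overlap is evidence of an internal
duplication, not one hit). Chains are extracted greedily by total score,
ties to the leftmost subject start. Any linked hit covering ≥95% of the
mitochondrial genome at ≥99% identity is flagged as a probable organelle
sequence misassembled into the nuclear set and excluded from annotation.

## Merging and rearrangement classification

Linked hits on one scaffold that overlap or lie within 25 kb are grouped
(single-linkage, end-to-end separation, strict `< 25000`). A group merges
into one numt when every junction between nuclear-consecutive fragments is
explainable by **at most one** gross event: interruption (nuclear gap ≥
200 b), deletion (mito-coordinate gap ≥ 200 b between same-strand colinear
fragments, circular-normalized), inversion (strand flip), or internal
duplication (mito interval revisited). A junction that would need two
simultaneous events — a large nuclear insertion *and* a large mito
discontinuity — marks a split into separate numts; this is the
deterministic replacement for manual micro-synteny curation. Nuclear
overlaps between fragments up to extension jitter are trimmed from the
later fragment; larger contradictory overlaps (the same nuclear bases
claimed by two mitochondrial origins) reject the group with a diagnostic.

Event sizes follow each class's natural evidence axis: interruptions in
nuclear bases, deletions and internal duplications in mitochondrial bases
(duplications as the multiply-covered interval length), inversions as the
inverted fragments' mitochondrial length (a maximal run of minority-strand
fragments is one event). Events below 200 b are not called — the minimum
detectable size. Reported numt lengths sum fragment nuclear lengths with
interruptions excluded and duplicated mitochondrial coverage counted once.

Repeat adjacency flags a numt when any repeat-library annotation lies
within 200 b of its span or inside interrupting sequence; numts with less
than 100 b of retrievable flank are excluded and counted separately.
Association is tested by Fisher's exact test against uniformly sampled
control loci under the same flank requirement (the published contingency
is not given; only the genome-wide repeat fraction is). Intron residence
counts a numt whose span lies inside an annotated transcript and touches
no exon.

## Dating by phylogenetic placement

Each numt is projected into its host mitochondrial genome's coordinate
frame using the exact residue correspondences of its (ungapped) fragments;
rows for the 11-genome panel plus outgroup come from a reference-projected
panel alignment (identity mapping for equal-length genomes, global
pairwise alignment to the host reference otherwise). Columns containing a
gap or N in any row are removed.

Likelihoods use F84 — unequal base frequencies plus a transition/
transversion bias, parameterized here by the expected ts/tv ratio (default
2.0, no rate variation among sites, empirical frequencies), matching the
defaults of the classic ML program this mirrors. Transition matrices come
from the spectral decomposition of the reversible generator, normalized to
one expected substitution per site per unit length. Felsenstein pruning is
pattern-compressed and per-pattern log-scaled; it agrees with exhaustive
summation over internal states to <1e−9.

Panel branch lengths are optimized once per dataset on the panel-only
alignment (coordinate-wise Brent, strided to ≤6000 columns) and frozen.
For placement, inner (subtree) and outer (rest-of-tree) conditional
likelihood vectors are cached, so attaching the numt as a pendant leaf at
position *a* along a branch with pendant length *p* costs O(patterns);
(*a*, *p*) are optimized by a coarse grid plus bounded Brent refinement
(tolerance 1e−4 substitutions). The significance set contains every
branch not significantly worse than the best placement under a one-sided
KH test (normal approximation on per-site log-likelihood differences) at
α = 0.05; the best branch is always retained, and the set can only shrink
as α grows. The insertion age window spans the node ages of the
significance set; density weights distribute the single insertion across
those branches in proportion to their durations in My. Numts whose window
reaches the configured deep split (default the Drosophila–Sophophora node)
or whose placement is uninformative are excluded from rate inputs.

## Paralogy and orthology

Two numts overlapping in mitochondrial origin are tested by comparing the
best tree with the numts as a clade against the best tree with them apart,
on a fixed mitochondrial backbone with branch lengths re-optimized per
arrangement (coordinate-wise Brent plus a joint L-BFGS-B refinement over
log-lengths — coordinate ascent alone stalls on the ridge where the pair's
stem trades against the host edge). The verdict is paralog (or ortholog)
only when the clustered arrangement is better and the one-sided KH p-value
is below α. Pairs sharing fewer than 100 gap-free columns are untestable.
Paralog calls close transitively into sets; each set counts as a single
duplication event.

Two design points matter in practice. First, the alignment must contain a
**non-saturated reference**: under a homogeneous model, a deep outgroup
alone (the 470-My dipteran outgroup is saturated at mitochondrial rates)
cannot polarize ancestral vs derived states, and a star-like arrangement
then fits the data as well as the clustered tree — the test has no power.
Including the host's nearest panel relative restores polarization.
Second, for paralogy the numt leaves attach on the host's own
mitochondrial lineage (they are copies of it); the alternative to
clustering is serial independent attachment along that lineage.

Micro-synteny confirmation extracts each numt's span plus 10 kb flanks,
masks all numt-annotated sequence, repeats and low-complexity segments,
and cross-searches the two contexts at the configured E-value threshold;
fewer than 200 unmasked bases makes a pair untestable.

## Rates

With a chosen set of recent branches (default: the ten branches younger
than ~20 My, stem branches clipped at the cutoff; total time T):

- insertion rate = N_i / T, with N_i the density-weighted insertion mass
  attributed to those branches (duplication-derived copies excluded);
- duplication rate = Dp / (N · T/2), with Dp one event per paralog set and
  N the mean numt complement per genome — the half-branch exposure
  reflects the assumption that a branch's numts are on average half as old
  as the branch;
- steady-state deletion rate = gain rate / N, half-life = ln 2 / rate.

The half-branch convention is exact when complements accumulate from zero
within the branch window (mean numt age = half the branch duration). On a
deep tree whose complement is older than the recent branches it
overestimates the per-numt duplication rate by roughly 1.4–2×; the rate
recovery experiment therefore runs on a calibrated 24-lineage, 20-My
star tree, where the estimator's operating assumption holds. Deletion
censoring biases both rates downward on real data — they are lower bounds,
and the recovery experiment plants no deletions for that reason. With
these conditions the planted insertion rate (0.75/My) is recovered to
~3–5% and the planted duplication rate (0.010/numt/My) to ~10–17% median
relative error over 30 simulations; the residual duplication bias is
definitional (one event per set; N includes duplicate copies).

Correlations (genome size vs numt content, etc.) are Pearson on raw
values and Spearman via average ranks, two-sided P by the t
approximation.

## The simulator

An A+T-rich (0.78) circular mitochondrial genome (16 kb) evolves along the
calibrated tree under F84 at 0.007 substitutions/site/My; nuclear
scaffolds (A+T 0.58) evolve 6× slower, inside the observed 4.5–9× band of
nuclear-to-mitochondrial synonymous-rate ratios. Numt insertions arise as
a Poisson process per branch (default 0.75/My, the genus estimate),
copying the mitochondrial ancestral sequence *at the insertion time* —
a contiguous, possibly origin-spanning fragment with log-normal length
(median 600 b, σ = 1.2, clipped to [200 b, genome length], so
near-complete genome copies occur) — into a uniform scaffold position
outside existing numt bodies (nested copies would corrupt recorded
coordinates and are resampled). Gross rearrangements apply at insertion
with per-class probabilities (interruption 0.15, deletion 0.12, internal
duplication 0.05, inversion 0.02 — proportioned like the observed event
spectrum), each ≥200 b. Duplications (0.010/numt/My) copy a numt with up
to 1 kb of flank (clipped at neighbouring numts) to a new position;
deletions (0.052/numt/My, the steady-state estimate) remove the numt body
and are censored from leaf output but logged. Events run only within the
focal radiation; the outgroup lineage contributes its mitochondrial
sequence. Substitutions are sampled lazily by exact transition-probability
draws between event times, so a branch costs one pass per sequence. A
single seed drives all draws through spawned child streams; runs are
bit-reproducible. The optional control-region flag makes the last ~2 kb
A+T-richer (default off, matching the assemblies that lack it).

**What the simulator does not model:** selection, recombination between
numts, within-numt indels, rate variation among sites, and compositional
heterogeneity along the genome. Consequently the validation demonstrates
correctness of the inference machinery under the stated model, not
robustness to alignment error, rate heterogeneity (a saturated outgroup is
strictly uninformative here, more so than in real data where conserved
sites persist), or assembly artifacts.

## Validation experiments (all seeded, regenerated at run time)

- **Annotation recall:** 60 copies at 2–14% divergence planted at >25-kb
  spacing on one scaffold, half carrying a single ≥400-b rearrangement;
  measured: recovery, boundaries within ±10 b, event-class recovery.
- **Placement coverage:** 50 clean original insertions from a full-tree
  simulation, placed from truth coordinates; the true branch falls in the
  α = 0.05 significance set ≥90% (typically 100%) of the time.
- **Homology calibration:** paralog power on duplicate pairs (3-kb copies,
  parent 15 My, copy 1 My; ≥90%) and false-positive rate on independent
  co-located insertions 15 vs 3 My old (≤10%, typically 0).
- **Rate recovery:** as described above.
- **Steady-state deletion:** gain–loss equilibrium simulations recover the
  planted deletion rate within sampling error via gain-rate/N.

Problem sizes were chosen so the full validation completes in minutes on
one core while keeping Monte Carlo noise well below the tolerances tested.
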