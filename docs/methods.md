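# Methods

## The rate-comparison model

Cross-species similarity is modelled as exponential decay over divergence
time, fitted in log-linear space: log *s* = *a* + *b·t*.  Working on the
log scale makes the three model structures (naïve: shared *a*, *b*;
aware: shared *a*, per-lineage *b*; specific: per-lineage *a*, *b*)
ordinary linear models, so all fits are closed-form least squares via the
normal equations — there is no iterative optimiser and therefore no
initialisation or convergence question.  The exponential is deliberately
the simplest decay law; no attempt is made to fit richer (multi-phase)
models, which would overfit at the handful of species pairs a lineage
provides.

Assumptions worth keeping in mind:

* errors are treated as Gaussian and homoscedastic on the **log** scale;
  additive noise on the similarity scale (as in the power simulation)
  violates this mildly, more so when similarities approach 0;
* observations are treated as independent across species pairs, ignoring
  phylogenetic covariance (all pairs share parts of the tree);
* similarities must be positive to enter the log fit.  Non-positive
  values are dropped with a logged warning and a recorded count rather
  than floored, because flooring would bias slopes; the drop makes the
  remaining sample slightly optimistic when noise is large.

**Model comparison.**  The naïve and aware fits are compared with the
Gaussian likelihood-ratio statistic *n*·log(RSS₀/RSS₁) against χ² with
df = Δ(parameter count).  That reference is asymptotic: its null p-values
are uniform for generous *n* but anticonservative for a dozen
observations.  The exact nested-model F-test is exposed as
`method="f"`; under Gaussian log-scale noise its null p-values are
uniform at any *n* (both facts are verified in the test suite).  The
default stays with the LRT because the decision rule's second gate makes
the choice immaterial in practice.

**Effect size.**  From the lineage-specific fits, the predicted absolute
difference in similarity after 100 Myrs, in percentage points.  With more
than two lineages the **maximum** over lineage pairs is used — a
difference is claimed if any pair differs — and all pairwise values are
reported alongside.  **Decision rule:** *different* iff *p* < α (default
0.05) and effect > threshold (default 5 points).  Both gates are
configurable; the defaults are the conventional ones for this analysis.

## Power simulation

Two lineages decay at rates *b* and *b* − Δ.  At each divergence time in
the panel, two similarity values are drawn — one per lineage — from
N(exp(rate·t), σ), and the full decision pipeline runs on each simulated
dataset; the detection frequency over 1000 simulations is reported per
(Δ, σ) condition.

The default conditions are: distance panel (0.5, 1, 3, 20.9, 91, 97.4)
Myrs — the mammalian comparison pairs, anchored by mouse–human at 91 and
mouse–dog at 97.4 Myrs — one draw per lineage per distance, and base rate
−0.007/Myr for the headline grid.  These settings were fixed by a
consistency argument: the four published detection frequencies for this
assessment (100%, 88.9%, 39.3%, 25.7% over the (Δ, σ) grid) are jointly
reproducible only under this reading.  In particular, the low-noise
Δ = 0.001 figure of ~26% is informative: the true effect sizes at
100 Myrs for base rates (−0.007, −0.005, −0.003) are (4.73, 5.77, 7.05)
percentage points, so any average over the three base rates is pinned
above ~50% by the 5-point gate, while base −0.007 alone — whose true
effect sits just *below* the gate — yields detection only when estimation
noise pushes the estimate over it.  That also explains the superficially
odd ordering in which *more* noise increases detection at Δ = 0.001.
Per-base-rate and base-rate-aggregated variants remain available through
`PowerConfig` and `power_grid`.

At σ = 5% a draw can be non-positive at long distances; such values fall
to the rate framework's drop rule and are logged.

## Synthetic clades

The generator produces a reference genome (uniform base composition) and
evolves each descendant independently (star phylogeny — appropriate
because every downstream measure is a pairwise reference-versus-species
comparison; shared internal branches are not modelled).  Three processes
act per branch:

* **segment loss** — annotation-class runs are split into blocks
  (default 2.5 kb) deleted independently with probability
  1 − exp(−h·t), so class survival is exp(−h·t) by construction.  The
  default hazards are 0.012/Myr for inaccessible chromatin in the
  fast-losing lineage and 0.004/Myr elsewhere, chosen so whole-genome
  retention at 100 Myrs lands near 30% versus ~65% — the magnitudes the
  genome-sequence layer is meant to exhibit.  Because 75 bp sampling
  segments are much shorter than loss blocks, measured retention tracks
  exp(−h·t) to within ~1 point;
* **indels** — Poisson events at 2×10⁻⁴/site/Myr with geometric(0.3)
  lengths capped at 50 bp: small enough to exercise chain-block logic
  without creating pathological spans;
* **substitutions** — Poisson at 2×10⁻³/site/Myr (a mammal-like neutral
  rate), multiple hits allowed, so observed divergence shows the usual
  back-substitution deficit.

Ground-truth correspondences are emitted as UCSC-convention chains (one
chain per surviving segment, score = aligned length; optional inversions
produce minus-strand chains with reflected coordinates).  The annotation
layout is a deterministic 10 kb cassette: a 1.2 kb accessible island, a
2 kb promoter directly upstream of a 1.5 kb gene, inaccessible intergenic
elsewhere.

**Binding sites live in accessible chromatin.**  The ChIP simulator
places reference sites uniformly within supplied regions (the replay uses
the accessible annotation), conserves each site in a descendant with
probability 0.5^(t/half-life), and replaces lost sites with novel sites
drawn from the same region space at loci that still exist in that
descendant.  This is the mechanism behind the end-to-end decoupling
scenario: lineages can differ threefold in bulk (inaccessible) sequence
loss while their regulatory space — and hence occupancy similarity —
decays identically.  The default half-life of 30 Myrs puts the occupancy
correlation near 0.1 at 100 Myrs, the regime of interest.  Reads are
fragments of fixed size L (default 200 bp) centred on sites with 20 bp
Gaussian jitter, sequenced from a strand-random end, plus 20% uniform
background.

**Expression** uses a Gaussian copula on log₂ expression: the latent
Pearson correlation with the reference is 2·sin(π·r/6) for target
Spearman r = exp(rate·t), which makes the realised rank correlation decay
as intended (verified to ±0.05 at r = 0.67).  The log-normal TPM scale
(log₂ mean 3, sd 2.2) leaves a realistic tail of genes under 5 TPM for
the abundance filter to remove.

What the generator does **not** emulate: transposable elements and other
repeat families (mappability masking is exercised only by chance k-mer
collisions and engineered duplications in tests), codon structure and
selection within genes, GC heterogeneity, sequencing errors and base
qualities, and phylogenetic correlation between descendants.  Passing
tests therefore demonstrate correctness of the measurement machinery and
internal consistency of rate recovery — not that real genomes satisfy the
generative assumptions.

## Homology layer

Chain files are parsed and written in the UCSC format with block-sum
validation; query coordinates of minus-strand chains are reflected via
q_size − 1 − raw.  One-to-one filtering assigns every position of either
genome to its highest-scoring covering chain (ties broken by chain id);
an aligned base survives only if its chain wins on **both** its target
and its query position, and this per-base rule — not a sequential
two-pass trim — defines the output, making it directly checkable against
a brute-force per-base table.

Interval lifting follows liftOver semantics: aligned bases are counted
within a single best chain (never pooled across chains), success requires
minMatch of the interval's bases, and the spanning query interval must
not exceed 1 kb (the guard against lifting through large insertions).
Retention sampling places non-overlapping fixed-length segments by
rejection sampling, uniform over all valid placements (by default 5000 ×
75 bp × 20 trials; desk-scale runs shrink these, stated per run).

Ungapped identity uses Smith–Waterman local alignment through Biopython's
`PairwiseAligner` with the EDNAFULL (NUC.4.4) matrix and EMBOSS-water gap
accounting — a gap of length k costs 10 + 0.5k, encoded as open −10.5 /
extend −0.5.  Identity is matches over aligned (non-gap) columns of the
best local alignment.  Segments whose best local score is 0 cannot be
aligned; they are excluded from the average and counted, since including
them would require an arbitrary identity value.

## Occupancy layer

Fragment size L is the offset maximising the Pearson correlation between
plus- and minus-strand 5′ read-start densities, located as the first
downward zero-crossing of the Gaussian-smoothed (sd 10 offsets, kernel
truncated at 4σ) finite-difference derivative of r(k).  Two numerical
guards: the search starts at read_length + 1 (skipping the phantom peak)
and a candidate crossing must sit in the upper half of the smoothed
curve's range — without the prominence gate, noise wiggles in a
near-flat derivative produce spurious early crossings.  The default
search range is [read_length + 1, 600] bp on raw per-bp densities.

Densities impute each read's fragment by extending its 5′ start L bp in
the 3′ direction (minus-strand reads extend leftward from their 3′-end
start).  Reads sharing a start site and strand are collapsed as PCR
duplicates (toggleable); replicates merge by vector addition before
normalization.  Mappability marks start positions whose error-free
read-length k-mer occurs exactly once over both genome strands (exact
k-mer counting, equivalent to zero-mismatch alignment).  Normalization
divides each position's density by the mappable fraction of its L-bp
upstream window, per strand and in the strand-appropriate direction;
positions whose window on either strand holds zero mappable starts are
masked, and strands are summed after normalization (a pre-sum variant
exists for sensitivity analysis).  Cross-species comparison transfers
the query profile onto reference coordinates through the one-to-one
chains and computes one Pearson r over all mutually unmasked, mapped
positions of the concatenated chromosomes.

## Segment-resolution grid

The five choice axes (2 caller variants × 3 quality filters × 3 minMatch
levels × 3 reference subsets × 2 overlap rules) give 108 pipelines.
External peak callers are not re-implemented; a Poisson-enrichment
stand-in tests fixed windows of profile density against the library-size
scaled control, with lenient (p < 10⁻⁵) and stringent (p < 10⁻²²) tiers.
The caller axis is realised as two window sizes (150 vs 75 bp), and the
stringent tier of variant "S" keeps the top-scoring tie class of windows,
mimicking q-value-saturated callers.  This preserves what the grid
probes — sensitivity of verdicts to analytical choices — but cannot
reproduce any external caller's exact output; real-data per-cell verdict
shares are out of reach by construction.  The asymmetric quality filter
calls the reference stringently and the query leniently.  Replicates
merge (lenient) or intersect (stringent): the intersection keeps merged
segments supported by at least one segment in each replicate.  At desk
scale some stringent/minMatch-0.95 cells yield degenerate similarity
series (empty subsets, all-or-nothing retention); these are reported as
*unresolved* rather than forced into a verdict.

## Motif layer

Log-odds PWMs are built from counts with pseudocount 0.1 against a
0-order, strand-symmetrised genome background, and entries are rounded to
3 decimals.  That rounding defines a discrete score lattice on which the
null score distribution is computed **exactly** by position-wise
convolution, so the significance cutoff (smallest reachable score with
tail probability < α, default 10⁻⁴) agrees with exhaustive word
enumeration identically, not approximately.  α ≥ 1 degenerates to the
minimal reachable score so that every word passes.  Scanning scores both
strands (the minus strand via the reverse-complemented matrix) and
reports 0-based half-open hits.

Retention: reference hits are lifted (minMatch 0.001), lifted loci are
extended 50 bp in both directions (total growth 100 bp; a one-sided
switch exists since the convention is not universal), and scanned for any
motif occurrence.  The background shuffles the lifted segments uniformly
within the same query chromosome — one shuffle per analysis, seeded —
and F = (mapped_with_motif − shuffled_with_motif)/mapped × 100.  F can be
negative by chance at large divergence; as a similarity input to the rate
framework such values fall to the drop rule.

## Expression layer

Ortholog maps must be strictly one-to-one.  The >5 TPM filter drops a
pair when **either** member is at or below the floor (symmetric by
construction; a reference-only variant exists because the filter's scope
is a genuine convention choice).  Spearman uses midranks, Kendall is
tau-b, and the Pearson variant correlates log₂(TPM) after filtering
(log₂(TPM+1) when the filter is off, where zeros are possible).

## Reproducibility and scales

A single global seed fans out into independent named streams
(SeedSequence spawn keys derived from CRC32 of the stage name), so every
stage is reproducible in isolation and full replays are bit-identical
under a fixed seed.  The default end-to-end replay uses a 250 kb genome,
five species per lineage at 15–95 Myrs, 60 binding sites, 20 000 reads
per dataset, 1500 genes and 400-segment retention trials; the test suite
uses smaller variants of the same conditions.  These scales keep the full
replay in tens of seconds while leaving every estimator in its working
regime (fragment-size recovery ±10 bp, retention ±3 points of the
generative hazard).

## Known limitations

* The χ² reference for the LRT is anticonservative at very small n; use
  the F variant when observation counts are near the parameter count.
* The power-simulation distance panel reconstructs unpublished figure
  values from published species pairs; headline frequencies shift by a
  few points under neighbouring panels.
* The stand-in peak caller preserves the grid's combinatorics, not any
  external caller's output.
* Mappability tracking is exact-match only (no mismatches), which is
  slightly stricter than error-tolerant aligners on near-repeats.
* The one-to-one filter's per-base rule can orphan positions whose best
  chain lost its partner position elsewhere; such positions are excluded
  rather than reassigned to the runner-up chain.
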