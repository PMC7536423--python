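# Methods

`surfdyn` analyses two-pool quantitative proteomics of the neuronal cell
surface: a *surface* pool measured through captured extracellular
N-glycopeptides and a *total* pool measured through ordinary tryptic
peptides, sampled over a developmental time course (by default days in vitro
2–20 in 2-day steps, three biological replicates per pool). This note
records the models, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Glycopeptide filtering and site counting

Surface-capture chemistry leaves a +0.98 Da deamidation on the asparagine of
formerly N-glycosylated peptides. A peptide is *quantifiable* for the surface
pool when at least one deamidated asparagine (mass delta within ±0.02 Da of
+0.98, accommodating report rounding) sits inside an N-X-S/T sequon; the
sequon is evaluated on the peptide extended by protein context when the
peptide's position in the protein is known, because the motif's third residue
may lie past the peptide's C-terminus. Unique site counting uses the broader
N-X-[S/T/C] consensus and three rules: only consensus-conforming deamidations
count; nonproteotypic peptides are assigned to a single protein of their
group — deterministically the lexicographically smallest accession, since any
fixed arbitrary choice prevents double counting and keeps runs reproducible;
and a peptide mapping to several positions in its protein keeps all
placements on a tie, otherwise only the placement whose deamidated residues
land on the most consensus sequons. Proline at the X position is accepted by
default (the literal motif); the common biological convention of excluding
N-P-S/T is a flag. Coordinates are 1-based; a motif occupies positions
p, p+1, p+2, so an asparagine within two residues of the C-terminus can never
complete one.

## Differential abundance

Per protein and pool, log2 feature intensities follow a fixed-effects
two-way additive model, intensity = feature offset + condition effect +
error, fitted by least squares. On balanced designs the condition contrasts
coincide with those of mixed-model feature-level summarization while
avoiding a heavier dependency; the equivalence is claimed only for balanced
group comparisons, and the residual degrees of freedom differ slightly.
Contrasts are two-sided t-tests on the pooled residual variance. Zero
residual variance (or zero residual df) yields a missing p-value rather
than p = 0: degenerate noise-free fixtures should not produce certainty.
Benjamini–Hochberg adjustment runs per contrast family across proteins;
missing p-values pass through and do not count toward the family size. A
variant restricts each family to entries already passing the fold-change
threshold before adjustment (the pre-filter used for the dense all-pairs
developmental comparisons); significance always requires both fold-change
> 1.5 and adjusted p < 0.05 (both configurable). Condition-level protein
abundance is the median across features of per-feature condition means, so
per-feature additive offsets cancel; per-sample medians are also emitted for
replicate-correlation analyses.

## Profile clustering

Surface profiles observed in at least 7 of the time points are z-scored per
protein over their observed entries (clustering shapes, not levels);
constant profiles are dropped; entries still missing after standardization
are set to 0, the standardized mean, which keeps ≥7-point proteins usable
with a neutral value. Fuzzy c-means minimizes
J = Σ u_ik^m ||x_i − v_k||², alternating membership updates
(inverse-squared-Euclidean-distance sharing with exponent 2/(m−1)) and
membership^m-weighted center updates until the largest center shift falls
below 1e-6. The fuzzifier m defaults to the Schwämmle–Jensen heuristic in
the number of profiles and time points (≈1.36 for 600×10); c defaults to 6
but is a parameter — six clusters is adopted as a convention, not derived
from a selection criterion. Initialization picks c distinct data rows at
random; five seeded initializations are run and the lowest-objective
solution kept, which removes the occasional split-cluster local optimum
while remaining deterministic under the seed. Hard labels are the argmax
membership with ties to the lowest index. Per-cluster annotation enrichment
is a one-sided Fisher exact test (computed as the hypergeometric upper
tail) over the universe of clustered proteins, reported without multiplicity
adjustment; a term is *specific* when enriched (p < 0.05) in exactly one
cluster.

## Impulse model

Time courses follow the product-of-two-sigmoids impulse curve

f(t) = (1/h1)·[h0 + (h1−h0)·σ(β(t−t1))]·[h2 + (h1−h2)·σ(−β(t−t2))]

with initial/intermediate/final levels h0, h1, h2, transition times t1 ≤ t2
(enforced by optimizing (t1, t2−t1) with t2−t1 ≥ 0), and slope β ∈ (0, 50].
Fitting is least squares with ten starts: data-driven initializations
(flat, peak, dip, two monotone ramps, with levels from early/extreme/late
means and times from quantiles of the time range) plus seeded random
restarts, refined by trust-region least squares with an analytic Jacobian.
A start that already interpolates the data (constant series) returns
immediately with SSE 0. Series are conventionally centered before display
per the baseline-anchoring transform out[t] = in[t] − in[baseline] + 10,
which pins the first time point at 10 and keeps values positive.

## Differential trajectory test

Whether a protein's surface trajectory is uncoupled from its total
trajectory is tested by an SSE decomposition: delta = sse_combined −
(sse_surface + sse_total), the cost of forcing one shared impulse curve onto
both pools. Under successful optimization delta ≥ 0 up to tolerance
(the combined-fit parameters are supplied as a warm start to both separate
fits, which enforces the nesting inequality in practice). The null
distribution permutes pool labels within each time point — at replicate
level when replicate observations are available (the per-pool medians are
recomputed for each relabeling), at condition level otherwise — and
p = (1 + #{delta_null ≥ delta_obs}) / (1 + n_perm), BH-adjusted across
proteins with calls at adjusted p < 0.01.

Three numerical choices matter for the test's validity and were selected by
measuring calibration and power on planted data:

- *Centering inside the statistic uses a single common shift* (placing the
  mean of the two baseline values at 10) rather than anchoring each series
  on its own baseline. A common shift commutes with the permutation;
  per-series anchoring injects the baseline-noise difference into every
  permuted point and, for truly differential proteins, inflates the null
  deltas through the large combined-fit residuals.
- *Replicate-level permutation is strongly preferred.* Condition-level
  label swapping has only 2^T relabelings, and for trajectories that differ
  at k time points the pure partitions recur with probability ≈ 2·2^−k,
  which bounds attainable p-values well above the 1/(n_perm+1) floor.
- *Both sides of the comparison use one exchangeable fitting procedure*: a
  vectorized batch Levenberg–Marquardt (bounded, analytic Jacobian, early
  stop on stall) warm-started only at the label-symmetric combined-fit
  solution plus per-series data-driven starts. Warm-starting the observed
  series at their own high-quality multi-start optima, but not the permuted
  series, measurably biases the null.

The reported per-pool SSEs take the best of the multi-start and batched
fits; the p-value comparison uses the batched values on both sides. Note
that the smallest reachable p is 1/(n_perm+1) ≈ 0.005 at the default
n_perm = 200, so calling at adjusted p < 0.01 in cohorts where differential
proteins are a minority requires a larger n_perm (the examples use 500).

## Pool comparison

Surface and total protein groups match when their accession sets intersect;
matching is one-to-one, ranked by descending intersection size with ties
broken by the lexicographically smallest pair of group keys, which makes
the outcome symmetric in the two pools. Coupling is summarized by
per-protein Spearman correlation over shared observed time points (≥3
required), per-contrast Spearman correlation of log2 fold-changes across
matched proteins grouped by time interval, the overlap of significant sets
per contrast (Jaccard |S∩T|/|S∪T| by default — symmetric and bounded —
with |S∩T|/min(|S|,|T|) by flag, since the field reports overlaps without
a fixed denominator convention), quadrant directionality (the fraction of
significant proteins with same-sign fold-changes in both pools, zeros
excluded), and within-complex versus all-pair profile correlation. The
interval trend is tested by one-sided Spearman correlation between interval
length and per-contrast rho; testing per-contrast values rather than
per-interval medians keeps power where the longest intervals contribute
only one or two contrasts.

## Synthetic data

The generator emulates the study design, not its measurements: 10 time
points × 3 replicates × 2 pools; protein trajectories drawn from six
impulse-parameter archetypes (monotone rise, steep early rise, early peak,
monotone decline, transient dip, late switch-on) with per-protein parameter
jitter; Gaussian noise on the log2 scale (log-normal intensities, the
standard label-free error model); per-peptide additive offsets (sd 1.0 by
default, a typical ionization-efficiency spread); replicate noise sd 0.2 by
default (a typical label-free replicate CV); condition-level profiles as
per-time-point replicate medians. An exact round(frac) subset of proteins
is *uncoupled*: the total pool keeps its archetype while the surface pool
stays at baseline until t ≈ 11–12 days and then rises ~2.5 log2 units —
the synaptic-vesicle pattern of an intracellular pool becoming surface
exposed at synapse formation. Uncoupled proteins draw their total-pool
archetype from the early-dynamics shapes only; a late-switch total would
coincide with the late-rising surface and plant no recoverable signal.
An optional surface-only per-time-point component (``trafficking_sd``)
models short-timescale trafficking independent of total abundance.
Missingness is completely at random, which keeps recovery tests
interpretable; intensity-dependent missingness, batch effects, correlated
peptide errors, interference, and protein-inference ambiguity are *not*
modeled, so passing recovery tests demonstrates correctness of the
estimators under their stated assumptions, not robustness to every real
acquisition artifact. A separate two-condition generator (CTRL vs TREAT,
3 replicates, exact planted effect counts with random sign) supports
error-rate calibration of the differential-abundance stage. The
glycopeptide-evidence generator plants sequons at known positions in
synthetic protein sequences (tryptic boundaries: cleave after K/R, no
proline rule, no missed cleavages), including a shared nonproteotypic
peptide, a peptide mapping to two positions distinguished only by protein
context, a proline-X sequon, a cysteine-third sequon (countable but not
quantifiable), and decoy peptides.

## Problem sizes and tolerances

The test suite exercises the pipeline at the scales it targets: 600
profiles for cluster recovery (adjusted Rand index ≥ 0.9 against planted
labels), 1000 proteins for differential-abundance calibration, 200 proteins
× 200 permutations for trajectory-test calibration, 50 planted uncoupled
proteins for trajectory-test power, and 150 proteins × 45 contrasts for the
interval-coupling trend. Noise-free generate-then-fit recovery is asserted
to SSE < 1e-6 with curve agreement within 1e-3; BH and enrichment p-values
are checked exactly against brute-force definitions. Acceptance-style
quantities are recomputed from scratch by `scripts/acceptance.py` at
comparable sizes.
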