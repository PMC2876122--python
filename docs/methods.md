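# Methods

## Probe matching

A probe placement is any genome window, on either strand, whose Hamming
distance to the probe is at most one; indels are not considered, because
the hit criterion (perfect identity or a single base substitution over a
25-mer) admits none. Coordinates are 0-based half-open on the + strand of
the target; a − strand hit is reported at the + coordinates of the matched
window. Both strands are always searched: probe/transcript orientation on
whole-transcript arrays is not modelled, and double-stranded search is the
conservative choice (more candidate hits can only enlarge the mask).
Ambiguity characters never match: any non-ACGT base in the genome counts
as a mismatch, and a probe containing non-ACGT characters is reported as
zero hits with a warning.

The seeded matcher indexes genome tiles of 12 bases at every offset
divisible by 7 and looks up probe tiles at every offset. Stepped genome
tiles alone are provably incomplete for single-mismatch placements — the
two stepped tiles inside a 25-base window overlap by 5 bases, and a
mismatch inside that overlap corrupts both — so the matcher additionally
scans the genome exhaustively for the probe's two terminal 12-mers
(offsets 0 and 13). Those tiles are disjoint, so one mismatch can corrupt
at most one of them and every ≤ 1-mismatch placement is seeded; candidates
are then verified by direct comparison. Completeness is not taken on
trust: an independent exhaustive sliding-window matcher
(`brute_force_hits`, vectorised byte comparison over every window) must
agree set-for-set on randomised instances in the test suite. For
`max_mismatches > 1` or probes shorter than twice the tile size the
terminal-tile guarantee lapses and the seeded matcher falls back to being
heuristic; the package's default usage (25-mers, ≤ 1 mismatch) is always
in the guaranteed regime.

Whether a probe with several placements counts once or per placement is
immaterial downstream: the masking rules consume only the boolean
"has ≥ 1 placement".

## Hierarchical masking rules

The in silico mask works on the design-time mapping table. Boundary
semantics are strict on the probe side and inclusive on the probeset side:
a probeset is removed only when strictly less than half of its original
probes remain, and a cluster is masked when at least half of its original
probesets have been removed. Denominators are always the original
association counts, never post-removal counts, and a probe shared by
several probesets is removed from all of them. Both thresholds are
configurable in (0, 1]; the defaults are 0.5.

The experimental mask is rank-defined: the top ceil(f·N) clusters by mean
log2 signal across the host-only replicates, extended to include any
cluster tied with the cutoff value, with f = 0.01 by default. The signal
threshold reported alongside the mask is the minimum selected mean — an
outcome of the selection, not an input. Means across replicates are
arithmetic on the log2 scale. A total tie (all cluster means equal)
selects the whole universe and warns.

Masks are combined by set union (cluster ids are treated as opaque, so no
universe check is attempted) and applied by removing rows, preserving the
order of survivors; downstream statistics operate on the reduced cluster
set. Probe-level masking followed by re-summarisation is deliberately out
of scope.

## Preprocessing

The normalisation chain is quantile normalisation on the linear scale, a
floor at 16 followed by log2 ("RMA-16" style), median-polish
summarisation of probes to clusters, and an optional mean batch
adjustment. The floor replaces full RMA's convolution background
correction: the "-16" variant's distinguishing behaviour is low-intensity
stabilisation, which the floor reproduces with one transparent parameter
(the exact vendor formula is proprietary). Quantile normalisation assigns
each column's sorted values the row-wise mean of all sorted columns, with
ties receiving the mean of the target values their rank range spans; this
matches limma's `normalizeQuantiles` and is idempotent. Median polish
sweeps rows then columns starting from rows, uses the midpoint convention
for even-count medians, and stops when the sum of absolute residuals
changes by less than a relative 1e-4 or after 10 full sweeps; the cluster
signal per sample is overall effect + sample effect. Probes shared across
clusters contribute to each cluster's polish independently. The batch
adjustment shifts each batch's grand mean to the global grand mean,
leaving within-batch variances untouched.

One practical consequence of quantile normalisation worth knowing when
deriving the experimental mask: normalising host-only arrays jointly with
human arrays forces the host arrays onto the human-dominated common
distribution and inflates their apparent signal. The rank-based mask is
insensitive to this (the cross-hybridising clusters top the ranking either
way), but the absolute threshold and the shape of the host signal
histogram are only meaningful when the host-only arrays are normalised as
their own set, which is how such arrays are processed in practice and how
the histogram comparison in the test suite is computed.

## Concordance statistics

Within-group Pearson comparisons are the unordered distinct sample pairs
(6 for 4 arrays); cross-group comparisons are the full cartesian product
(16 for 4 vs 4, 24 for 3 vs 8). Summary statistics per group pair are n,
min, max, mean, SD (ddof 1) and SE = SD/√n. A zero-variance sample is an
error naming the sample.

MvA takes two per-cluster mean profiles: M is their difference and A their
average on the log2 scale; the outlier count uses the inclusive rule
|M| ≥ 1, i.e. at least two-fold. MSD is the mean squared difference of the
paired profiles; ranking by descending reference mean fixes the reporting
order of the ranked-profile view but cannot change the value. The MSD here
is on mean log2 signals; absolute MSD values on other scale conventions
are not comparable, so only directions of effect (masked < unmasked) are
asserted anywhere.

The moderated t-test shrinks per-cluster pooled variances s²_g (residual
df d = n₁+n₂−2) towards a prior s₀² with df d₀ via the posterior
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d). Hyperparameters come from method of
moments on log s²_g: with e_g = log s²_g − ψ(d/2) + log(d/2), the excess
of var(e) over ψ′(d/2) determines d₀ through a Newton inversion of the
trigamma function, and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the
observed dispersion does not exceed sampling noise, d₀ = ∞ and s₀² is the
mean of the variances. Zero variances are excluded from estimation but
their clusters still receive a positive posterior variance whenever
s₀² > 0. The moderated t uses d₀ + d degrees of freedom, capped at the
pooled residual df over all clusters so an infinite prior yields a finite
reference distribution. These conventions reproduce limma's `eBayes` to
numerical precision, which the test suite verifies against R where
available. `prior_df` can be overridden to force the two limiting cases
(0 = ordinary pooled t, ∞ = common variance). BH adjustment is the
standard step-up procedure, delegated to statsmodels.

## Synthetic-data generator

The generator emulates the validation design of a high-engraftment
xenograft study: graded human/host cell mixtures at 100%, 95% and 90%
human, in triplicate, plus pure-host (NES) hybridisations, on an array of
1,000 transcript clusters × 4 probesets × 4 probes of 25 bases against a
100 kb uniform random host genome (defaults; all configurable).

Defaults and why:

- `frac_homologous_clusters = 0.05` — of the order of the few-percent
  cluster fractions that genome-wide homology screens of human arrays
  against the mouse genome identify.
- `mixture_fractions = (1.0, 0.95, 0.90)`, `replicates_per_mixture = 3` —
  the mixing design being emulated.
- `noise_sd = 0.2` (log2) — typical replicate-level microarray noise;
  after summarisation over 16 probes it yields between-replicate cluster
  correlations ≈ 0.99, the regime reported for engrafted-array replicates.
- `human_signal_log2_range = (6, 12)` — a realistic array dynamic range
  above background.
- `host_affinity_fold = 10` — planted probes cross-hybridise at ten times
  the mean linear human signal, a strong binder; `background_level = 20`
  (just above the floor of 16) is the host-side signal of all other
  probes.
- `homolog_mismatches = 1` — planted probes sit at the edge of the hit
  criterion, exercising the single-mismatch path.

Per probe the linear intensity in a mixture with human fraction f is
f·h + (1−f)·a, where h is the cluster's human signal (log2-uniform over
the configured range, shared by the cluster's probes) and a is the probe's
host affinity (the configured scalar for planted probes, the background
level otherwise), times 2^ε with ε ~ N(0, noise_sd²). NES arrays are
simulated as f = 0.

Homolog placement is rule-aware: in each contaminated cluster,
ceil(probesets/2) probesets consist entirely of probes copied from random
genome windows (random strand, with the configured number of
substitutions), so the cluster satisfies the in silico rule by
construction; every other probe is rejection-sampled until it has no
≤ 1-mismatch placement, guaranteeing a clean negative set. Rejection uses
the seeded matcher, whose set-equality with the exhaustive oracle is
itself under test, so the guarantee carries over at a fraction of the
cost. Everything is reproducible from a single seed, with child seeds for
genome, design and each mixture.

What the simulator does *not* model — and what passing tests therefore do
not show about real data: sequence-dependent hybridisation thermodynamics
(affinity is a configured scalar, not derived from mismatch count or GC
content), partial homology below the 1-mismatch criterion, probe-level
affinity differences within a cluster, transcript-level expression
structure (no correlation between clusters, no differential expression
between mixtures beyond contamination), array spatial artefacts and batch
structure. In particular, perfect mask recovery on synthetic designs is a
construction-soundness check of the filtering logic, not a claim about
sensitivity on real xenograft arrays, where cross-hybridisation is graded
rather than planted.

## Problem sizes and numerical choices

The default study scale (1,000 clusters, 16,000 probes, 100 kb genome,
13 arrays) is chosen so a full simulate–match–mask–validate cycle runs in
tens of seconds on one core while leaving every rule with a non-trivial
population to act on (50 planted clusters, hundreds of hit probes). The
matcher/oracle equivalence suite uses 2 kb genomes × 25-mer probes, where
the exhaustive oracle is fast, with planted 0- and 1-mismatch placements
on both strands to hit the completeness-critical paths. Experimental-mask
recovery on synthetic data is evaluated with `top_fraction` equal to the
planted contamination fraction; a smaller selection could not contain the
planted set by arithmetic alone.

Ties: quantile normalisation averages tied target spans; median polish
medians use midpoints; experimental-mask selection extends through ties at
the cutoff. Degenerate inputs: empty hit sets give empty masks; an empty
mask application is the identity; a full mask leaves a 0-row matrix with
its header; single-probe clusters pass through median polish unchanged;
all-identical host arrays select everything with a warning. Writers are
deterministic (stable ordering, full float repr) so byte-identical
round-trips are testable.
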