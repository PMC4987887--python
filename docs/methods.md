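# Methods

## Problem and model

`trackmatch` answers the question: *given a functional-genomic signal track
(ChIP-seq binding intensity, DNase accessibility, a peak call set, ...),
where in the genome does it look like any track in a collection?*  The unit
of output is a genomic region together with the target track it matches.

A candidate region `(i1, i2)` on one chromosome is scored against target
`t` with the local similarity score

    R_t(i1, i2) = ln(C_t(i1, i2) + 1.001) + alpha * ln(i2 - i1)

where `C_t` is the Pearson correlation between the two signals over the
region, computed at a fixed bin resolution, and `alpha` (default 0.01)
weights a weak bonus for longer regions.  Natural logarithms are used for
both terms; any other base would rescale `R` monotonically and leave every
ranking unchanged, so all thresholds in this package are stated in this
base.  Since `C >= -1`, the first argument is at least 0.001 and `R` is
finite whenever `C` is defined.  `C` is *undefined* on a region where
either binned signal has zero variance — in particular on the all-zero
stretches that dominate real genomes — and undefined regions can never be
seeded, proposed into, or reported.  This is deliberate: a correlation
between two flat signals is a fabrication.

The search maximizes `R_t(i1, i2)` over regions for every target, ranks
all resulting regions by score, reports those with `R > 0` and truncates
to the top `result_cap` (default 1000).

When the index records a matched control for a target (e.g. an IgG
ChIP-seq), the target is normalized to it first: both tracks are binned
and scaled so the genome-wide mean of their nonzero bins is 1 (depth
equalization that ignores the empty majority of the genome), then the
control is subtracted and the result floored at 0 — background-removal
semantics, the standard reading for input/IgG controls.  A log2-ratio
variant (`control_mode: log_ratio`) is available for users who prefer
fold-enrichment semantics; which of the two a given upstream pipeline used
is generally not knowable, so it is a config knob rather than a fixed
choice.

## Seeding

Candidate chains start from *seed* windows: a `seed_window`-base window
(default 1000) slid across each chromosome in steps of one bin, kept when
its correlation is defined and `C >= seed_c_min` (default 0.8) and
`R >= seed_r_min` (default 0.5).  Two remarks:

* **Attainability.**  The maximum possible score of a 1000-base window at
  `alpha = 0.01` is `ln(2.001) + 0.01*ln(1000) ~ 0.763`, reached at
  `C = 1`.  A score cutoff above that value would disable seeding
  entirely; cutoffs should be chosen jointly with the window size.  The
  default 0.5 corresponds to roughly `C ~ 0.8` on a 1000-base window, so
  the correlation cutoff is the operative criterion under the defaults.
* **Step granularity.**  Windows advance one bin (default 10 bp), not one
  base.  Scanning per-base would multiply cost by the bin width while
  producing near-duplicate windows whose refined optima coincide.

Runs of *connected* seeds (overlapping or exactly adjacent windows) are
merged before refinement: each maximal run is replaced by its union iff
the union's `R` strictly exceeds every member's, otherwise the run's
best-scoring member represents it.  The pass iterates to a fixed point,
which in practice is reached after one sweep because merged runs are
separated by at least one base.

## Boundary refinement

Each merged seed starts one Metropolis–Hastings chain over its two
boundaries.  A proposal flips a fair coin for which boundary moves and
shifts it by a uniform draw of up to `delta` bases (default 100) in either
direction; the draw's midpoint is the null move.  Shifts beyond a
chromosome edge are clamped to the edge, and the proposal probability
`q = 1/2 * u/(2*delta + 1)` carries the clamping multiplicity
`u = 1 + (positions beyond the edge)`; interior moves have `u = 1`, and
the exact reverse of any reachable move is itself interior, so the
backward `q` always uses `u = 1`.  A move is accepted with probability

    min(1, (R_proposed * q_backward) / (R_current * q_forward))

treating the score as an unnormalized density.  The ratio is only
meaningful for positive scores: proposals with `R <= 0` or undefined `R`
are rejected outright, and a chain started below zero (possible only with
user-lowered seed thresholds) climbs greedily until it reaches the
positive domain.  The chain runs a fixed `mcmc_iterations` steps (default
2000), tracks the best-scoring state visited, and returns it — so
refinement never does worse than its seed, and the goal is maximization,
not posterior sampling; there is no burn-in or convergence diagnostic.

Numerically, the chain lives on the bin lattice: boundaries are multiples
of `bin_size` and `delta` is converted to lattice units.  For any fixed
set of overlapped bins the score is maximized at bin-aligned boundaries
(identical correlation, maximal length term), so the lattice restriction
loses none of the attainable optima, and it lets every score evaluation
run in O(1) from per-chromosome prefix sums of `x`, `y`, `x^2`, `y^2`,
`xy`.  Proposals that would invert the region or shrink it below two bins
are counted as steps but leave the state unchanged.  Zero-variance
detection uses a relative tolerance (`1e-10` of the second-moment scale)
so that exactly-constant segments are flagged despite floating-point
cancellation in the prefix-sum variance.

The acceptance ratio concentrates only weakly around the optimum (typical
score ratios are close to 1), so the chain behaves like a guided random
walk with a per-boundary drift of a couple of kilobases over 2000 steps.
That is enough to locate block boundaries precisely, and deliberately not
enough to wander across the tens-of-kilobase empty gaps that separate
signal blocks in realistic data.

After refinement, chains started from nearby seeds can return overlapping
regions.  These are first passed through the same union-if-better merge
rule used for seeds (two chains that bracketed the same optimum collapse
into it; two chains whose overlap is incidental keep their best), and any
overlap that survives is resolved by keeping the higher score.

## Orchestration and determinism

Targets pass metadata filters (conjunction across fields, disjunction
within a field), are split into up to `subsets` (<= 100) non-overlapping
groups, and the groups are processed on up to `threads` (<= 24) workers.
Reproducibility is a hard contract: each target's RNG stream is derived
from `(rng_seed, sha256(target_id))`, results are assembled in a fixed
order and globally re-sorted (score descending, then chromosome, start,
end, target id), so output is byte-identical whatever the thread count or
scheduling.  Per-target failures are recorded and skipped, never fatal to
the run.

## Synthetic benchmarks

The `simulate` module generates the study designs used by the test suite
and the acceptance script:

* **Matched pairs.**  `n_regions` matched regions, each holding 1–10
  signal segments of 100–2000 bp, are placed on the genome by rejection
  sampling without overlap; query and target carry *identical* signal
  inside them.  Decoy segments of the same length distribution are placed
  outside the truth in the target only (clean, gold-standard design) or in
  both files (noisy design without a gold standard: two decoys that happen
  to overlap are a genuine pattern match, yet the evaluation deliberately
  refuses to credit them, under-estimating precision).  Where the design
  leaves details open the generator chooses once: segment intensities are
  per-segment constants drawn Uniform(1, 10) — correlation structure, not
  amplitude, is what the method detects, and constants keep hand oracles
  exact; inter-segment gaps are Uniform(0, 500) bp.
* **Noise replacement.**  Given a positive set (here: the track's top-k
  self-search regions), signal inside positives is kept bitwise; the rest
  of the genome is replaced by point noise at Poisson-process locations
  (per-base rate `lambda = 0.01`, i.e. exponential gaps averaging 100 bp)
  with Gaussian values whose mean and variance are estimated per-base over
  the positive regions; negative draws are floored at 0 and points are
  written at bin width.
* **Evaluation.**  A returned region is a true positive iff it comes from
  the expected target and overlaps a truth region by at least one base;
  sensitivity is the fraction of truth regions hit, precision the fraction
  of returned regions that are true positives (undefined on empty output).

The default synthetic genome is 10 chromosomes of 5 Mb (the
oversubscribed-cap benchmark uses 20 x 5 Mb, and the noise-replacement
benchmark 5 x 2 Mb with a 10-track index).  All per-region rates and
lengths are full-scale, so per-region behavior matches larger genomes;
what shrinks is only the amount of empty space between regions.  Passing
these benchmarks therefore demonstrates the engine's behavior on clean,
piecewise-constant, exactly-reproduced signal — it does not demonstrate
robustness to replicate-level biological variability, mappability
artifacts, or assembly mismatches, none of which the generator emulates.

## Known limitations

* All tracks must be local files on one assembly; no liftover, no remote
  streaming.
* Peak (BED) inputs are binarized to 1.0 — the score column is ignored, so
  peak heights do not influence matching.
* The bin grid (default 10 bp) bounds boundary precision; matches shorter
  than two bins are undetectable by construction.
* One chain per merged seed: a pathological seed bridging two distant
  optima refines to one of them.
* The score-ratio acceptance rule is a heuristic maximizer, not a sampler;
  on near-flat score surfaces (e.g. `query == target` genome-wide) the
  refined boundaries extend a random couple of kilobases into the
  zero-signal flanks of each block, where extension is score-neutral in
  correlation and weakly favored by the length term.
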