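# Methods

This note documents the models, statistics and numerical choices behind
`sibfate`, and what the synthetic experiments can and cannot demonstrate.

## The analysis problem

A microcolony of tracked *E. coli* cells is exposed to a semi-lethal heat
shock. Each cell either resumes growth and division (survives) or not.
Because cell-cycle progression is desynchronized across the colony, the
moment of the shock catches every cell at a different relative position
x ∈ [0, 1] of its cycle (0 = birth, 1 = division). The analysis asks three
questions:

1. Can x be predicted at the moment of the shock from observable features?
   (x itself is unobservable then — the division that would define it never
   happens for stressed cells.)
2. Do sibling cells share their survive/die fate more often than two
   independent coin flips with the population survival probability p would,
   and how does that coupling depend on x?
3. Among surviving siblings, how correlated are their resuscitation lags,
   and how does that correlation depend on x?

## Synthetic lineage generator

There is no public dataset for this assay, so all statistical machinery is
validated on a generator with recorded ground truth.

**Growth and division.** Each cell elongates exponentially,
L(t) = L_b·exp(λt), with per-cell rate λ ~ N(λ₀, cv·λ₀) truncated positive,
λ₀ = ln2 / 23.44 min⁻¹. Division follows an adder: a cell divides when it
has added increment Δ ~ N(Δ̄, cv·Δ̄) to its birth length (Δ̄ = 2.5 µm,
cv = 0.15). Division splits the mother length by a fraction
0.5 ± N(0, 0.03), conserving length exactly; the old pole goes to a random
daughter. Founders are desynchronized by a uniform initial cycle phase, so
the population at any fixed shock time is approximately uniform in x.
Frames are sampled on a 30-s grid; the schedule is analytic, so interdivision
times and true positions are known exactly. Divisions in the sliver between
the last pre-shock frame and the shock are treated as unresolved (the cell
counts as undivided, x clipped to 1), matching what a tracker could see.

**Defaults as study conditions.** Mean doubling time 23.44 min, 30-s frames
(≈47 samples per cycle), growth-rate CV 0.1, founder/adder length 2.5 µm,
shock after a configured number of mean generations (4 for the
multi-generation design, 1 for the one-generation design), survival
p = 0.454 / 0.558 for the two designs.

**Fluorescence.** The nucleoid-reporter channel is emulated as
length-proportional intensity with (i) per-cell reporter-level variability
(log-normal, CV 0.2 — expression noise), (ii) 15% per-frame multiplicative
measurement noise, and (iii) a 4-min exposure grid (values held between
exposures), mirroring acquisitions where fluorescence is imaged far less
often than phase contrast. Fidelity here is deliberately low: the channel
exists so that the ΔF/F features participate in model fitting while staying
only weakly informative, as observed for DNA-content features in this kind
of assay. No replication/segregation dynamics are modeled.

**Fate coupling.** Each cell's marginal survival probability is p at every
x. Sibling pairs share fates with probability
c(x) = chance + (c₀ − chance)·exp(−x/s), chance = p² + (1−p)², c₀ = 0.875,
s = 0.03 cycle fractions. Both constraints are met with a mixture: with
probability w(x) = (c(x) − chance)/(1 − chance) one pair-level Bernoulli(p)
fate is copied to both siblings, otherwise the fates are independent
Bernoulli(p) draws. (Copying alone preserves the marginals, which is what
the mixture reduces to at w = 1 — tests must not count this twice as a
separate mechanism.)

**Resuscitation.** Surviving pairs draw lag pairs from a bivariate normal
(mean 60 min, sd 15 min — plausible scales for post-heat-shock lags; no
published summary statistics pin them down) with correlation
ρ(x) = 0.62·exp(−x/0.5), truncated at 0. Post-shock traces stay flat at the
pre-shock length and then regrow exponentially, timed so the trace first
exceeds 110% of its baseline exactly at the programmed lag; non-survivors
stay flat. Post-shock traces carry no measurement noise, so programmed lags
are recoverable to one frame — detection robustness to noise is a property
of the >10% threshold, not something the generator stresses.

**Seeding.** One master seed; every colony and the shock stage draw from
counter-based sub-streams (`SeedSequence(seed, spawn_key=…)`), so changing
the number of colonies never shifts the draws of existing colonies.

## Feature extraction

Six features at evaluation time `at`: L_b (length at the first frame at/after
birth), Δt = at − birth, ΔL, GR, ΔF, F. GR is a log-linear fit over the
7 minutes ending at `at`; when the window reaches across the cell's birth,
the mother's frames are spliced in after scaling by the daughter's share of
the mother's final length (the asymmetric-division correction; ½ for a
symmetric split), making the spliced log-trace continuous. If no windowed
estimate exists (parentless cell near birth), the whole-trace fit is used.
ΔF/F use total (extensive) cell fluorescence. Ground-truth x is linear in
time between observed birth and division. Training tables sample one
uniform x per completed cell cycle, snapped to the nearest frame (the
recorded x is the snapped frame's true position). Filters: cells whose
maximum pre-shock length strictly exceeds 11 µm are removed with their
descendants (filaments); optionally only founder lineages with exactly a
required number of pre-shock divisions are kept (1 for the one-generation
design).

## The cycle-position model tree

A depth-limited (default 3) regression tree whose leaves hold OLS linear
models over all six features, ≥25 cells per leaf. Fitting is greedy
top-down; at each node every feature and every midpoint between consecutive
sorted distinct values is scored by the summed squared error of one OLS fit
per child, computed exactly via prefix sums of the normal equations.
Numerical choices:

* features are standardized per node before solving (they span five orders
  of magnitude; the affine map changes neither the optimal split nor the
  SSE in exact arithmetic, only the conditioning);
* a tiny ridge (1e-10 relative to the Gram trace) keeps degenerate designs
  (constant features) well-defined instead of crashing;
* a split is accepted only if it strictly improves on the node's own linear
  fit (relative tolerance 1e-9, so float-noise "improvements" on
  already-exact fits are refused — a noiseless linear target yields one
  exact leaf);
* ties are broken toward the lowest feature index, then the smallest
  threshold — determinism over cleverness;
* predictions are clipped to [0, 1] (the target's defined range).

Tests verify the greedy search against independent brute-force enumeration
with per-candidate `lstsq` fits on tables up to 200 rows.

**Cross-validation.** Seeded k-fold (default 10) with pooled out-of-fold
predictions. The headline R² is the squared Pearson correlation between
predicted and actual x (it pairs naturally with the reported correlation
p-value); the coefficient of determination 1 − SSE/SST is reported
alongside. Per-decile R² bins by *actual* x so that bin membership does not
depend on model quality.

## Fate-coupling statistics

* Chance coupling level: p² + (1−p)² (= 0.504 at p = 0.454, 0.507 at
  p = 0.558). Symmetric in p ↔ 1−p, minimum ½ at p = ½.
* Survival CI: Wilson score interval (default; reproduces the published
  interval for 45.4% of 425 cells at one decimal), Wald selectable.
* Survival per x-bin: two-sided Fisher's exact test of each bin against the
  complement of all other cells (a bin cannot be Fisher-tested against "the
  average" in any other 2×2 form).
* Coupling per bin of the pair's average position: exact two-sided binomial
  test (scipy's min-likelihood convention) of the coupled count against the
  analytic chance level — the faithful exact analogue of testing against a
  fixed percentage; a bin-vs-complement Fisher variant is provided.
* No multiple-testing correction by default (fixed α = 0.01 per bin);
  empty bins are reported untested.

**Power, honestly.** With the default kernel (c₀ = 0.875, s = 0.03) the
*average* coupling over the first decile is 0.61, not 0.875: an exponential
kernel spreads the decay inside the bin. At ~40 pairs per bin the exact
binomial test then detects the first-bin excess in only ~9% of simulated
experiments, so a single synthetic run usually does *not* flag bin 1 even
though the aggregate over replicates recovers the pattern. Reproducing a
first-bin coupling of ~0.875 with later bins at chance is impossible for
any exponential kernel (forcing the first-bin mean that high drags the
second bin to ~0.73); a sharper-than-exponential decay would be needed.
Similarly, with 10 exact binomial tests per run at α = 0.01, the
probability that a null (instant-decay) run shows no significant bin is
≈ 0.99¹⁰ ≈ 0.92. These ceilings are inherent to the chosen kernel and test,
and the acceptance suite states them explicitly where it asserts stronger
patterns.

## Resuscitation analysis

Baseline = mean of the first three post-shock lengths; the lag is the time
of the first later frame whose length strictly exceeds 1.10 × baseline
("increased over 10%"), plus the dead time between stress end and recording
start (default 5 min). Only survivors are analyzed, but the detector is a
total function on any trace (flat traces → absent). Sibling lag
correlations use Pearson's r with the two-sided correlation p-value and a
seeded percentile bootstrap CI (default 10,000 resamples; the resampling
unit is the pair), overall and within the cycle-position intervals 0–0.05,
0.05–0.2, 0.2–0.4, 0.4–1; intervals with fewer than three complete pairs
are reported as not computable.

## Pipeline

`run_pipeline` chains simulate → filter → features → train/CV → predict at
shock → survival/coupling (→ resuscitation) with per-stage seeds derived
from one master seed; identical config + seed reproduces every output file
byte for byte. Problem sizes used throughout the tests and presets: 635 /
453 training cells (from ~60 / ~45 unstressed colonies), 29 four-generation
or 450 one-generation shocked colonies (≈ 450–750 shocked cells, ≈ 200–420
sibling pairs), 100-run Monte Carlo for null calibrations — sizes chosen to
match the emulated study designs while keeping a full run in seconds.

## Known limitations

* Pre-shock length traces carry no measurement noise, so the synthetic
  cycle-position model performs better (CV R² ≈ 0.95, RMSE ≈ 0.07) than a
  model fitted to real microscopy data would; the acceptance band is
  therefore one-sided (R² ≥ 0.8, RMSE ≤ 0.12).
* The generator has no spatial geometry, nutrient gradients or neighbor
  effects (the emulated assay design controlled these away), no
  replication-fork or nucleoid dynamics, and no post-shock divisions.
* Passing recovery tests shows the estimators are correct under the
  generator's assumptions (exponential growth, adder division, exponential
  coupling/correlation kernels); it does not validate those assumptions
  against real data.
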