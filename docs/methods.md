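# Methods

This note documents the models, conventions and numerical choices behind
`mousebarn`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Interval semantics and time handling

All RFID stays are half-open intervals `[entry, exit)` in UTC epoch seconds.
Half-open semantics make boundary cases unambiguous: a mouse exiting at the
instant another enters shares zero time with it, so touching intervals never
produce a meeting. Zero- and negative-duration stays — which occur in real
RFID logs as reader glitches — are dropped at ingest and counted in a QC
report; overlapping stays for one mouse violate the physical model (a mouse
cannot occupy two boxes at once) and abort ingest with the offending ids.

Calendar operations (seasons, ISO weeks, hour of day) use a configurable
fixed UTC offset, default +1 h (central European standard time). Using a
fixed offset rather than a civil timezone removes daylight-saving
ambiguities from every downstream histogram. Seasons follow the
meteorological convention: spring = March–May, summer = June–August,
autumn = September–November, and the *winter of year Y* spans December of Y
plus January and February of Y+1, so January timestamps map to the previous
year's winter.

## Meetings and the co-occupancy index

A *meeting* is a maximal interval during which two mice co-occupy one box —
computed by a sweep over entry-sorted stays per box, with back-to-back
fragments (a mouse exiting and instantaneously re-entering) merged to
restore maximality. The association index between mice i and j over a
season window is the time-based Jaccard coefficient

    COI(i, j) = T_ij / (T_i + T_j − T_ij),

with `T_ij` the pair's total meeting time and `T_i` the mouse's total
in-box time, all clipped to the window. This is the natural "time together
normalized to total box use": symmetric, bounded in [0, 1], exactly 1 for
identical stay sets and 0 for mice that never meet. Alternative
normalizations (e.g. half-weight or simple-ratio indices from the
association-index literature) differ only in the denominator; Jaccard was
chosen because it is the only common variant that is simultaneously a
metric complement and bounded, and the choice is isolated in
`networks.compute_coi`.

## Networks, communities, nulls

Seasonal networks have one node per mouse with at least one stay in the
window and a COI-weighted edge for every positive pair. Community structure
is found by Louvain modularity maximization on the COI weights. Louvain is
a greedy stochastic optimizer whose single-run output depends on its
visiting order, so `detect_communities` runs 20 independent restarts and
keeps the partition with the highest weighted modularity; on graphs of ≤ 10
nodes the result is checked in the test suite against exhaustive
enumeration of all set partitions.

The modularity null model preserves the degree sequence exactly
(double-edge swaps, ≥ 10·|E| attempted swaps per replicate) and then
permutes the multiset of COI weights across edges; graphs admitting no swap
fall back to weight permutation only and are flagged. The z-score compares
the observed Louvain modularity with the null distribution of re-detected
modularities. Degree-preserving rewiring is the conservative standard for
social-network nulls: it keeps each individual's gregariousness fixed and
randomizes only who meets whom.

The small-world coefficient is σ = (C/C_rand)/(L/L_rand), with C the mean
unweighted clustering coefficient and L the mean shortest path on the
largest connected component of the binarized (COI > 0) graph, and baselines
the means over Erdős–Rényi graphs matched on node and edge count (default
20), measured on their largest component when disconnected. A graph with
zero clustering returns σ = 0 rather than an error. Weighted clustering and
weighted shortest paths are deliberately out of scope.

Box sharing versus distance uses, for each box pair, the Jaccard percentage
of shared users over the season; pairs where neither box was inhabited are
omitted. The exponential decay `y = a·e^(−bx)` is fitted by bounded
(a, b ≥ 0) nonlinear least squares initialised at a = max y, b = 1/mean x,
with solver tolerances tightened to 1e−14 so the degenerate constant-data
case converges to b = 0 at test precision.

## Audio model and clock correction

Recorders run a 55 s record / 5 s pause duty cycle; segment i of a
recording occupies `[start + 60i, start + 60i + 55)` and one analysis
"minute" is one such segment. Events are points at their onset for all
binning and alignment — durations are retained but unused — so an event
spanning a segment boundary is never double-counted. Onsets falling in a
5 s gap cannot be genuine detections and are dropped with a warning.

Each recording carries two anchor pairs (recorder timestamp, RFID
timestamp) produced by a chime at its start and end. Clock correction is
the unique affine map through the two pairs — the exact inverse of linear
drift injection, verified to sub-millisecond residuals at ±2 s/day drift
over two-day recordings. Times outside the anchor span are converted by
extrapolation and flagged. No piecewise refinement is attempted: a single
affine map per recording is the model.

## Permutation tests

All permutation p-values use the add-one estimator
`p = (1 + #{null ≥ observed})/(1 + n_perm)` with a one-sided "greater"
alternative, which is super-uniform under its null by construction.

**Squeak–USV co-minutes.** The statistic is the number of segments with at
least one squeak and at least one USV. The null permutes the per-segment
squeak counts across segments (squeak times shifted relative to USV times;
the count multiset preserved, USVs fixed). Under such a permutation the
statistic is exactly hypergeometric — the overlap of a uniformly random
set of squeak-occupied segments with the fixed USV-occupied set — and the
null replicates are drawn from that law directly, which makes the test
cheap enough for large calibration sweeps. Because the statistic is
integer-valued, the test is conservative when per-minute presence
saturates: with squeaks in nearly every minute the null distribution has
almost no support in the tail and the achievable type-I rate collapses
toward zero. Calibration simulations therefore use per-minute presence
probabilities near 0.5 for squeaks (0.7 expected squeaks and 0.25 expected
USVs per 240-segment recording), where the statistic has enough resolution
for the empirical type-I rate to sit near the nominal 5%; at
production-scale vocal rates the test only becomes more conservative, never
anticonservative. A circular-shift variant of the null would preserve
within-recording autocorrelation; uniform permutation was chosen as the
declared default because segment-level counts carry little autocorrelation
once the event kernel is localized well below the segment length.

**Peri-event alignment.** Vocal onsets within ±60 s of each box entrance or
exit contribute at their signed lag to a histogram (default 5 s bins, a
compromise between lag resolution and per-bin counts; 2–10 s bins give the
same modal lag in the recovery simulations). The null redraws the same
number of onsets uniformly over the recording's *recorded* segments —
duty-cycle gaps never receive events — and recomputes the histogram,
yielding pointwise envelopes.

## Negative-binomial count models

Per-recording vocal counts are modelled with negative-binomial GLMs
(log link) and a log-exposure offset (exposure = number of recorded
segments). Four candidate mean structures are compared: season only, and
season plus each of adult count, sex ratio, and pup count. The dispersion
α is not jointly estimated; per model it is profiled on a 50-point log grid
over [0.01, 10] by minimal negative log-likelihood, with warm-started IRLS
across the grid. AIC = 2k − 2·logL counts every estimated parameter
including α (a constant offset across models, so rankings are unaffected by
that convention). "Variance explained" is reported as the deviance-based
pseudo-R² (1 − residual/null deviance), the only variance notion
well-defined for GLMs here. Designs with a single season are rejected as
singular, and all-zero counts as degenerate.

## Pair series: vocal counts and future co-occupancy

For each recorded (focal) box, every pair's meetings inside the recording
span are ordered; meeting k contributes the number of vocal onsets (per
call type) inside the meeting interval *and* inside a recorded segment,
paired with the pair's cumulative all-box COI evaluated at the start of
meeting k+1. The last meeting has no "next" and contributes no point.
Pairs need at least 4 usable points — the smallest series length with a
non-trivial Spearman permutation null (3! = 6 distinct orderings). Spearman
ρ uses average ranks for ties; constant series are undefined and excluded.
Shuffled controls permute each pair's count sequence while holding its COI
sequence fixed, pooling the resulting null ρ distribution.

## The synthetic barn

The generator emulates the statistical regularities such a monitored
population exhibits, with all draws flowing from one root seed through
named substreams (population, groups, stays, vocals, pups, drift,
recordings) so components can be regenerated independently and outputs are
bit-reproducible.

- **Population and layout.** Near-balanced sexes by permutation of an
  exactly half/half vector (counts never differ by more than one); boxes
  row-major on a square grid, default 16 boxes at 2 m spacing.
- **Social groups.** Per season, mice are partitioned into groups and boxes
  into group home-sets. A stay lands in a home box with probability
  `box_affinity` (default 0.9), otherwise in a random other box; on
  "defection days" (per-day probability `switch_rate`) a mouse temporarily
  uses another group's boxes. Group counts and sizes vary by season —
  fewer, larger, stickier groups in winter; smaller, more dynamic groups in
  spring/summer.
- **Stays.** Start times follow an inhomogeneous process whose diel profile
  is two wrapped Gaussians (dawn ≈ 06:00, dusk ≈ 20:00, 2 h widths) over a
  uniform floor — the crepuscular pattern — and durations are log-normal.
  Defaults (median 180 s, log-sd 1.5, 2 stays/h) make the *typical* stay a
  few minutes long while the heavy tail produces the hours-long nest stays
  that dominate cumulative box time; mice then spend roughly a third of
  their time in boxes, which is what sustains realistic co-occupancy.
  Candidate stays that would overlap a mouse's previous stay are discarded,
  so no mouse is ever in two boxes at once.
- **Vocal events.** Per recording, the per-second rate is
  `[λ0/55 + λ_event·K(t)]·exp(β_pup·pups)` with K a sum of two-sided
  exponential kernels (τ default 5 s) centred `lag_event` after each box
  entrance/exit. Sampling is by thinning; the bound uses the fact that a
  sum of two-sided exponential kernels is convex between adjacent centres,
  so its maximum lies at a centre. Defaults: λ0 = 3 bouts per 55 s segment;
  a bout emits both call types in the same segment with probability 0.05,
  otherwise a single call that is a squeak with odds 20:1 — jointly giving
  an emergent squeak:USV ratio near 10:1. Pup counts follow two seasonal
  waves (spring and late summer) with Poisson per-recording counts.
- **Pair coupling.** The planted link between vocalization and future
  association is a shared latent per-pair random walk z over meeting index
  that multiplies both meeting durations and the vocal rate during meetings
  (`exp(γ·z)`), so with γ > 0 counts and subsequently accumulated COI rise
  and fall together without either being defined from the other, and with
  γ = 0 counts are independent of the COI trajectory. This generator
  operates at the meeting level (isolated pairs in private boxes, each with
  its own recording and solo stays between meetings) so the planted effect
  is exactly controlled while the real meetings→series→ρ code path is
  exercised. In the full barn simulation a *structural* positive coupling
  also emerges without any planted latent — busier meetings are longer and
  longer meetings raise subsequent COI — which mirrors how such a
  correlation can arise mechanistically in real data.
- **Clock drift.** Recorder time = RFID time + offset + drift·elapsed days
  (default 2 s/day, per-recording offsets uniform in ±60 s), with anchors
  emitted at recording start and end.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: detector errors (missed or spurious
vocalizations, label confusion), identity of the vocalizer, weather and
temperature covariates, births/deaths and tenure turnover beyond pup-count
schedules, antenna-level read errors, and any audio content. Recovery
results show that the pipeline measures what it claims on data obeying its
assumptions, not that real recordings satisfy those assumptions.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by design: barns of
10–60 mice, seasonal windows of 2–7 days, deployments of 120–720 segments
(2–12 h) rather than the two-day default, 100-seed recovery sweeps, and
1000-recording calibration sweeps with 1000 permutations each. Every
stochastic operation is seeded; reruns of the pipeline with the same config
are byte-identical (verified by manifest checksums), and a completed bundle
is never recomputed unless forced.

## Known limitations

- Weighted small-world and weighted path metrics are not implemented; the
  binarized graph is the declared basis for clustering/path statistics.
- The co-minute test's conservatism at saturated vocal rates is inherent to
  the discrete statistic, not removable by more permutations.
- Exact modularity maximization is exponential; above ~10 nodes the Louvain
  optimum is the operational definition of "the" partition, and at weak
  planted contrast the global modularity optimum itself can differ from the
  planted labels.
- COI timelines in the pair analysis are cumulative from the start of the
  observation window, not windowed; early meetings therefore influence late
  COI values.
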