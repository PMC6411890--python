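# Methods

This note documents the models and procedures `meanet` implements, the
parameters that matter, the design choices made where the conventions in
the field are genuinely open, and what the synthetic benchmarks do and
do not establish.

## Recording model and units

The pipeline targets 60-electrode planar MEAs recorded for 10 minutes at
22.3 kHz. All spike times are seconds (double precision) in
[0, duration); voltages are volts; burst rates follow the
bursts-per-minute convention. Bandpass filtering (e.g. 268–8036 Hz) is
treated as an acquisition-side property: an optional 4th-order zero-phase
Butterworth re-filter exists (`DetectionConfig.bandpass_hz`) but is off
by default, since re-filtering hardware-filtered data is at best a
no-op.

## Spike detection

An action potential is a negative-going crossing of
−(multiplier × σ_noise), multiplier 5 by default. Two choices deserve
justification:

* **Noise estimator.** σ_noise is the robust MAD-based estimate
  median(|x|)/0.6745 rather than the raw SD, because the spikes
  themselves inflate the raw SD and would raise the threshold on the
  most active electrodes. For Gaussian noise the estimator is consistent
  (unit tests verify 1% accuracy at 10⁶ samples and 2% under 0.1%
  contamination at −10σ).
* **Polarity and dead time.** Only negative crossings count —
  extracellular spikes on planar electrodes are dominantly negative —
  and detection is suppressed for 1 ms after each crossing so one
  waveform cannot yield several events at 22.3 kHz. The event time is
  the negative peak within the dead-time window.

A degenerate all-constant trace gives σ = 0; the detector warns and
returns no events rather than dividing by a zero threshold.

Artifact rejection deletes any event coincident (±1 ms) with events on
at least 90% of recorded channels: sub-millisecond array-wide
coincidence is electrical, not biological. The window and channel
fraction are configurable since the convention varies between labs.

Electrode QC uses strict inequalities exactly as conventionally printed:
more than 4000 spikes per 10 minutes is noisy, fewer than 10 is silent;
counts of exactly 4000 or 10 stay active. QC is idempotent, and the
percentage of active electrodes is reported against the device's
electrode count (60 by default).

## Bursts and activity features

Burst detection is the classic max-interval method in three phases:
seed a candidate at an ISI ≤ 0.1 s and extend while ISIs stay ≤ 0.2 s;
merge candidates separated by < 0.5 s; discard candidates shorter than
0.05 s or with fewer than 10 spikes. Phase order merge-then-filter is
the convention of the established tools; it is what makes the minimum
IBI meaningful (two sub-threshold runs can merge into a valid burst). A
brute-force re-derivation of the three phases, plus a hypothesis-driven
property test, pin the implementation exactly.

Burst duration is last spike − first spike (no padding); IBI is next
start − current end. Per-electrode features aggregate to device level by
unweighted mean over active electrodes with a *defined* value:
electrodes without bursts contribute 0 to bursts/min and % spikes in
bursts, but are excluded from burst-duration/IBI means; undefined values
are NaN, never 0, so they cannot bias study aggregates. The ISI feature
is the mean of consecutive differences (median is a config switch away
in principle; mean was chosen as the common default).

## SPIKE-distance and surrogate normalization

The SPIKE-distance profile S(t) is built from, for each train, the
preceding/following spike around t, the local ISI, and the distances of
those two spikes to the nearest spike of the other train; per-train
terms are combined weighted by the opposite train's local ISI and
normalized by 2⟨x_ISI⟩². D = (1/T)∫S dt ∈ [0,1], 0 iff identical.
Auxiliary spikes at 0 and T bound the edge intervals (the measure's
standard edge correction; configurable off).

Between consecutive corner times (the union of both trains' spikes) all
profile ingredients except the two linear offsets are constant, so S is
piecewise linear and the trapezoid rule on corner intervals is *exact*.
The test suite checks this against a dense-grid (0.1 ms) numerical
oracle on 100 random pairs (agreement < 10⁻⁴; in practice ~10⁻¹⁶) —
the two routes share the profile definition but not the integration.
Degenerate corner intervals of subnormal length (possible only with
pathological inputs) underflow the normalization; their contribution is
defined as 0, which is also their limit.

Raw SPIKE-distances between random trains are substantially below 1, so
observed distances are normalized to chance: for a pair with n₁ and n₂
spikes, surrogate pairs are drawn uniformly at random on [0, T] with the
same counts (no refractoriness — deliberately matching the stated
surrogate model), and synchrony = 1 − D_obs/mean(D_surr), clamped to
[0, 1]. The alternative reading mean(D_obs/D_surr) is implemented behind
`SynchronyConfig.normalization`; divide-by-mean is the default because
it cannot blow up on a small surrogate denominator. Clamping negative
values to 0 matches the [0,1] synchrony scale; consequently the *mean*
synchrony of null pairs is slightly positive (≈ +0.005 at 10-minute,
2 Hz trains) — the unclamped mean is what is calibrated to 0 (tested:
|mean| < 0.02 over 200 surrogate-distributed pairs).

Each electrode pair gets an independent surrogate substream seeded from
(global seed, electrode i, electrode j), so matrices are bit-identical
under a fixed seed regardless of computation order. The production
surrogate count is 1,000; tests and demo analyses use 20–100, which
leaves Monte-Carlo error far below every tolerance asserted (the
surrogate mean's relative SE is ≈ CV(D)/√R ≲ 0.3% at R = 100 for
10-minute trains).

## Graph, modularity, Louvain

Edges with synchrony strictly below 0.10 are removed ("below" read
strictly: weight exactly 0.10 is kept); isolated electrodes remain as
nodes. Modularity is the standard Newman Q with resolution fixed at 1
(exposed in config). Q of the all-in-one partition is identically 0;
two disconnected unit 4-cliques partitioned by clique give exactly 0.5;
a unit-weight K5 split into singletons gives −5·(4/20)² = −0.2 (m is
the sum of edge weights; cross-checked against networkx).

Louvain is implemented in-package because testability demands exact
determinism: node visiting order is a seeded permutation, ties between
candidate communities break to the lowest label, and moves require a
strictly positive gain (ε = 10⁻¹²). Phase 2 aggregates communities into
super-nodes carrying self-loops equal to their internal (ordered) weight
and recurses until a level no longer merges. Optional restarts keep the
best-Q partition. On 50 random ≤ 8-node weighted graphs the result
never exceeds the exhaustive optimum over all set partitions and attains
it in ≥ 90% (it is a greedy heuristic; occasional local optima are
expected and accepted). `networkx`'s Louvain and modularity serve as
independent cross-checks in the tests, never as the implementation.

Reported community counts include only communities with ≥ 2 electrodes;
singletons (isolated nodes after edge filtering) are reported separately
— a deliberate reading, switchable via `count_singletons`, since a lone
unconnected electrode is not a functional community.

## Synthetic recordings

The generator emulates the statistical structure of mature-culture
recordings, not their biophysics:

* **Poisson devices** — independent homogeneous trains per electrode
  (counts Poisson, times uniform order statistics); the null model.
* **Bursting trains** — burst onsets form a Poisson process at the
  requested bursts/min; the count is drawn first and onsets are then
  placed uniformly, resampling offenders until bursts do not overlap and
  are separated by ≥ 0.5 s plus a 0.2 s guard. Drawing the count first
  keeps the expected burst count exactly rate × duration (pure
  rejection would thin high-rate configurations and bias the round trip
  low by a few percent). Each burst is `spikes_per_burst` spikes at the
  intra-burst ISI; generation requires ≥ 10 spikes at ISI ≤ 0.1 s so
  every generated burst is detectable by construction. Background
  spikes within 0.2 s of a burst window are deleted so the max-end-ISI
  rule terminates bursts cleanly; with a 0.2 Hz background, the
  detector recovers generated bursts exactly (0 mismatches in 500
  trains), so round-trip error is purely the Poisson count noise.
  The benchmark rates (3.19, 1.54, 1.33 bursts/min) are mature-culture
  (~30 days in vitro) group means for ECM-coated and control devices.
* **Assembly devices** — per assembly, one "mother" Poisson train
  (default 3 Hz); each member copies each mother spike with probability
  `copy_prob` plus N(0, jitter²) jitter, over independent background
  spikes. Copies closer than 0.1 ms are deduplicated (refractoriness;
  strict monotonicity). With copy 0.9 and 5 ms jitter, within-assembly
  synchrony ≈ 0.6 versus ≈ 0 between, so the 0.10 edge filter isolates
  the planted communities.
* **Raw traces** — Gaussian noise plus a fixed biphasic template
  (negative lobe to −1, 0.4 positive rebound, ~1 ms) scaled to
  `spike_amplitude_sd_units` × noise SD at each spike time. Any
  dominant-negative template exercises a lower-limit threshold; no
  claim of waveform realism is made.

Defaults not fixed by the recording protocol (background 0.5 Hz, 8σ
spike amplitude, 3 Hz mothers, 0.3 Hz assembly background) were chosen
once as representative of active mature cultures and are documented
here rather than tuned.

**What passing these benchmarks shows — and does not.** Recovery on
synthetic devices establishes the internal consistency of the chain
(generator → detector → features → synchrony → communities) under the
stated statistical structure. Real recordings add nonstationarity
(development over days, network-wide bursts), electrode crosstalk,
non-Gaussian noise and waveform diversity, none of which the generator
models; performance there depends on the robustness arguments above
(MAD noise floor, artifact rejection, surrogate normalization), not on
these tests.

## Numerical and size choices

* Exact piecewise integration makes the distance deterministic to the
  last bit; surrogate draws and Louvain orders are the only stochastic
  elements and are seeded throughout (end-to-end bit-reproducibility is
  tested).
* The 50-train burst-rate round trips have a relative SE of ≈ 3.5% at
  the lowest rate purely from Poisson onset counts; recovered means are
  typically within 1–4% of truth.
* Demo analyses and tests run with 20–100 surrogates and devices of
  6–30 electrodes; the production defaults (1,000 surrogates, 60
  electrodes) scale linearly in pairs × surrogates (~1 ms per
  10-minute pair distance).
* CSV round trips use pandas' exact (`round_trip`) float parsing so
  staged and in-memory pipelines agree bit-for-bit.

## Known limitations

* No spike sorting: electrodes are multi-unit signals, as in the
  target workflow.
* No network-burst (array-wide burst) detection and no time-resolved
  synchrony; only the pairwise time-averaged measure.
* No inferential statistics: the study tables end at mean ± SEM per
  condition, ready for any stats package.
* Louvain is a heuristic; global optimality is neither guaranteed nor
  claimed (see the brute-force comparison above).
* The artifact-rejection window (±1 ms, 90% of channels) and the
  merge-then-filter burst phase order are documented conventions, not
  universal standards; both are configurable.
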