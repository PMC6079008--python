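# Methods

This note documents the models and procedures the package implements,
the conventions and numerical choices behind them, what the synthetic
generators do and do not emulate, and the known limitations.

## Event streams and movement reconstruction

The primitive datum is a detection event: integer milliseconds since a
configurable epoch, an opaque animal tag, a sensor id and a sensor kind
(tube antenna, floor antenna, gate, beam). Events are totally ordered
by `(timestamp, sensor_id, mouse_id)`; simultaneous detections at the
same millisecond therefore have a deterministic, if arbitrary, order.
All intervals are half-open `[start, end)` — a boundary instant belongs
to the later interval — so visits, sessions and schedule lookups
partition time without double counting.

A transition is a pair of consecutive detections of one mouse on the
two antennas of the same tube; direction follows antenna order. Tube
antennas are treated as fully reliable, so an inconsistency (a
transition starting from a compartment the mouse should not be in)
indicates log truncation rather than sensor noise: the reconstruction
trusts the antenna evidence, resynchronises the location state, and
counts the event in the anomaly report. Two consecutive detections on
the *same* antenna are a back-out (the mouse entered the tube and
retreated) and consume both detections without emitting a transition;
a detection orphaned by one on a different tube is counted and skipped.
Visits span from one arrival to the next; the position before the first
completed transition is unknown and yields no visit, and the open tail
after the last transition is excluded by default (its exit time is
unknown) with an opt-in flag to close it at log end. These choices make
the conservation law exact: per mouse, visit durations sum to the span
between first and last arrival.

## Activity measures

Occupancy proportions are time fractions over the mouse's tracked time;
entropy is `−Σ p_i ln p_i` in nats (the natural log is a convention,
configurable in base by post-scaling; bounds 0 and ln K are attained at
point mass and uniformity). Circadian histograms fold event times onto
a 24-h dial in 10-min bins (144 bins; the bin width must divide 1440)
and normalise by days observed. Visit-duration densities are Gaussian
kernel estimates on log10(duration in minutes) with a **fixed absolute
bandwidth of 0.1 log-units**; the kernel is evaluated directly rather
than through a variance-scaled KDE so that the bandwidth means the same
thing for every compartment and degenerate (zero-variance) inputs are
handled. Dark phase is 19:00–07:00 (lights on at 07:00, configurable);
cumulative dark-phase curves sum each night's metric across nights,
which is the natural view for watching individuals diverge over time.

## Social measures

Co-presence classifies every instant of a mouse's tracked time by the
number of co-present conspecifics in the same compartment (alone / 1 /
2 / ≥3), via a sweep-line over visit intervals with exits processed
before entries at equal times (the half-open convention again); the
four buckets partition tracked time exactly. Lead/follow pairs
same-destination arrivals of distinct mice with lag in `(0, 5 s]`: each
follow is matched to its nearest preceding lead, a lead is credited at
most once per other mouse per occurrence, and exactly-simultaneous
arrivals are discarded since no order is determinable. The pairing
construction makes `Σ leads = Σ follows` an identity. The window bound
is closed at 5 s and exposed as a parameter. The transition PETH pools,
for every arrival, the arrival lags of other mice into the same
compartment within ±10 s and smooths them with a fixed 2-s Gaussian
kernel; note the pooled histogram is symmetric by construction (each
pair is seen from both members' perspectives), so coupling appears as
twin peaks at ±lag. Chasing episodes chain concomitant (≤5 s)
detections of an ordered mouse pair across distinct antennas with the
leader reappearing within ≤30 s; at least two antennas make an episode.
Chasing rests on floor antennas, which miss ~25% of crossings, so
chase-derived quantities are excluded from profile building.

## The choice model

The T-maze task is modelled as a two-armed dynamic foraging problem.
The switch rate SW is a pure balance statistic (order-invariant, in
[0, 100]); the slope *a* regresses |cumulative L − cumulative R| on
trial index (with intercept), which calibrates exactly to 1 for a
never-switching animal and stays near 0 for a balanced one. Win-stay
probabilities are estimated only on *repeated* trials; the repeat
criterion is the gap from the previous exit to the next entry ≤ 20 s
(entry-to-entry is available via a flag — the choice matters little for
fast re-entries but exit-to-entry remains meaningful when a trial
itself lasts longer than the window).

The learning model is the standard softmax reinforcement learner:
`P_i = exp(βV_i) / Σ_j exp(βV_j)` with rewards water=1, sucrose=2,
nothing=0. The default value update is the delta rule
`V_c ← V_c + α(R − V_c)` on the chosen side only; a pure accumulator
variant `V_c ← V_c + αR` is available as `rule="literal"` but is not
the default because it diverges under repeated reward and cannot
produce stable post-swap learning curves. Values start at (0, 0), are
not reset at bottle swaps (the animal receives no swap cue), and are
reset between sessions. The likelihood is the forward-pass product of
the realised choices' softmax probabilities, computed with a max-shift
for stability; for any parameter pair the leaf probabilities of the
full binary choice tree sum to one, which is the oracle property the
tests enforce. Fitting is a deterministic multistart — α on a 10-point
grid in [0.05, 0.95] crossed with 7 log-spaced β in [0.1, 10], bounded
Nelder–Mead refinement from the three best starts, bounds α ∈ (0, 1],
β ∈ [0, 100] — and the refined optimum is never allowed to be worse
than the best grid point. One-sided sequences leave β unidentifiable;
the fit is returned with a boundary flag rather than an error.

## Profiles, PCA, clustering

The 16-variable profile comprises 7 general-activity variables
(occupancy of the five compartments, entropy, tube detections/day),
5 social variables (time alone / with 1 / 2 / ≥3 others, LF) and
4 T-maze access variables (entries, time per day, time per entry, mean
inter-entry interval). This assembly is one defensible reading of the
three-class scheme; it is documented here rather than asserted as
canonical. Per-class PCA standardises the class columns, drops
constant ones, and fixes each component's sign so the largest-|loading|
variable loads positively (determinism across linear-algebra backends).

Switcher clustering standardises (a, SW, α, β), projects on principal
components, and applies bagged k-means: k-means centroids are collected
over 50 bootstrap resamples, pooled, grouped by average-linkage
hierarchical clustering into k groups, and observations are assigned to
the nearest aggregated centroid — the classical bootstrap-aggregation
scheme for stabilising k-means. Groups are renamed LS/IS/HS by
ascending mean SW; the ordering is a labelling contract. The whole
procedure is driven by one seed and deterministic.

## Burst segmentation

Bursts follow the classical two-threshold ISI rule: onset at the first
interval strictly below 80 ms, continuation while intervals are at most
160 ms, termination at the first interval strictly above 160 ms.
Intervals in [80, 160] ms can therefore extend a burst but never start
one, and both thresholds are strict exactly as stated (80 ms does not
open; 160 ms does not close). Two-spike bursts are valid. %SWB is the
percentage of spikes inside bursts; a silent train has an undefined
(NaN) %SWB, not zero. Per-animal statistics are unweighted means over
neurons. Electrophysiological cell identification (waveform shape,
1–10 Hz rate band) is an ingest-time filtering concern, not an
algorithmic stage.

## Synthetic data: what it emulates, what it does not

The colony simulator moves each mouse as a continuous-time Markov chain
over the tube-connected compartments (default symmetric 15/h per edge),
with all rates multiplied during the dark phase (default ×2) and by a
per-mouse lognormal heterogeneity factor — both of which leave the
chain's stationary distribution unchanged, so the analytic occupancy
prediction stays exact. Social coupling is planted explicitly:
designated followers copy their leader's transition with a configurable
probability after a 1–3 s lag, if they are in the leader's source
compartment. Detection is modelled as the hardware behaves: every tube
crossing emits its antenna pair with probability 1.0 by default
(misses, when configured, drop the whole pair — truncation, not
noise), floor arrivals are detected with probability 0.75, and there
are no false positives. Choice agents implement the softmax learner
exactly (plus side-biased and random controls) against a swap schedule
timed at block-start entries. Spike trains alternate truncated-
exponential tonic intervals (>161 ms) with bursts of uniform 40–75 ms
intervals, so every planted burst satisfies and every tonic gap
violates the detection rule — ground-truth %SWB is exact and the
detector must recover it with zero error. The planted switcher cohort
draws all four choice features from group-typical Gaussians (SW centred
at 5/50/95), reflecting that the phenotypes are coherent in feature
space rather than differing in SW alone.

What the generators do not emulate: home-range memory and non-Markovian
movement, dominance structure, body-contact social interactions,
sensor-level timing jitter, drift between acquisition clocks, and any
fitting of the simulator to a real cohort's statistics. Passing
recovery tests therefore demonstrates correctness of the algorithms
under the stated statistical assumptions, not validity of those
assumptions for real colonies.

## Problem sizes and determinism

Validation uses desk-scale runs chosen to keep the whole suite fast
while leaving comfortable statistical margins: the end-to-end colony
check uses 10 mice for 48 simulated hours (~20k crossings), parameter
recovery fits 100 agents of 300 trials, the likelihood oracle
enumerates all 2^8 length-8 sequences under 50 parameter draws, and the
burst oracle covers 1000 random plus 500 generated trains. Every
stochastic component takes a single integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical outputs.

## Known limitations

* Reconstruction assumes per-mouse detection streams are causally
  ordered; clock skew between independent acquisition systems is not
  corrected.
* The lead/follow statistic counts temporal precedence, not intent;
  at high traffic it picks up coincidental pairings, which is why
  planted-coupling recovery is assessed against a same-rate baseline.
* The RL fit assumes a single stationary (α, β) per sequence; regime
  switches within a session bias the estimates toward averages.
* The 16-variable assembly and the win-stay gap convention are
  documented choices among defensible alternatives, both configurable.
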