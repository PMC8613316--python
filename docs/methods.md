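# Methods

This note documents the models and conventions behind each pipeline stage,
the choices made where a definition was genuinely open, what the synthetic
generators do and do not emulate, and the package's known limitations. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Conventions used everywhere

* Times are seconds from recording start; the frame of a time *t* is
  `floor(t × fps)`. All windows and intervals are half-open `[a, b)`: a
  frame at exactly *b* is excluded. One convention everywhere avoids
  window off-by-one disagreements between stages.
* 30 fps behavior aligns to 10 fps imaging by non-overlapping 3-frame
  block means; trailing frames that do not fill a block are dropped.
* Every stochastic routine takes a seed (or derives per-neuron seeds from
  one via `numpy.random.SeedSequence`), so identical configs give
  bit-identical outputs while streams stay independent.

## dF/F₀ and transients

F₀ is a sliding-window percentile (default: 50th percentile, 300 s
window). The window is **centered** and truncated at the recording edges;
recordings shorter than the window use the whole trace for every frame.
Whether such a window should be centered or trailing is a genuine choice;
centered is symmetric and is exposed in the configuration by its window
length only — a trailing variant would bias F₀ upward on rising baselines.
The window length in frames is forced odd so centering is unambiguous, and
percentiles interpolate linearly between order statistics (continuous in
the window contents). Implementation uses pandas' skiplist rolling
quantile, O(n log w); tests pin it elementwise to a brute-force per-window
percentile.

dF/F₀ requires F > 0 throughout; non-positive fluorescence is an input
error, not something to silently clamp.

**Baseline noise SD.** "SD of the baseline" is deliberately robust here:
σ = 1.4826 × median absolute deviation of dF/F₀. A naive SD is inflated by
the very transients being detected; the MAD estimate changes by < 5% when
1% of frames carry large transients (tested), and equals the SD for
Gaussian noise.

**Transient detection.** Three thresholds: peak ≥ 4σ; inter-peak interval
≥ 0.5 s (closer peaks collapse to the larger, the earlier winning ties —
a deterministic tie-break); extent ≥ 0.3 s, where the extent is the
contiguous run strictly above 2σ around the peak. Overlapping extents
merge, keeping the taller peak. Size = Σ dF/F₀ over the extent; frequency
is transients per minute. Flat-topped peaks are detected at their left
(earliest) plateau frame. Denoising zeroes samples below 2σ and is
idempotent.

Default kinetics of the synthetic transients (instantaneous rise,
single-exponential decay, τ = 0.4 s, amplitude 1.0 dF/F₀) are a
fast-indicator (GCaMP6f-like) proxy, not a biophysical model; both are
configuration fields, as is the noise SD (default 0.05 dF/F₀) — real
recordings publish no such parameters, so these are stand-ins chosen to
give clearly detectable but not trivial events.

## Population synchrony

The raster binarizes denoised dF/F₀ (nonzero → 1). Each of the 1000
surrogates applies to every neuron an independent circular shift drawn
uniformly from {0, …, T−1} — zero included, which keeps the draw uniform
and the null slightly conservative — and sums the rows. The threshold θ is
the 95th percentile of the **pooled** frame values of all surrogates (not
of per-surrogate maxima). Row sums are conserved exactly by construction.
On rasters small enough to enumerate (3 neurons × 20 frames = 8000 shift
combinations), the sampled θ equals the exact pooled percentile.

Events are maximal runs with population count **strictly above** θ; a tie
at θ neither starts nor extends an event. Event peak = argmax within the
run, earliest frame on ties; participants are the neurons active at the
peak frame (binary raster, not raw dF/F₀).

**Discreteness caveat.** The population trace is integer-valued, so θ
(which lands on an integer of the pooled distribution) truncates the
exceedance tail at the next integer: for independent stationary neurons
the long-run fraction of frames above θ is 1 − F(k) for the smallest
integer k with F(k) ≥ 0.95, which undershoots the nominal 5% by up to one
CDF step — roughly P(population = k), about 2–3 percentage points at 100
neurons. This is a property of strict exceedance on count-valued traces,
not a sampling artifact; it makes the detector conservative (fewer, more
reliable events). The idealised 5% calibration holds only in the
continuous-trace limit (many neurons), and the corresponding calibration
test documents the measured shortfall.

Pairwise structure: Pearson ρ between dF/F₀ traces; d = √(1 − ρ)
(d = 0 for duplicates, 1 at ρ = 0, √2 at ρ = −1); complete-linkage
hierarchy on d; the dendrogram leaf order is returned for matrix display.
A zero-variance trace is an error naming the neuron, not a NaN.

## Widefield and whisking

* **Optic flow**: per grid point, the integer displacement minimising the
  block SSD within the search radius (block 11 px, grid 16 px, radius 8 px
  by default); ties resolve to the smallest displacement. Grid points
  whose search window would leave the frame are skipped. Mean magnitude is
  the average Euclidean norm over grid points. Pure translations of a
  textured image are recovered exactly; the 0.5 px tolerance in the
  verification covers noise.
* **Activity mask**: pixels with lag-1 autocorrelation ≥ 0.95.
  "Autocorrelation" without a stated lag is read minimally as lag 1 (at
  10 fps a signal varying over ≥ ~20 s passes easily: a 20 s-period
  sinusoid has lag-1 autocorrelation cos(2π/200) ≈ 0.9995, while white
  noise is near 0); the lag and threshold are exposed in configuration.
  Constant pixels are excluded with a warning.
* **Whisking onsets**: first frame at/above threshold after ≥ 0.5 s below
  it, staying above for ≥ 0.5 s. The default threshold is median +
  3 × 1.4826 × MAD of the magnitude series; for a degenerate quiet
  baseline (MAD 0, as in noiseless synthetic bouts) it falls back to
  halfway between the quiet level and the maximum. These criteria are
  package decisions — episode definitions are rarely printed — and are all
  configuration fields.
* **Onset-locked metrics**: modulation = mean over episodes of
  (mean Ca_WF on [0.3, 1.3) s) − (mean on [−1, 0) s). Scaling Ca_WF
  scales it; adding a constant does not. Episodes without the full ±2 s
  alignment margin are dropped with a warning; zero usable episodes is an
  error. The **response delay** is reported as the *time* of the
  post-onset maximum (averaged over episodes), because the quantity is a
  delay in seconds; the literal mean of the maximum *values* is available
  as `delay_mode="peak_value"` rather than guessing further at intent.
* Cross-correlation: Pearson r at integer frame lags within ±2 s; a
  positive peak lag means activity follows whisking. With a planted gain
  and delay, the peak lag recovers the delay to within one frame.

The whisking generator couples a square-bout magnitude series (30 fps) to
a whole-field trace (10 fps) as `gain × delayed, downsampled whisking +
noise`. It does not emulate hemodynamic contamination: the pipeline
consumes already-filtered per-pixel dF/F₀ by design, since that filtering
is an external published method.

## Texture selectivity

Touch events keep contacts strictly longer than 1 s (a 1.0 s contact is
excluded). Touch response and DP use the same windows: pre-contact
[−1, 0) s and contact [0.3, 1.3) s after onset; the decision variable is
the window-mean dF/F₀. DP is the ROC area = (wins + ½ ties)/(n₁n₂),
computed from average ranks (Mann–Whitney U); an independent library U
statistic serves as a cross-check in the tests, and exhaustive pair
counting is the oracle.

The permutation test pools all DVs and reassigns labels preserving group
sizes (1000 shuffles). Whether the reshuffle should preserve the
within-episode pairing is unstated in common usage; the pooled scheme is
the default and a paired within-episode swap is available
(`paired=True`). The test is one-sided (responsiveness = elevated contact
activity) with a two-sided option, and uses the add-one estimator
p = (1 + #{DP* ≥ DP}) / (1 + n_perm), which cannot return 0. On
exchangeable inputs the rejection rate at α = 0.05 sits at or slightly
below 5% (the discrete DP distribution plus the add-one estimator make it
mildly conservative).

Classification: p < α for the novel texture only → NTS; familiar only →
FTS; both → non-selective; neither → non-responsive. Neurons with zero
detected transients over the session are excluded before classification —
the programmatic form of removing silent/noisy ROIs — and reported with
category `excluded`. Recovery of planted category fractions is assessed by
whether the binomial 95% CI around the recovered fraction covers the
planted value; the recovered NTS/FTS fractions carry the expected ~α-level
false-positive contamination from non-responsive neurons, which the CI
reading accounts for without hiding it.

## Behavior

DI = (novel − familiar)/total approaches, antisymmetric under label swap,
undefined (an error) at zero approaches. Encoding exclusions: < 12 total
approaches, or > 60% of approach time on one column — both strict
inequalities, so exactly 12 approaches or exactly 60% is included; both
thresholds are parameters. Session criterion: earliest 10-trial window
with ≥ 8 correct, reported as the count of trials consumed. Omissions
count as non-correct by default, because the criterion asks for trials
*correctly completed*; `skip_omissions=True` removes them before
windowing (the met index still counts every consumed trial), and both
modes are reported where the distinction could matter.

## Spines

Identity is carried by protrusion ID (annotation-level matching). For
ID-free tables a positional matcher is provided (same dendrite, nearest
record within 0.5 µm across consecutive sessions, greedy); the tolerance
is a package decision, since manual relocation pipelines publish none.

Turnover between sessions: formed = present now, absent before;
eliminated = the converse; spine percentages divide by the
previous-session **spine** count, filopodium percentages by the
previous-session **protrusion** (spines + filopodia) count. Survival
follows the cohort newly formed at a session (absent at the preceding
one). Re-emergence: a new spine counts if it lies strictly within 2 µm of
a recorded elimination site on the same dendrite (a tie at exactly 2.0 µm
does not count); both directions are reported — fraction of new spines
near a site, and fraction of eliminated spines recovered — each with its
denominator, and an empty denominator yields "undefined", never 0. A
re-emerged spine is a new identity; no record resurrects.

The history generator eliminates each protrusion per interval with
`p_eliminate`, except spines in their first interval after formation,
which survive it with `p_survive`; spine and filopodium formations are
separate binomials on their own previous-session counts, so each recovered
rate has a clean binomial oracle. A configurable fraction of new spines is
placed within the re-emergence radius of a site eliminated in an *earlier*
interval (sites from the current interval are not yet visible), which
makes the forced-re-emergence case exact. Presence obeys conservation:
spines at s = survivors from s−1 plus formations.

## What the generators do not emulate

Synthetic traces have stationary Gaussian noise, sinusoidal drift
(period ≥ 100 s so the 300 s baseline window is exercised), and linear
superposition of transients; real recordings add motion artifacts,
neuropil contamination, photobleaching, and indicator nonlinearity. The
whisking model is a square-wave bout with a single gain and delay; real
coupling is state-dependent. Spine histories assume homogeneous
probabilities across spines and sessions. Passing recovery tests therefore
demonstrates correctness of the quantification arithmetic and its
statistical calibration under the stated assumptions — not robustness to
every artifact of real data, which is what the upstream corrections
(motion correction, hemodynamic filtering, manual curation) are for.

## Verification problem sizes

The verification suite uses sizes chosen to make sampling error small
relative to the tolerances while keeping each check quick: exhaustive
shift enumeration at 3 neurons × 20 frames against 10⁴ surrogates; 200
random DP instances at ≤ 10 episodes; 1000 exchangeable neurons at 1000
permutations for type-I calibration; 200-neuron planted populations
(amplitude 5 × noise SD, 10 contacts per texture) for selectivity
recovery; 20 seeds of 30-bout sessions for whisking recovery; 20 seeds of
100-neuron, 10-minute recordings for the synchrony exceedance
measurement.

## Known limitations

* The synchrony exceedance fraction is conservative on count-valued
  population traces (see the discreteness caveat above); with few neurons
  the shortfall from the nominal rate is material.
* DP with few episodes takes few distinct values; permutation p-values
  inherit that granularity and the add-one floor of 1/(n_perm + 1).
* The optic-flow estimator returns integer displacements; sub-pixel motion
  rounds to the nearest grid shift.
* `compute_dff` is O(n log w) per neuron but still the slowest stage on
  long recordings; the rolling window is the place to shorten first when
  iterating.
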