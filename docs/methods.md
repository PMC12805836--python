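# Methods

## Lipid orientation and the flip-flop detector

Each lipid's orientation is reduced to one angle per frame. With head bead
**h** and tail-end beads **t₁**, **t₂** (one terminal bead per acyl
chain), the two head→tail vectors are taken under the minimum-image
convention (orthorhombic boxes only), normalized, and summed; the angle of
this bisector against the bilayer normal, θ = arccos(û·ẑ) in degrees, is
the per-frame observable. The normal is taken to be the box z axis, which
is appropriate for membrane systems built with the membrane in the xy
plane; no re-estimation of the normal from lipid positions is attempted.
Lipids resting in the lower leaflet (head down, tails up) sit near 0°,
upper-leaflet lipids near 180°. If the two tails are exactly antiparallel
the bisector is undefined (‖n̂₁+n̂₂‖ < 10⁻⁶); such samples are flagged
invalid and excluded downstream rather than assigned an arbitrary angle,
so degenerate geometry cannot fabricate crossings.

Raw 1 ns angle samples are noisy; denoising uses a centered moving average
over a 50 ns window, decimated to one sample every 25 ns. Windows are
truncated at the series edges, invalid samples are excluded from each
window mean, and output timestamps are the window centers. Centering was
chosen because it introduces no phase lag in event timing; the windows
overlap (stride < window), which the decimation makes harmless.

Detection is a three-zone state machine on the smoothed series. Angles
below 55° are zone A (lower leaflet), above 125° zone B (upper leaflet),
and the band in between is a buffer in which nothing is decided. A lipid's
*committed zone* updates only on valid non-buffer samples; its initial
committed zone is deferred to the first non-buffer sample (no prior state
is invented for lipids that start mid-transit). One event is emitted per
committed-zone change, carrying start = time of the last sample seen in
the origin zone and end = time of the first sample in the destination
zone; direction labels (`up->down` / `down->up`) follow the leaflet
reading of the zones above, which is also verifiable independently from
the phosphate z-trace. Excursions into the buffer that return to the
committed zone emit nothing — this is what separates a flip-flop from a
large tilt fluctuation. The detector is exactly equivalent to collapsing
the sequence of non-buffer zone labels and counting adjacent changes; the
test suite asserts that equivalence exhaustively on short series and
property-based on arbitrary ones. Widening the buffer (raising the upper
or lowering the lower threshold) can only remove events, never add them.

Rates are events per µs per replicate, averaged across replicates with the
sample standard deviation; with equal-length replicates the mean equals
pooled events over pooled time. Times are ns throughout the trajectory
domain; the rate aggregator accepts ns or µs durations explicitly to keep
the two-domain unit conventions (ns for trajectories, s for assays) from
leaking into each other.

### Event anatomy

Contact profiles scan, for each event window extended by a ±10 ns margin
(the default; recruitment and release flank the crossing itself), all
frames at full resolution: a residue is contacted by the event if any of
its beads comes within 5 Å (minimum image) of the event lipid's head bead
in at least one frame. Reported are the fraction of events each residue
contacted and the distribution of contiguous-contact dwell times. The
z-trace reports the head bead's height relative to the per-frame mean z of
all head beads (the membrane midplane estimate), positive meaning the
upper leaflet.

## The synthetic trajectory generator

The generator emulates the input statistics the detector assumes, not
membrane physics. Per lipid it schedules excursions as a Poisson process:
attempts arrive at rate `flip_rate/(1 − backslide_prob)` per µs and each
is independently aborted with probability `backslide_prob`, so *completed*
inversions arrive at `flip_rate` with Poisson-distributed counts (verified
by a χ² goodness-of-fit test at ~10⁴ events). An attempt arriving while a
transit is in progress is queued to start when it ends — one lipid is
never in two transits at once — and attempts that cannot finish before the
trajectory ends are dropped; both distortions are negligible while the
per-lipid duty cycle `flip_rate · flip_duration` stays well below 1, which
bounds the rates at which the generator is meaningful (≈ 7/µs per lipid at
the 100 ns default transit).

Completed inversions follow a logistic ramp between the resting angles
over `flip_duration` (default 100 ns, the order of magnitude of a
coarse-grained lipid inversion transit); aborted excursions rise to a peak
drawn uniformly inside (55°, 125°) and return along a sin² bump, which
exercises exactly the buffer-zone rule. Frame-to-frame angular jitter is
Gaussian with sd `angle_noise_sd`, reflected at 0° and 180° (a folded
approximation of angle noise near the poles). The default sd of 15° is a
fixture choice — large enough that unsmoothed threshold crossing would
misfire, small enough that 50 ns smoothing (variance reduction ≈ 1/50)
suppresses it — not a measured property of any force field. Defaults
(100 lipids, 10 µs at 1 ns, 1 completed flip per lipid per µs, 30 %
aborted excursions) give a dense event stream for validation; real
membrane-protein systems show per-lipid rates orders of magnitude lower,
so passing at fixture densities demonstrates detector correctness, not
performance on any specific protein.

The bead-level generator realizes the same angle program geometrically:
five beads per lipid (phosphate head, two tails of a mid and a terminal
bead), tails splayed ±25° around the intended bisector so the
head→tail-end bisector reproduces the programmed angle to float precision,
heads placed on an xy grid at ±18 Å from the midplane with the noise-free
inversion program driving z across the membrane (plus 1 Å thermal jitter).
Optional static labelled "decoy" beads stand in for protein residues in
contact-profile tests. What the generator does **not** emulate: lateral
diffusion, area fluctuations, tail conformational dynamics, membrane
undulations, protein motion, or any energetics — tests passing on it
validate the analysis chain, not simulation realism.

## The two-pool assay model

A vesicle's reporter lipid is split into an outer pool O (exposed to the
probe, initial share `outer_fraction0`, default 0.5 for symmetric
labelling) and an inner pool I. The probe removes outer-pool fluorescence
capacity at `k_probe` (first order); scrambling exchanges the pools
symmetrically at `k_scramble` — symmetric because lipid translocation
through a scramblase groove shows no directional bias. Dithionite-acted
lipid is dark (`quantum_factor` = 0); BSA-captured lipid retains
`quantum_factor` = 0.4 of its in-membrane fluorescence. The population
signal mixes scramblase-active and inactive vesicle classes with weight
`fraction_active`; heterogeneity beyond this two-class mixture (e.g.
Poisson protein occupancy per vesicle) is deliberately not modelled and is
absorbed into `fraction_active`. Dithionite permeation into vesicles and
BSA capture saturation are neglected.

The 2×2 linear system is solved by eigen-decomposition:
λ± = ½[(k_p + 2k_s) ± √(k_p² + 4k_s²)], computed with the product form
λ₋ = k_p·k_s/λ₊ to avoid cancellation at small k_s. F(t) is therefore
exactly plateau + ΣAᵢe^(−λᵢt) (at most three terms for the mixture), with
F(0) = 1 and monotone decay; no numerical integration is used anywhere
(the tests cross-check against a stiff ODE solver to 10⁻⁶). Plateau
algebra: dithionite loss = (1−qf)·[f_a + (1−f_a)·o₀] with qf = 0, BSA the
same with qf = 0.4; its inverse maps an observed loss to `fraction_active`
and refuses (rather than clamps) losses outside the attainable interval.
One guard deviates from naive algebra: a vesicle class flagged active with
`k_scramble` = 0 cannot expose its inner pool, so `plateau()` treats it as
inactive, keeping the algebra consistent with the dynamic solution's
long-time limit.

## Trace fitting

Traces are normalized to the mean pre-addition signal and re-zeroed to
probe addition (idempotent; at least one pre-addition sample required,
fewer than five warns). Fitting is ordinary (unweighted) nonlinear least
squares over the post-addition segment with bounds plateau ∈ [0, 1],
amplitudes ≥ 0, rates > 0. Initialization is deterministic: plateau from
the tail mean, slow component from a log-linear fit of the tail residual,
fast component from a log-linear fit of the early remainder — so repeated
fits are bit-identical. Components are labelled fast/slow by rate after
fitting; half-times are ln 2/k. Non-convergence returns a flagged result
with diagnostics instead of raising. A warning is issued when the trace is
shorter than five half-times of the fitted slow phase, where the
plateau/slow-rate trade-off is poorly constrained. The fitted biexponential
eigen-rates can be mapped back to (k_probe, k_scramble) by inverting
λ₊+λ₋ = k_p+2k_s, λ₊λ₋ = k_p·k_s (the branch with k_p ≥ k_s).

The scrambling verdict compares a sample's plateau loss against a
protein-free reference; the default margin of 5 percentage points is a
reporting threshold, configurable, not a statistical test.

## Numerical and scope notes

- Exponential terms with rates closer than 10⁻¹² s⁻¹ are merged; a zero
  eigenvalue contributes to the plateau, not a decay term.
- Smoothing-window length in samples is round(window/Δt); windows shorter
  than 2 samples are a configuration error.
- Detector timings inherit the smoothed/resampled grid, so detected event
  boundaries differ from generator ground truth by up to about one window;
  validation matches events by lipid, direction and midpoint within
  150 ns.
- Problem sizes in the test suite (100 lipids × 10 µs angle series, 200
  noisy traces for recovery studies) were chosen as the smallest scales at
  which the statistical assertions (sensitivity ≥ 0.95 with zero false
  positives, median slow-phase half-time error ≤ 5 %) are comfortably
  powered.
- Known limitations: orthorhombic boxes only; bilayer normal fixed to z;
  no automatic leaflet assignment from coordinates (the angle convention
  carries it); no global multi-trace fitting, drift or photobleaching
  corrections; vesicle-size distributions and probe-permeation leaks are
  out of scope.
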