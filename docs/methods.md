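# Methods

## The simulated subject

The phantom is the package's oracle: a ground-truth excitability model
against which every estimator can be scored.  Its components and defaults:

| parameter | meaning | default | units |
|---|---|---|---|
| `a_max` | recruitment-curve plateau (p2p amplitude) | 2000 | μV |
| `I₅₀` | half-maximum intensity at the hotspot | 50 | % MSO |
| `s` (slope) | sigmoid steepness | 0.3 | 1/(% MSO) |
| `c` | true hotspot centre | (−34.19, −14.33, 66.83) | mm (MNI) |
| `σ_r` (sigma) | spatial spread of the excitability field | 7 | mm |
| `amp_cv` | lognormal CV of trial amplitude | 0.3 | — |
| `baseline_rms` | background EMG noise | 5 | μV |
| `latency_mean ± sd` | MEP onset statistics | 24.05 ± 1.88 | ms |

The hotspot coordinate is the published group-mean FDI location that also
seeds the search grid; the latency defaults match typical resting FDI MEPs.
The remaining values are simulation configuration, not measured physiology:
no published noise or recruitment parameters exist for this protocol, so
they were fixed once at values a motor-mapping practitioner would call
ordinary (a 2 mV plateau, threshold near 40% MSO, ~30% amplitude
variability) and are not revisited.  Key modelling choices:

* **Multiplicative amplitude noise on the p2p scalar, not per sample.**
  MEPs enter the protocol only as one p2p value per trial, so noise is
  applied where the protocol reads it.  The lognormal is parameterized so
  its *mean* (not median) equals the noise-free amplitude; a Monte-Carlo
  test verifies mean-neutrality at 10⁴ draws.
* **Spatial attenuation acts on intensity, not amplitude.**  Moving away
  from the hotspot shifts the recruitment curve rightward (`I·w(p)`), which
  reproduces the clinically familiar behaviour that a nearby, sub-optimal
  site can yield the same MEP at higher intensity.
* **Waveform.**  The rendered MEP is one cycle of a Hann-windowed sine,
  8 ms wide, scaled so its sampled p2p equals the drawn amplitude exactly;
  it is placed at the drawn latency on Gaussian baseline noise.  Latency
  jitter is truncated to the 10–40 ms window so every synthetic MEP is
  detectable by the latency rules.
* **Pre-activation** is a 100 Hz burst spanning −80…−10 ms, sized by
  `preactivation_amp`, so the near (−50…0 ms) rejection rule can fire.

What the phantom does **not** emulate: coil physics and e-fields, multiple
muscle representations, inter-trial drift or fatigue, correlated (1/f) EMG
noise, and head/coil geometry.  Passing tests therefore demonstrate that
the *procedure logic* is correct under a stationary, unimodal excitability
landscape — not that the procedure is robust to every feature of real data.

## EMG processing

Both study-center profiles are implemented over a shared chain: 4th-order
Butterworth band-pass 10–500 Hz, p2p over 10–40 ms post-pulse, rejection
rules (≥50 μV minimum; pre-activation >25 μV from baseline in −50…0 ms or
>100 μV in −300…−100 ms; RGB additionally rejects MEP-to-baseline p2p
ratios below 160%).  Decisions where the rules are under-specified:

* **Zero-phase filtering** (forward–backward, doubling the effective
  order) is the default because causal filtering would bias every latency
  estimate by the filter's group delay.
* **"Baseline"** for the 25 μV rule is the mean over −300…−100 ms; the
  baseline-p2p window for the ratio rule is −110…−10 ms (same 30 ms width
  as the MEP window, clear of the pulse).  Both are configurable.
* **Boundary conventions:** amplitude exactly 50 μV is kept ("at least");
  ratio exactly 160% is kept ("less than" excludes); a silent baseline
  gives ratio +∞ (never excluded).
* **Differential latency rule (MUC):** first time in the window where the
  |first difference| strictly exceeds the mean |first difference| over the
  window; "absolute mean differential" is read as mean-of-absolutes, with
  `abs_of_mean` available as a switch.
* **Baseline-SD latency rule (RGB):** the 2 SD band is computed over
  −200…−100 ms.  Because baseline and MEP-window noise share statistics, a
  literal "first sample outside the band" detector fires on noise before
  the MEP roughly half the time; the rule is therefore anchored on the
  dominant post-stimulus deflection ("the first EMG peak"): locate the
  first sample reaching half the window's maximal deviation and walk
  backwards while the signal stays outside the band.  On clean high-SNR
  MEPs both rules agree within 2 ms (tested).

## Search controller

Numerical/ordering choices the protocol leaves open:

* **Visit order** is a row-major serpentine starting at the posterior,
  low-x corner — any fixed order is valid; serpentine minimizes coil
  travel.  Determinism: one seeded generator drives every draw, so a
  (phantom, seed) pair reproduces the session log bit-exactly.
* **Escalation applies to sweeps too.**  If a sweep finds no stable point
  below the ceiling, intensity rises one step and the grid is re-swept
  (the workflow's "no MEPs → raise intensity" applied grid-wide).  Failure
  — an explicit aborted result, never a silent fallback coordinate — is
  declared only when nothing responds at the ceiling.
* **Candidate selection** is lexicographic: maximal stability first, then
  mean amplitude within 10% (`candidate_tol`) of the best; a flag switches
  to joint stable-set selection.  If no point reaches 3-of-4, the points
  with maximal stability act as fallback candidates.
* **Tie-breaking** lowers intensity in 5% steps (floor: start − 10%) and
  re-tests only the tied candidates.  A round in which *every* candidate
  loses all MEPs is uninformative and is rolled back; a persistent tie at
  the floor resolves deterministically (stability, then amplitude, then
  visit order).
* **Fine stage** starts at the intensity in force at the end of the coarse
  stage and re-enters escalation if that intensity no longer elicits MEPs
  (this also recovers from tie-breaks that ended below threshold).  It can
  be disabled (`fine_stage=False`), and a run whose fine winner coincides
  with the coarse winner is reported as stage `"coarse"` — the analogue of
  a hotspot already found in the big grid.
* **Stimulation back-ends.**  `TraceStimSource` runs the full synthetic
  EMG → filter → QC chain; `ScalarStimSource` applies the same accept
  rules to the drawn amplitude directly and is the default for batch
  simulation (the two agree on matched trials; tested).  Batch studies in
  the test suite use 25–100 phantoms — enough for stable medians while
  keeping the whole suite in seconds.

The manual-search emulator is an amplitude-guided stochastic hill-climb
(Gaussian 7 mm in-plane steps, stop after 6 non-improving proposals once a
stable point is held, cap 40 points).  It exists only as a comparator with
realistically larger localization error, not as a model of any specific
experimenter.

## Threshold estimation

* **RMT staircase:** 10 pulses per level, pass = ≥5 accepted MEPs ("at
  least 50% of trials", so ≥, not exactly 5).  Steps: −2% MSO while
  passing, +1% after a failure; the estimate is the lowest passing level
  whose next-lower level failed.  Intensities are integers (stimulator
  granularity).  The level cap (60 tests) and the 100%-MSO boundary give
  explicit failure results.
* **120% RMT** is rounded half-up to the integer grid and capped at 100.
* **SI1mV hunt:** 5-pulse probe blocks anchored at 120% RMT, stepping 2%
  MSO while >0.3 mV from target, else 1%.  A single in-band block is a
  biased stopping criterion (approaching from below, the first lucky block
  stops at an intensity whose true mean is below the band), so an in-band
  block is confirmed with a 20-pulse block; unless the confirmed mean is
  within 0.05 mV of 1 mV, the neighbouring intensity toward the target is
  probed once and the closer confirmed mean wins.  Note the integer grid
  is coarse here: on the default phantom adjacent intensities have true
  means 0.85 / 1.00 / 1.15 mV, so band-edge outcomes remain possible and
  the achieved-amplitude check is intrinsically stochastic.

## Projection

* The projection origin ("geometric central point") defaults to the vertex
  centroid of the mesh; the volume centroid is exposed as an alternative
  since the two differ by millimetres on real cortical surfaces and the
  choice shifts projections.
* Rays are cast with a vectorized all-faces Möller–Trumbore test (no
  spatial index; cortical meshes intersect in milliseconds).  Of multiple
  hits the one farthest along the ray is kept, so cortical folds do not
  capture the projection — points land on the outer surface.
* An `AnalyticSphere` surface with exact quadratic intersection provides a
  closed-form validation route; the mesh path is additionally checked
  against an independent scalar triangle-scan oracle in the tests.
* Group glyphs use per-axis sample SD (n−1); the glyph radius is the
  Euclidean norm of the SD vector.

## Method comparison

Only descriptives are computed: per-method sample mean ± SD and the paired
mean difference mean(MHS) − mean(CHS), which equals the fixed-effect method
estimate in a balanced paired design.  Mixed-model inference (random
subject intercepts, covariates) is deliberately delegated to external
fitters; the module emits the long-format table they consume.

## Known limitations

* The excitability field is unimodal and stationary; multi-peak or drifting
  landscapes would exercise the tie-break logic differently.
* The scalar stimulation back-end bypasses waveform-level artifacts other
  than pre-activation.
* The MHS emulator is a caricature of manual search; only the *direction*
  of its accuracy difference versus the grid search is meaningful.
* Projection assumes the supplied mesh encloses the targets' rays; no
  volumetric segmentation is performed (a template must be supplied as a
  surface mesh).
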