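# samhs — semi-automated TMS motor hotspot search, simulated end to end

`samhs` implements a standardized grid-based search for the motor hotspot —
the scalp location where transcranial magnetic stimulation (TMS) at a given
intensity evokes the largest, most stable motor-evoked potentials (MEPs) in
a hand muscle — together with everything the procedure needs around it:
EMG trial processing and artifact rejection, resting-motor-threshold (RMT)
and SI1mV estimation, and projection of hotspot coordinates onto a cortical
surface for group visualization.  It is aimed at TMS methodologists who
want to study, tune or regression-test hotspot-search protocols without a
stimulator, a robot or a participant: every component runs against a
built-in synthetic subject ("phantom") with known ground truth.

## The model and the procedure

The phantom couples a spatial excitability field to a sigmoidal
input–output recruitment curve.  At scalp position *p* and stimulator
intensity *I* (% of maximum stimulator output, MSO) the noise-free MEP
peak-to-peak amplitude is

```
A(p, I) = a_max · σ( s · (I · w(p) − I₅₀) ),   w(p) = exp(−‖p − c‖² / 2σ_r²)
```

with hotspot centre *c*, spatial spread σ_r (mm), plateau `a_max` (μV),
half-maximum intensity `I₅₀` (% MSO) and slope `s`.  Trial-to-trial
variability is multiplicative lognormal noise on the amplitude
(mean-preserving, coefficient of variation `amp_cv`), Gaussian onset-latency
jitter confined to the 10–40 ms MEP window, baseline EMG noise, and optional
Bernoulli muscle pre-activation.

The search controller reproduces the two-stage grid protocol:

1. a coarse 4×4 grid, 10 mm spacing, centred on the group-mean FDI hotspot
   (MNI −34.19, −14.33, 66.83), starting at 45% MSO with escalation in 10%
   steps (at most 3, ceiling 75%) whenever no MEPs are detected;
2. four pulses per grid point (inter-stimulus interval 4 s, 10% jitter);
   a point is *stable* when ≥3 of 4 pulses give accepted MEPs (≥50 μV,
   artifact-free); candidates are the stable points with near-maximal mean
   amplitude, discriminated by re-testing at intensity lowered in 5% steps;
3. a fine 3×3 grid, 5 mm spacing, centred on the coarse winner, run the
   same way.  The fine winner is the motor hotspot.

Thresholds then follow the standard definitions: RMT is the lowest integer
intensity at which ≥5 of 10 pulses evoke ≥50 μV MEPs (relative-frequency
staircase); SI1mV is the intensity whose mean MEP amplitude is ~1 mV
(accepted inside 0.85–1.15 mV).  A pseudo-random "manual search" emulator
is included as a comparator, and a descriptive-statistics module mirrors
the paired method comparison (group mean ± SD and paired mean differences
on a long-format outcome table).

## Worked example

```python
import numpy as np
from samhs import (SubjectPhantom, ScalarStimSource, run_chs, estimate_rmt,
                   find_si1mv, acquire_batch, intensity_120, summarize_batch)

phantom = SubjectPhantom()                      # default synthetic subject
result = run_chs(phantom, seed=7)
print(np.round(result.position, 2), result.final_intensity, result.pulse_count)
# [-34.19 -14.33  66.83] 65.0 236

source = ScalarStimSource(phantom, np.random.default_rng(8))
rmt = estimate_rmt(source, result.position, result.final_intensity)
si = find_si1mv(source, result.position, rmt.rmt)
print(rmt.rmt, si.intensity, round(si.mean_p2p_mv, 3))
# 38 50 0.94

batch = acquire_batch(source, result.position, intensity_120(rmt.rmt), 20)
print(summarize_batch(batch)["p2p_mean_uV"])
# 486.69...
```

The search localizes the phantom's true hotspot exactly (it falls on a
fine-grid node here) after 236 pulses, ending at 65% MSO.  The RMT
staircase lands at 38% MSO — the analytic 50 μV crossing of this phantom's
recruitment curve is 37.8% — and the SI1mV hunt settles at 50% MSO, the
exact intensity whose expected amplitude is 1 mV, with a confirmed block
mean of 0.94 mV.  The 20-trial batch at 120% RMT (46% MSO) then averages
~490 μV, as expected for a stimulus 4% MSO below the half-maximum point.

A command-line interface wraps the same pipeline:

```
samhs run --phantom phantom.yaml --seed 7 --out session/
samhs thresholds --phantom phantom.yaml --hotspot session/hotspot.json --out thr.json
samhs project --mesh brain.obj --points hotspots.csv --out projected.csv
```

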