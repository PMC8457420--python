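# Methods

## The task and the trial parser

The task is a two-lever serial-order sequence: at least four presses on
lever 1 (subsequence S1) followed by at least four on lever 2 (S2) deliver
a reward in the magazine. Sessions alternate **forced** blocks (one lever
exposed at a time, so the apparatus enforces the order) and **self-paced**
blocks (both levers exposed), switching after five consecutive correct
sequences; errors trigger a 10-s timeout; sessions end at a reward target
(default 70). Event logs are timestamped at 10-ms resolution, and all bin
arithmetic uses half-open intervals [t, t+Δ). Simultaneous events are
ordered by a fixed code priority (block markers < beam < presses <
magazine < reward < timeout < light) so parsing is deterministic.

The parser partitions the stream at magazine entries. A trial opens at the
first beam crossing (or press) after the previous magazine entry and
closes at the next magazine entry; a crossing followed by a magazine
re-entry with no press is recorded as a *return to start* rather than a
trial. Classification is a total function of the press counts at closure:

- first press on lever 2 (self-paced) → incorrect start;
- < 4 S1 presses, no S2 press → break in S1;
- < 4 S1 presses, ≥ 1 S2 press (self-paced) → premature switch;
- ≥ 4 S1 presses, < 4 S2 presses → break in S2;
- ≥ 4 and ≥ 4 → correct (forced blocks require exactly 4 + 4), with
  *long-S1* flagged when S1 > 4.

Two edge cases the task description leaves open are resolved as follows
and flagged in the output: (1) lever-1 presses after the first lever-2
press do not count toward S1 (the trial is classified by the counts at
closure; all presses still count toward `n_presses`); (2) a self-paced
trial with ≥ 4 S1 presses and zero S2 presses is a break in S2 (the animal
abandoned S2 at 0 of 4 presses). Latency uses the *last* beam crossing
before the first press, since the beam sits between magazine and lever.

## The synthetic performer

`PerformerModel` generates sessions from explicit parameters; defaults are
chosen to mimic a well-trained animal and are the conditions under which
all recovery tests run:

| parameter | default | note |
|---|---|---|
| p_incorrect_start / p_break_s1 / p_premature_switch / p_break_s2 | 0.06 / 0.03 / 0.08 / 0.17 | per self-paced trial; forced trials can only break. Yields ~66% self-paced, ~80% forced correct |
| latency mean ± sd | 1.5 ± 0.8 s | floored normal, floor 0.05 s |
| inter-press interval | 0.5 ± 0.15 s | floored normal |
| transition | 1.0 ± 0.3 s | floored normal |
| s1_extra_press_geometric_p | 0.32 | extra S1 presses ~ geometric − 1, mean ≈ 2.1, so S1 ≈ 6 presses and most correct sequences are long-S1 |
| p_return | 0.01 | aborted initiations per beam crossing |

Timing variables use a normal clipped at a 0.05-s floor — the positivity
floor matters more than the exact tail shape for everything downstream.
Light trials are drawn per trial as Bernoulli(0.5) (the realized fraction
is checked, not forced); the light lasts 2 s and is triggered at the beam
crossing (pre-initiation protocol), the first press (execution protocol),
or S1 press n−2 (transition protocol; third press in forced blocks).
Optogenetic effects are deltas applied to the *generative* parameters on
light trials — never post hoc — and only to parameters the light can still
causally reach under the given protocol (the transition protocol, for
example, can only alter the transition gap). Downstream recovery is
therefore a genuine end-to-end test.

What the generator does **not** emulate: learning across days (sessions
are stationary), within-session fatigue or satiety drift, between-animal
heterogeneity (cohort animals differ only by seed), lever-press kinematics
and video, and any coupling between neural activity and behavior beyond
the programmed kernels. Passing tests show the *pipeline* recovers
programmed structure; they are not evidence about biology.

Spike trains are inhomogeneous Poisson, sampled by thinning against an
intensity tabulated on a 1-ms grid: baseline + event-locked kernels
(boxcar / ramp / Gaussian, anchored to the first press, every S1 or S2
press, the last S1 press, or the sequence end) + a per-trial offset of
`duration_gain × sequence duration` applied from 1 s before the first
press to the last press, clipped at zero. The expected-count oracle
integrates the same grid, so count-conservation checks are exact up to
Poisson error.

## Rates, rescaling, epochs

Instantaneous rate is a sum of unit-mass Gaussians (σ = 25 ms) evaluated
on a 100-Hz grid. The kernel is truncated at ±4σ and renormalized on the
discrete grid, so the integral of a trace equals the spike count exactly
whenever the kernel has full support (< 1e-4 mass would otherwise be
lost at the tails). z-scoring uses the pooled per-trial baseline bins
(−4.5 to −4 s before the first press) with a single mean/sd per unit; the
sd has a 0.1-Hz floor so near-silent units do not produce unbounded z,
and exactly-constant baselines raise a flagged exclusion.

Per-trial rescaling warps each trial's rate trace onto a canonical
template anchored at the first, second, penultimate and last press of
each subsequence (template spacing = pooled mean IPI within subsequences,
pooled mean transition between them). Each inter-anchor segment is mapped
linearly, so anchor values are preserved exactly; the second before the
first anchor and the tail after the last are carried over un-warped.
Anchors that coincide on either side are collapsed instead of creating
zero-length segments; non-monotonic anchors raise rather than being
silently reordered. Epoch means are then taken on the template:
pre-initiation (1 s before the first press), S1, transition, S2. A unit's
modulation category comes from which epochs exceed |z| ≥ 2, with the
precedence: initiation + transition → "Init S1 & S2"; initiation →
"Init & S1 execution"; S1 + S2 → "S1 & S2 execution"; transition →
"Transition (init S2)"; S2 alone → "S2 execution"; an S1-only pattern is
folded into "Init & S1 execution"; only-negative exceedances → "Negative".
The precedence is a design choice: the category names describe joint
activity at the starts of the two subsequences, and the pre-initiation
epoch is the most diagnostic, so it is tested first.

## Inference

**AUROC maps.** Each 200-ms sliding bin (10-ms step) compares the
per-trial mean rates against the pooled baseline bins with the
Mann–Whitney construction (ties count ½). Significance comes from
shuffling the test/baseline labels: p = (b+1)/(n_perm+1) with b the
permutations at least as extreme in |AUROC − 0.5| (1000 permutations;
a one-sided variant is selectable). Per-bin significance is reported
uncorrected, matching the binary-matrix convention for recruitment
summaries; corrected summaries go through the FDR utilities.

**Permutation regression.** Covariates are binned first — press counts to
even classes 2…16 (odd counts round up), latencies to 1-s classes from
0.5 s (earlier values join the first class), durations to seven
equal-count classes in descending order — then rate is regressed on class
value by OLS. p is the fraction of covariate shuffles with |r| at least
the observed (exact enumeration available at small n); acceptance
requires p < 0.05 and |r| > 0.6, with R² selectable instead of r since
both conventions circulate.

**z-difference test.** `z = (Z1 − Z2)/sqrt(1/(N1−3) + 1/(N2−3))`,
two-sided normal p; requires both unit counts above 3. A literal variant
with `1/(N2+3)` in the second term is available behind a flag for
comparison, but the symmetric Fisher-style form is the default — the
asymmetric form breaks the antisymmetry that a difference statistic must
have.

**Estimation statistics.** Paired effects flip signs of per-animal
differences (all 2ⁿ flips enumerated when 2ⁿ ≤ 4096, otherwise 5000
Monte-Carlo flips with (b+1)/(n+1) smoothing); unpaired effects shuffle
group labels (exhaustive when C(n, n₁) ≤ 10 000). CIs are 95% percentile
bootstrap over 5000 resamples — percentile rather than BCa because it is
the simplest interval consistent with the estimation-statistics
conventions used here. Proportion metrics divide category counts by the
total trials of the light condition; returns-to-start use all initiation
attempts as denominator. BH-FDR q values are computed within each
protocol × group × comparison family and flagged at q < 0.10.

**Photo-identification.** A unit is accepted as a cortico-striatal
projection neuron when the median first-spike latency over responding
pulses is strictly below 10 ms and the Pearson correlation between the
behavioral and light-evoked mean waveforms is strictly above 0.9. The
median (rather than mean or minimum) is robust to occasional spontaneous
spikes inside the window; spikes after 10 ms are ignored rather than
scored as slow responses.

## Problem sizes and numerical choices

The test suite exercises the pipeline at sizes where each guarantee is
decidable quickly: parser closure at 10 × 500 self-paced trials;
calibration of the AUROC maps on 20 seeds × two 40-trial homogeneous
Poisson units; t-test calibration at 1000 replicates; regression recovery
at 50 seeds × 60 trials (duration_gain 5 Hz/s against a 10-Hz baseline);
the optogenetic end-to-end check on 9 + 9 animal cohorts with 70-reward
sessions. Tolerances follow the statistic: exact assertions for
enumerative and closed-form quantities (1e-9…1e-12), 3-SE binomial or
Poisson bands for programmed-probability recovery, ±0.02/±0.015 bands for
type-I calibration.

Two numerical conventions worth knowing: permutation p values are never
0 (the +1 smoothing bounds them below by 1/(n_perm+1)); and Monte-Carlo
and exact permutation paths agree within Monte-Carlo error by
construction, which the suite verifies at small n.

## Known limitations

- The end-to-end optogenetic check couples a power-limited change-score
  test (9 animals, binomial proportions) with a null-control
  non-significance requirement at q < 0.10, so replicate cohorts fail it
  at a non-trivial base rate even though the per-animal deltas are
  unbiased; the suite documents the observed rate rather than relaxing
  the thresholds.
- The per-trial rescaling assumes anchor-to-anchor linearity; activity
  locked to events between anchors (e.g., individual mid-sequence
  presses) is smeared when trials differ strongly in press count.
- The transition-protocol trigger fires at the realized press n−2,
  whereas a hardware implementation estimates the penultimate press from
  the animal's mean; the simulated trigger index is therefore exactly −2
  on correct self-paced trials instead of distributed around it.
- Sliding-window AUROC bins overlap 95%, so neighboring significance
  calls are strongly correlated; recruitment curves should be read as
  smoothed summaries, not independent tests.
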