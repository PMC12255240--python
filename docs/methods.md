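# Methods

This note documents the model, the synthetic-data design, the numerical
choices and the known limitations of `kneeload`.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The loading model

The medial tibiofemoral contact force is obtained from a frontal-plane
moment balance about the lateral tibiofemoral contact point:

    F_med = −( Σ_i r_i F_i / d̂ + F_RJF / 2 + τ_KAM / d̂ )

A single sign-convention table governs every term (see
`kneeload/trial.py` and `kneeload/loads.py`):

| quantity | convention |
|---|---|
| `F_RJF` | resultant knee joint force; compression **negative** |
| `τ_KAM` | frontal-plane knee moment; adduction (medial loading) **negative** |
| `r_i`   | frontal-plane arm of structure *i* about the lateral contact point, expressed as a configured fraction of `d̂` (−0.5 = line of action through the joint centre; MCL −1.0; LCL 0.0) |
| `F_i`   | axial component `F · cos(φ(θ_knee))` of the muscle/ligament force |

With these signs every physiologically compressive term contributes
positive medial force after the leading minus.  The three hand-computable
cases (pure resultant → F/2 split; adduction moment → +τ/d̂; single muscle
term) are asserted to machine precision in the tests.

`F_RJF` is approximated quasi-statically by the vertical ground reaction
force (`F_RJF = −Fz`).  Full 3-D inverse dynamics is upstream of this
package (its net moments are pipeline *inputs*), and the same proxy is used
by the synthetic generator and the analysis path, so the generator/reducer
round trip is well-posed.  Users with true resultant forces can substitute
them at the `compute_joint_loads` boundary.

### Muscle-force reduction

Net moments are distributed in a fixed sequence — ankle, hip, then knee —
with CSA-proportional sharing inside each agonist group
(`F_m = CSA_m·M / Σ_j r_j·CSA_j`), which is the unique proportional rule
satisfying exact moment closure `Σ r_m F_m = M`.  Antagonist-direction
moments yield zero group force (muscles only pull).  The quadriceps
balances the net knee extension demand plus the knee-flexion contributions
of the *biarticular knee flexors* — hamstrings and gastrocnemius — computed
in the earlier steps.  (Descriptions of this scheme sometimes name gluteus
maximus in the knee balance; it does not cross the knee, and this package
deliberately uses the biarticular pair instead.)  Residual anterior /
posterior tibial shear goes to ACL / PCL by sign, and frontal-plane
distraction of the medial / lateral compartment to MCL / LCL, each divided
by the cosine of the configured ligament orientation.

### Coefficients are configuration, not code

Muscle cross-sectional areas, per-gender moment-arm and orientation
polynomials (with validity ranges), ligament parameters, condylar ratios
and the height-scaling reference means live in a schema-validated JSON
(`model_config.json`).  The shipped values are documented placeholders
within physiological ranges — published fits can be substituted without
touching code, and every model-level test is coefficient-agnostic (closure
and round-trip properties).  Angle inputs outside a polynomial's declared
range are clamped to the boundary with a warning; silent extrapolation of
fitted quadratics is the failure mode this guards against.

Hip and ankle arms are multiplied by `group mean height / grand mean
height` (male 1.75/1.69 = 1.0355, female 1.628/1.6895 = 0.9636) because the
underlying literature fits are not gender-specific; knee arms are, so they
are not height-scaled.

## Signal conditioning and segmentation

- 4th-order Butterworth, forward–backward (zero phase).  The second pass
  squares the magnitude response, so a sinusoid at the nominal cutoff is
  attenuated to 0.50, not 1/√2; **no cutoff correction is applied**,
  matching common motion-analysis practice.  Cutoffs: 45 Hz for ground
  reaction forces; 10 Hz (running) or 6 Hz (other movements) for kinematic
  and moment channels.
- Heel strikes: first sample at/above 20 N on the vertical force, sustained
  ≥ 10 ms.  Strides run heel strike to heel strike; at most the first five
  clean strides are kept (no NaN gaps; duration within 2 SD of the trial
  median, with a 2%-of-median floor so that near-identical durations do not
  reject one-sample timing jitter).  Stance is the contact portion of the
  stride (to the next sub-20 N sample).
- Sit-to-stand: starts where |dFz/dt| ≥ 10% of its trial peak-to-peak value
  while Fz is below the standing band; ends at the first sample from which
  Fz stays within (1 ± 0.01)·BW for 200 ms.  Stand-to-sit: starts at the
  first Fz ≤ 0.98·BW at/after the quiet-standing period; ends where
  |dFy/dt| ≤ 1% of its peak-to-peak value or |pelvis vz| < 0.02 m/s,
  whichever first.

Numerical choices for the phase equations, all deliberate:

- derivatives are central differences on a smoothed copy of the channel;
- threshold crossings resolve to the first discrete sample satisfying the
  condition (no sub-sample interpolation), consistently everywhere;
- peak-to-peak values are computed over the whole trial — the only
  parameter-free choice;
- derivative thresholds compare *absolute* values;
- the smoothing for event logic uses a 3 Hz dual-pass filter: sit–stand
  transitions evolve over ~1 s (content well below 2 Hz), while the
  derivative of 45 Hz-filtered force noise would swamp a 10%-peak-to-peak
  threshold.  This smoothing is internal to event detection; reported
  signals keep the conditioning cutoffs above;
- phase-*end* clauses and the unloading surge carry sustain requirements
  (200 ms standing band, 100 ms end clauses, 30 ms surge) plus a 100 ms
  quiet lead-in before the surge: instantaneous equality is measure-zero on
  sampled data, any smooth transition bump has interior derivative
  zero-crossings that would otherwise end the phase mid-descent, and filter
  edge transients would otherwise fake onsets at the trace boundary.  A
  clause that holds identically (e.g. pelvis vz ≡ 0) still ends the phase
  at the first post-start sample.

## Synthetic data: what it emulates, what it does not

The generators stand in for undeposited force-plate / inverse-dynamics
exports.  Design principles:

- **Band-limited construction.**  Curves are built from raised-cosine bumps
  and half-cosine steps whose spectral content lies below the conditioning
  cutoffs, so filtering cannot distort the planted truth and
  parameter-recovery tests stay sharp.
- **Invertibility by construction.**  Net moments are *constructed* from
  planted muscle forces through the same moment-arm polynomial model the
  reduction uses; within each CSA-sharing group the planted forces follow a
  common activation envelope scaled by CSA — the unique configuration the
  proportional rule can recover.  At zero noise the reduction inverts the
  generator to < 1e-9 relative error (asserted).
- **Ground-truth events by definition.**  The sit-stand generator takes
  construction knots but returns as truth the indices where its *noise-free*
  analytic channels satisfy the detection definitions, evaluated directly
  on the clean curves; recovery tests compare the detector against these.
- Noise is i.i.d. Gaussian per channel.  Defaults: 5 N on forces, 1 N·m on
  moments, 0.01 rad on angles, 0.005 m/s on pelvis velocity — plausible
  instrumentation/inverse-dynamics residual magnitudes.  Only the
  floor-plate force is generated for sit-stand (the detection equations
  consume nothing else); the seat reaction is implicit in the 30%-BW seated
  plate load.
- All channels are evaluated analytically on the 1000 Hz kinetic clock; the
  200 Hz kinematic acquisition rate constrains the bandwidth of the
  kinematic curves rather than introducing a resampling step, so no
  interpolation error enters the planted truth.
- The pseudo-ultrasound master is smoothed random speckle with two bright
  condyle-like arcs — feature-rich enough for correlation registration;
  tiles are exact crops at validated offsets (≥ 20% overlap).
- Rating tables are two-way random effects
  `y = μ + subject + rater + error` with planted variance components and
  the closed-form ICC(2,k) returned alongside.

What passing tests therefore show: the pipeline's algebra, segmentation
logic, registration and statistics are correct against known truth.  What
they cannot show: fidelity to real gait variability (trial-to-trial
correlation structure, soft-tissue artifact, marker noise spectra are not
modelled), real ultrasound physics (speckle decorrelation, probe tilt), or
the human cohort's actual effect sizes.  Demo-cohort anthropometry and
speeds are drawn around the published cohort means (heights 162.8/175.1 cm,
masses 59.9/71.8 kg, walking 1.28/1.31 m/s, running 2.71/2.97 m/s, set-speed
3.0 m/s), and the default midcondylar distances are the cohort means
(female 4.86 cm, male 5.53 cm) when no ultrasound measurement is supplied.

## Ultrasound measurement

Frames are subsampled to 10 fps from a sweep, stitched by translation-only
normalized cross-correlation (the probe slides laterally in contact, so
perspective warp is negligible and NCC is deterministic and testable);
overlapping pixels are averaged.  A correlation peak below 0.7 aborts with
an error naming the tile pair.  Condyle centres are supplied as annotation
JSON — raters click them; the package does not auto-segment.  The
calibration factor (px/cm) is a required input.  The measured intercondylar
distance is scaled to the midcondylar estimate `d̂` by a per-gender cadaver
ratio (configured; shipped placeholders 1.08 female / 1.06 male), and the
per-subject value is the grand mean over raters × repeats (a single-rater
aggregate is allowed with a logged warning).

## Statistics

- ICC convention: Shrout–Fleiss ICC(2,k) / McGraw–Wong ICC(A,k) — two-way
  random effects, absolute agreement, average of k measurements — computed
  from ANOVA mean squares; the single-measure ICC(2,1) is exposed but
  unused.  Confidence intervals use the F-bounds with Satterthwaite degrees
  of freedom, stepped up by Spearman–Brown.  Mean squares below 1e-12 of
  the between-subject mean square are treated as zero so a
  perfect-agreement table yields exactly ICC 1, SEM 0.  SEM = SD·√(1−ICC)
  in the measurement units.
- Test gating: Shapiro–Wilk per group and Levene across groups at α = 0.05;
  Levene uses the median-centred (Brown–Forsythe) variant, the robust
  default.  Failures route to Mann–Whitney U; otherwise an unpaired
  Student's t-test with the requested sidedness.  Cohen's d (pooled SD) is
  always reported.  A summary-statistics mode reproduces t and d from
  printed means/SDs, since published tables often provide nothing else;
  note that effect sizes recomputed from *rounded* summaries can differ in
  the second decimal from values computed on raw data.
- The power solver uses the noncentral t distribution (not the normal
  approximation) and brentq root-finding to 1e-6; at n = 26/group, power
  0.8, one-tailed α = 0.05 it gives d = 0.699.  Bonferroni: α/m, reported
  to 4 decimals (0.05/18 → 0.0028); the 18-test family is five movements ×
  three knee-load variables plus three speed comparisons.

## Pipeline and problem sizes

The orchestrator filters per movement class, segments, reduces, evaluates
the contact balance, extracts peaks (walking: one peak per stance half; the
classic double hump), averages over a subject's clean trials, and runs the
gender comparisons.  Trial failures are logged with stage and trial id and
skipped — exclusions must be auditable, not silent.  Everything is
deterministic under a fixed seed.

The shipped demo and the test suite run scaled-down cohorts (2–3 subjects
per gender, 1–3 trials per condition, 5 strides per gait trial, 100-trial
Monte-Carlo batches for detection and 50 for force recovery) — sizes chosen
so the full battery executes in well under a minute while keeping
Monte-Carlo error far from the asserted tolerances.  Study-scale runs
(10 walking, 5 + 5 running, 10 sit-stand trials per subject) are available
through the same interfaces.

## Known limitations

- No marker-level simulation, 3-D linked-segment inverse dynamics, seat
  reaction force, toe-off detection, treadmill handling or marker-gap
  filling.
- The quasi-static `F_RJF = −Fz` proxy ignores segment accelerations;
  swing-phase contact force is therefore underestimated (peaks, which occur
  in stance, are the reported quantities).
- Lateral compartment force, contact stress and cartilage damage
  accumulation are out of scope.
- Placeholder model coefficients are physiological but not literature fits;
  absolute load magnitudes shift with the configuration, while the closure,
  round-trip and scaling properties hold for any valid configuration.
- The symmetric percent-difference definition (|a−b| over the mean of the
  means) is used for group contrasts; relative-to-one-group definitions
  give different numbers.
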