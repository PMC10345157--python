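# Methods

This note documents the models, parameters, and numerical choices behind
`spindlesim`, stage by stage, together with the design decisions that
were genuinely open and the limitations a user should know about.

## 1. Task trajectories (synthetic-data generator)

The generator is first-class code, not a fixture: it defines the study
conditions everything downstream inherits.  Five closed planar end-point
paths are produced as dense parametric curves and resampled to `n_points
= 200` positions with equal arc-length spacing (piecewise-linear
interpolation of the cumulative chord length).  One cycle lasts 1 s, so
the end point moves at constant speed along each path and the effective
sampling rate is Fs = 200 Hz.  Each task is traversed forward (FWD) and
in reverse (REV); `reverse` revisits the identical point set in opposite
temporal order starting from the same initial point, so the two
directions differ only in their dynamics.

| task | geometry (defaults, mm) | FWD direction |
|---|---|---|
| circle | diameter 5 (arc length 15.71) | clockwise |
| line | 6 one-way on a 26.57° incline (50% grade); 12 per cycle | lower end → upper end → back |
| oscillatory | sine, amplitude 20, one spatial period over a 40 horizontal extent | left → right → retrace |
| lemniscate | 1:2 Lissajous figure-eight, rescaled to 20 tall | from the crossing, upper lobe first |
| square | side 5, axis-aligned | counterclockwise |

All tasks are centered on the **workspace center**, by default the
end-point position of the reference posture (hip 65°, knee interior
100°), ≈ (−43.9, 138.9) mm in the hip frame.  This guarantees every
sample is reachable and keeps all four muscles near their optimal
lengths.  Any other center, and a per-task line midpoint, can be set in
the config; placements far from the reference posture stretch IL and SM
several millimetres past L_max (see §2).

Two parameters deserve justification because their values are the
dominant source of freedom in the whole experiment:

- **Oscillatory spatial periods.** The generating sine has amplitude
  A = 20 mm and frequency f = 10 Hz.  Read literally against a 1 s
  cycle, 10 Hz implies ten spatial periods, a ≈ 800 mm/s end-point sweep
  that drives simulated Ia rates to 850–1750 pps — about three times the
  ~600 pps physiological ceiling for mammalian spindle afferents, and
  fast enough that the 20 samples per period barely resolve the wave.
  The default is therefore **one** spatial period of the sine swept
  across the extent and retraced (`oscillatory_spatial_periods = 1.0`;
  set `10.0` to recover the literal reading).  With one period the
  oscillatory task peaks near 190 mm/s and all afferents stay within
  physiological bounds.
- **Lemniscate scale.** The figure-eight's printed coefficients,
  interpreted in meters, span 400 mm vertically — unreachable for a
  190 mm limb.  The curve is rescaled uniformly so its taller dimension
  is `lemniscate_height = 20` mm and translated to the workspace center.

What the generator does *not* emulate: measurement noise, trial-to-trial
kinematic variability, non-constant end-point speed, or out-of-plane
motion.  Passing tests therefore demonstrate properties of the idealized
closed-cycle design, not robustness to the variability of recorded
movement data.

## 2. Limb model and musculotendon kinematics

The limb is a standard two-link revolute chain rooted at the hip
(l1 = 90, l2 = 100 mm).  Inverse kinematics is closed-form: with
c = (x² + y² − l1² − l2²)/(2 l1 l2), the knee uses the non-negative
elbow branch q2 = acos(c) ∈ [0, π] (interior anatomical knee angle
= 180° − q2) and q1 follows from the quadrant-safe two-argument
arctangent.  The reference posture (hip 65°, knee 100°) fixes the elbow
branch; forward∘inverse reproduces any reachable target to below
10⁻⁹ mm (tested on 1000 random points).  Unreachable targets and the
hip singularity raise typed errors rather than clamping.

Musculotendon lengths use constant moment arms, which are equivalent to
a linear length–angle map:

    L_mt,m(q) = L_ref,m + r_m,hip (q1 − q1_ref) + r_m,knee (q2 − q2_ref)

with L_ref = L_O = (fraction) × L_max, the optimal length at the
reference posture (85% of L_max for unifunctional muscles, 75% for the
bifunctional SM).  With the conventions *hip flexion = q1 increasing*
and *knee flexion = q2 increasing*, the signed moment arms below make
each muscle shorten during its named action:

| muscle | L_max (mm) | r hip (mm) | r knee (mm) | L_O/L_max |
|---|---|---|---|---|
| AB (hip extensor) | 70 | +30 | — | 0.85 |
| IL (hip flexor) | 70 | −44 | — | 0.85 |
| VL (knee extensor) | 50 | — | +9 | 0.85 |
| SM (hip extensor / knee flexor) | 70 | +30 | −38 | 0.75 |

Normalized fascicle kinematics are L_ce = L_mt/L_O (dimensionless, = 1
at the reference posture), with V_ce and A_ce by central finite
differences at Fs under periodic wrap (the cycles are closed; no
smoothing is applied — corner spikes in the square and at sweep
reversals are genuine signal).  The periodic cycle is then tiled
`warmup_cycles + 1 = 3` times so the spindle's initial-condition
transient decays before the final, analyzed cycle.

Hard bounds: non-positive lengths and joint angles outside the
configured anatomical range (hip 10–160°, knee interior 10–170°) always
raise.  Lengths *above* L_max only log a warning by default
(`strict_length_bounds = True` upgrades this to an error): the
oscillatory and lemniscate amplitudes combined with IL's 44 mm moment
arm legitimately carry IL/SM a few millimetres past L_max near the
workspace extremes, and the spindle model remains well-defined there
(L_ce ≈ 1.2–1.35).

## 3. Muscle-spindle afferent model

Each muscle hosts one spindle with three intrafusal fibers — dynamic
bag1, static bag2, and chain — in the tradition of mechanistic
mammalian spindle models.  Lengths are in units of L_O and tension in
normalized force units, so the sensory-region stretch is T/K_SR.  Each
fiber's tension follows a second-order dynamic:

    T'' = (K_SR/M) [ C β sign(dv) |dv|^a (L − L0_SR − T/K_SR − R)
                     + K_PR (L − L0_SR − T/K_SR − L0_PR)
                     + M A + Γ − T ],        dv = V − T'/K_SR

The fractional-power (a = 0.3) damping term models the polar region's
thixotropic behaviour; C is asymmetric (C_L = 1 lengthening, C_S = 0.42
shortening), which is what makes FWD and REV traversals of the same
path produce different afferents.  Fusimotor drive enters through a
saturating activation f = γ²/(γ² + freq²): dynamic drive modulates
bag1's damping (β = β0 + β_γ f) and active force (Γ = Γ_γ f); static
drive does the same for bag2 and chain.  Drives are constant within a
run, so the activation is held at its steady value.

Afferent potentials (pps; negative values allowed, firing rates are the
clamp at zero):

    primary(fiber)   = G (T/K_SR − (LN_SR − L0_SR))
    secondary(fiber) = G_sec [ X (L_sec/L0_SR)(T/K_SR − (LN_SR − L0_SR))
                               + (1 − X)(L_sec/L0_PR)(L − T/K_SR − L0_SR − LN_PR) ]

Ia combines the bag1 branch with the bag2 + chain branch under partial
occlusion (larger branch in full, smaller at S = 0.156); II sums the
bag2 and chain secondary endings (bag1 carries no secondary, X = 0).
The full constants table (K_SR = 10.4649, K_PR = 0.15, M = 2 × 10⁻⁴,
β0 = 0.0605/0.0822, rest and threshold lengths, gains G = 20000/10000
primary and 7250 secondary, X = 0.7, L_sec = 0.04, fusimotor freq/τ per
fiber) ships as literature defaults in `config.default_fibers()`, fully
overridable and versioned (`constants_version =
"mammalian-intrafusal-v1"`).

**Fusimotor default.** γ_dynamic = γ_static = 0 pps (passive spindle).
This is the minimal assumption; moderate drives (70–100 pps) roughly
triple the baseline rates and are a single config change.  All
discriminability conclusions below hold in both regimes; absolute pps
levels do not.

**Numerics.** Fixed-step classical RK4 at Fs with `substeps = 20`
internal steps per sample and linear interpolation of (L, V, A) between
samples; initial state is the passive fixed point at the first sample.
Twenty substeps (dt = 0.25 ms) were chosen so that halving dt changes
the output by < 0.1% RMS — the fractional damping is non-smooth at
dv = 0, which locally degrades the integrator's order and makes the
nominal step count matter.  The same non-smoothness produces a
*stiction band*: under constant input the state converges (to machine
precision) but its rest tension can settle anywhere within ~10% of the
frictionless fixed point, a history dependence that is a feature of
thixotropic models, not an integration error.  Non-finite states abort
with the fiber name and sample index.  Rates above a configurable
600 pps cap log a warning.

## 4. PCA pre-processing

Plain, explicit PCA: column centering only (no variance scaling),
covariance C = XᵀX/n, symmetric eigendecomposition, eigenvalues sorted
descending (tiny negative rounding clipped to zero), components' signs
fixed so each one's largest-magnitude loading is positive.  The
combined-muscle analysis fits one model on the pooled 2000 × 8 matrix
(10 conditions × 200 samples) and projects each condition with the
*shared* basis — a single basis is what makes cross-condition
correlations comparable; per-muscle analyses do the same on the pooled
2000 × 2 blocks.  k = 3 combined and k = 2 per muscle.  Rank-deficient
input is permitted; k > d, non-finite data, and n ≤ d raise.

## 5. Discriminability analysis

`xcorr_max` slides one multichannel block past the other along time
only, circularly (the cycles are closed 1 s loops, so every lag is
meaningful), and reports the maximum of the **uncentered** normalized
correlation of the flattened blocks, max_τ ⟨a_τ, b⟩/(‖a‖‖b‖), together
with its lag (ties break toward the smallest lag).  The uncentered
(cosine) form is deliberate and is the pivotal analysis choice of the
package: raw firing rates are non-negative with a large shared baseline,
so raw-space values cluster high and movements look alike; PCA scores
are centered by the pooled mean, so the identical statistic spans both
signs after pre-processing.  Mean-subtracted variants were evaluated and
erase this raw-versus-PCA contrast almost entirely (the top-3 projection
alone is a near-isometry of the 8-D data).  The maximum is over signed R
(not |R|): perfect anticorrelation is informative, not similar.  Blocks
that are constant in every channel raise an undefined-correlation error
rather than returning a number.

Derived statistics over the 45 unordered condition pairs: the
discriminability percentage (share of pairs with R_max below the 0.5
threshold — the midpoint of the positive range, i.e. chance level —
reported both exact and rounded to integer), the span metric
(α = max − min of the 45 values, β = 2, percent = 100 α/β), 10 × 10
similarity confusion matrices with cells (R + 1)/2 and unit diagonal,
and a two-sided Wilcoxon signed-rank test pairing the 45 raw values with
the 45 PCA-space values (scipy implementation; identical sets raise a
degenerate-test error, which the pipeline records rather than crashes).

The unsupervised baseline is a from-scratch K-means++ (D²-weighted
seeding, Lloyd iterations to 10⁻⁸ centroid motion or 300 iterations,
10 seeded restarts keeping the best inertia; empty clusters reseed to
the farthest point) with the cluster count chosen by maximizing the
mean silhouette over k = 2…9 (ties to the smaller k; k = 1 falls back
to the smallest allowed k since the silhouette is undefined there).  On
the default run it selects k = 2 — nowhere near the ten overlapping
task-direction clusters — which is the motivating failure of spatial
clustering that the correlation analysis addresses.

## 6. Pipeline, determinism, and problem sizes

`run_experiment` executes the stages in order and returns (optionally
writes) a machine-readable report with a provenance block (config hash,
constants version, timestamp).  Everything is deterministic given the
config: the only random element is K-means++ seeding, which is
seed-controlled, so two runs differ only in the timestamp.  The default
problem is deliberately desk-scale — 10 conditions × 600 simulated
samples × 12 intrafusal fibers, a 2000 × 8 PCA, and 10 correlation sets
of 45 pairs × 200 lags — and completes in ~25 s on one CPU; the test
suite adds refinement and oracle checks and runs in ~2 minutes.

## 7. Fidelity and known limitations

Reference values exist for this experimental design, and the package
reproduces its structural and directional results exactly: 45 pairs;
raw-space correlations tightly clustered in the high positive band with
a small span; PCA strictly increasing the discriminability of the
combined set *and* of every individual muscle; the span expanding
several-fold under pre-processing; VL the least discriminable muscle in
the raw space (0%); PC1 > PC2 > PC3 with ≥ 96% of pooled variance in
three components; and a significant raw-versus-PCA Wilcoxon comparison.
The *absolute* percentages, however, sit below the reference values
(combined 0% → 53% here versus 29% → 82%; PC1/PC2 share 77/16 versus
70/29).  These absolute levels are controlled by quantities that are
not fixed by the design and had to be chosen here on a-priori grounds:
the fusimotor drive (passive default), the intrafusal constants table,
the workspace placement of each task (a shared reference-posture
center; per-task placements would differentiate the muscles' operating
points and raise raw-space structure), and the oscillatory reading
(§1).  Users comparing against their own reference numbers should
treat those four knobs — all in the config — as the sensitivity
frontier.
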