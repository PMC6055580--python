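# Methods

## Model

The habitat is a one-dimensional column of `n_sectors` equal sectors
(default 10 sectors × 0.1 m × 0.6 L). The 0.6 L sector volume makes the
total 6 L, which reconciles the experimental stocking range (1–360
individuals) with the reported density range (0.166–62 ind/L). Each sector
carries a food concentration (mg C/L), a light intensity (relative
units), a red/green/blue spectral weight vector, and a column-wide
predator-cue flag. Gradients are exponential in depth, evaluated at sector
midpoints; light attenuation is physically exponential and the food
profile is configurable (any per-sector vector can be supplied).

Each virtual animal scores a sector by the Werner–Gilliam fitness ratio
GR/mu. For GR ≤ 0 the ratio is misleading (higher mortality would *raise*
it), so non-positive-growth states are scored GR·L — a negative number
that ranks them by growth alone and always below any positive-growth
state.

Growth is Monod in food with additive linear costs of density, log10(1 +
light) (so darkness stays finite) and predator cues. Predation mortality
is per-capita risk P·C(N)/N from a threshold disc equation whose attack
(clearance) rate is derived from the fish's visual reaction distance: a
fish cruising at v cm/s sweeps a cylinder of radius RD, so a =
pi·RD²·v·86.4 L/day. RD = (r0 + k·log10(1+light) + l·[adult]) × (w_red·alpha
+ w_green + w_blue·phi). Since no fish were physically present in the
verification columns — risk is *information* — predation mortality (and
the kairomone growth cost) applies only when the predator-cue flag is on;
in the no-gradient and food-only treatments the only density feedback is
interference, and the simulated distribution is driven by crowding alone.

Updates are asynchronous: one time step visits every animal once in a
fresh random permutation; each compares the perceived fitness of staying
with that of the two adjacent sectors, using the occupancy left by earlier
movers. A candidate sector's density counts the prospective mover
((occupancy+1)/volume); the current sector's occupancy already includes
the agent. Ties (within a relative 1e-12) are broken uniformly at random,
including the stay option — a strict stay rule would freeze a point
release forever, whereas the uniform tie-break produces the observed
uniform spread (mean depth 0.5 m) in the absence of gradients. Perception
is imperfect: a candidate's food (light) is replaced by the current
sector's value when the relative difference is below the detection
threshold ae_F (ae_I). The thresholds act deterministically; a
probabilistic error model would be a drop-in replacement at the same hook.
Demography is frozen — mortality enters only through the fitness
denominator.

The sweep kernel is compiled with numba when available (a pure-Python
backend with identical semantics is kept and cross-checked in the tests).
Replicate r of a batch draws its random stream from
`SeedSequence((seed, r))`, making every trajectory bit-reproducible.

## Default parameterization

Coefficient magnitudes are not printed in the source material, so defaults
were fixed once from field-plausible scales and two structural
calibrations, and are all configurable:

| parameter | default | rationale |
|---|---|---|
| g0, a1, a2 | 0.05, 0.35 /d, 0.164 mg C/L | max juvenile growth ~0.4 /d; half-saturation well below the 0.8 mg C/L incipient level |
| b | 0.001 /d per ind/L | interference noticeable only at crowded densities (≥100 ind/L) |
| c, u | 0.005, 0.010 /d per log10 unit | light cost small; adult interaction is the significant term |
| kappa | 0.02 /d | predator-cue cost of the order of background mortality |
| r0, k, l | 0.5, 1.5, 1.3 cm | RD of a few cm at laboratory light; the adult increment reflects the ~1.66× body-length ratio of adults to juveniles |
| alpha, phi | 0.6, 1.0 | RD lower in red, equal in green and blue |
| gamma | 3.4158 (juv) / 0.0342 (ad) ind/L | fitted juvenile threshold; adult = two orders lower |
| n, h | 2, 1e-8 d | classic type III exponent; handling small (see below) |
| P | 4.1e-6 /L | calibrated so low-density type II fish mortality at mid-column light equals background (1/50 d) |
| ae_F | 0.19 (juv) / 0.08 (ad) | relative food-difference detection thresholds |
| ae_I | 0.10 | light-difference threshold (literature-scale default) |
| food gradient | 0.8 mg C/L surface, 3.0 /m | adjacent-sector differences (~26%) exceed both ae_F values, so the gradient is perceptible to both age classes |
| light gradient | 100 surface, 4.6 /m | ~60-fold surface-to-bottom contrast |

Two calibration notes. First, the disc equation contains a
safety-in-numbers effect: when a·h·N approaches 1 at swarm densities, a
dense aggregation dilutes per-capita risk enough to become a refuge, and a
point release never disperses. The observed regime — risk driving animals
into deep strata across the whole 1–360 range — requires that saturation
be negligible at column densities, hence the small handling time; the
density dependence of risk then comes from the type III threshold and the
interference term. Second, the food attenuation of 3.0 /m was chosen so
that adjacent-sector food steps are visible to juveniles (threshold 0.19):
with a shallower gradient juveniles are blind to the food *loss* when
moving down but still see the gain when moving up, an asymmetry that makes
them sink through the food gradient and invert the adult/juvenile depth
ordering.

Whether the detection thresholds are relative or absolute is not
documented; they are treated as relative differences (0.19/0.08 are
plausible fractions). The mapping from the measured growth slowdowns to
the thresholds is likewise not reconstructible, so the perception-cost
estimator returns the percent slowdown and the thresholds are set directly
in configuration.

## Estimation

All fits are ordinary least squares (a Poisson-style loss was considered
and left out; the trials report means per session, not counts).
The functional-response fit is multi-started — attack from the slope
through the low-density points, handling from 1/max(C), gamma from the
largest density with near-zero consumption and from 0, n in {1,2,3} —
because the threshold creates flat, multimodal error surfaces. Type II
(gamma=0, n=1) is nested in type III; the primary selection criterion is
the extra-sum-of-squares F-test on two parameters, with AIC reported
alongside, and a numerically negligible SSE improvement counts as none
(parsimony on noiseless data). The growth fit drops factors without
variation (naming them) and reports per-coefficient Wald tests; raw
estimates keep their sign while the derived parameter object clips to the
physical domain. The reaction-distance fit fixes the green band multiplier
at 1 as the identification gauge and reports red-vs-green and
blue-vs-green contrasts against 1.

## Distribution statistics

Each experiment or simulation batch is summarized by its mean depth
(fractions × sector midpoints). Two-group comparisons are standard ANCOVA
with density as covariate: slope homogeneity first (density×group
interaction F); the intercept test, computed under the pooled-slope model,
is reported only when slopes do not differ. The battery runs 12
experiment-side contrasts (age within each treatment; treatment pairs
within each age) at family alpha/12 and the experiment-vs-simulation
contrasts (2 ages × 4 treatments × 2 response types) at alpha/4, with
explicit missing-comparison rows for empty cells. Column side is carried
as a blocking label but not tested. Bonferroni levels are reported at
3 significant figures (0.00417 for 12 comparisons, 0.0125 for 4).

## Synthetic data

Generators plant known truths and add Gaussian noise clipped at zero
(responses are non-negative rates/distances; a lognormal option would slot
into the same hook). Defaults: feeding sessions at 15 densities spanning
0.5–60 ind/L × 2 replicates with noise SD 8 prey/d (~4% of the plateau);
growth trials over a 6 food × 2 density × 2 light × 2 age × 2 kairomone
factorial × 2 chambers with SD 0.02 /d (the scale of the observed growth
SDs); reaction-distance trials over 3 light × 3 band × 2 age × 3 trials
with SD 0.3 cm. These replicate counts give the planted-effect tests
(adult×light interaction, foraging threshold) comfortably more than 80%
power at alpha 0.05.

Pseudo-experiment records run the IBM itself over the treatment × age ×
density grid, then re-observe each animal's sector twice with
misclassification probability epsilon = 0.05 (observed sector = true with
probability 1−epsilon, else an adjacent one) and average the two counts.
The paired growth generator follows one focal animal through a
food-gradient run and integrates the growth rate over the sectors it
occupied during the final 20-step stable window (the short measurement
phase after gradient establishment); this mechanism yields both a mean
deficit and a wider between-animal spread than the homogeneous arm, whose
SD is pure measurement noise (0.013 /d). A `target_deficit` knob rescales
the gradient-arm mean to plant an exact percent slowdown (default 9.2 for
juveniles; 4.7 for adults) while keeping the location-driven spread.

## What the synthetic data do not show

The generators share the very rate equations the estimators fit, so
recovery tests demonstrate correctness of the fitting machinery, not of
the functional forms; real feeding, growth and reaction-distance data
could prefer different shapes. Counting noise is independent across
animals, unlike a human counter's correlated errors. The pseudo
-experiments inherit the IBM's own behavioral rules, so
experiment-vs-simulation batteries on them test the statistical pipeline,
not the biology. Real *Daphnia* behaviors outside the model — directed
swimming toward subsurface layers ("evolutionary memory"), diel timing,
physiological state — are absent by design.

## Problem sizes and numerics

Default protocol: 200 steps, first 100 discarded as burn-in, 100
replicates, release in the fifth sector from the top. The analysis drivers
use 20 replicates per grid cell; behavioral ordering checks use 20 matched
replicates and one-sided sign tests; power checks use 200 seeds. Fits use
`scipy.optimize.least_squares` (trf, tolerances 1e-14) with standard
errors from the Jacobian at the solution. Fitness ties in the simulator
are resolved at relative tolerance 1e-12 — exact in practice, since
perceived-equal options share the same arithmetic path. Degenerate inputs
(zero-density rows, empty comparison cells, single-level factors) are
dropped, reported or rejected with named errors rather than propagated as
NaN.

## Known limitations

- The type II/III dichotomy is hard-wired to the threshold-disc family;
  sigmoid (Hill-type) type III responses are representable only through
  the exponent n.
- No within-sector position, continuous swimming, or reactive predators.
- The age contrast in simulated depths (adults deeper) is expressed at
  low-to-moderate densities, where the juvenile threshold refuge operates;
  at high densities the additive reaction-distance form gives juveniles
  the steeper relative risk gradient and the ordering can invert.
- No bootstrap confidence intervals in the fitting stage (hook provided);
  no depletion-corrected (random-predator) functional response.
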