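# Methods

## Geometric model

The carpal tunnel is idealized as a frustum (truncated cone) of height
`L` with circular inlet (radius `r2`, scaphoid–pisiform level) and
outlet (radius `r1`, trapezium–hamate-hook level) cross-sections:

    V = (1/3) · π · L · (r1² + r1·r2 + r2²).

The outlet radius depends on the curvature angle α of the hook of the
hamate. Treating the hook as a triangle with fixed side lengths and
applying the law of cosines, the chord spanning the outlet satisfies
`(2·r1)² = B · (1 − cos α)` for a constant `B` that absorbs the bone
dimensions, hence

    r1(α) = √(B · (1 − cos α)) / 2.

`B` is calibrated once from a reference measurement pair
(r1₀ = 8.29 mm at α₀ = 98°): B = (2·r1₀)² / (1 − cos α₀). The model's
assumptions are strong and explicit: cross-sections are perfect
circles, the taper is linear, only the outlet responds to the hook
angle, and bone side lengths do not change as the angle changes. Real
tunnels violate all of these to some degree; the model is a controlled
way to ask how much volume an angle change *could* move, not a
reconstruction of any individual wrist.

### Numeric conventions

The reference table this model reproduces was evidently produced with
mixed precision, and those conventions are first-class, configurable
parameters rather than incidental behavior:

- **π:** full-precision `math.pi` for degree→radian conversion and
  area↔radius conversion; the rounded literal `pi_volume = 3.14` inside
  the volume formula (its default).
- **cos α₀ rounding:** the reference cosine is rounded to
  `cos_decimals = 3` places (−0.139) before calibration, while the
  sweep itself uses full-precision cosines. Pass `"full"` to disable.
- **B truncation:** the calibrated B is truncated (toward zero, not
  rounded) to `b_decimals = 2` places, giving B = 241.34 from the raw
  241.3489. Truncation matters: rounding would give 241.35, and the
  reference table's r1 column back-solves to 241.34 exactly in every
  row. Printed source values elsewhere show the same truncation
  convention (e.g. r2 = 9.8369 from the full-precision 9.83698).
  Pass `"full"` to keep the raw value.
- **Angle domain:** curvature angles live on (0°, 180°]. The
  straight-line limit α = 180° (cos α = −1) is geometrically
  well-defined and accepted; zero and reflex angles are rejected
  rather than wrapped, since a curvature angle has no meaning past a
  straight line. The degenerate α₀ → 0 calibration (division by zero)
  raises.
- **Units:** mm / mm² / mm³ throughout, the natural scale of wrist
  anatomy; the source measurements carry no explicit units.
- Table rows are stored and written to CSV at full floating precision;
  any rounding for display happens in the CLI layer only.

With the default conventions the 22-row sweep (98°–140°, step 2°,
r2 = 9.8369 mm, L = 19.4 mm) reproduces the reference table to
|Δr1| < 1e−7 mm and |ΔV| < 1e−3 mm³, comfortably inside the test
tolerances (1e−3 mm, 0.05 mm³) that allow for the reference's own
print truncation.

## Synthetic cohort generator

No subject-level data are available for the emulated study, so cohorts
are simulated with the published summary structure as defaults:

| parameter | default | meaning |
|---|---|---|
| `n` | 91 | cohort size |
| `male_fraction` | 51/91 | Bernoulli probability of male sex |
| `angle_mean`, `angle_sd` | 122.55°, 8.20° | parent normal of the true hook angle |
| `angle_min`, `angle_max` | 97.20°, 139.31° | truncation bounds (observed range) |
| `measurement_sd` | 0.5° | SD of each of the three repeat measurements |
| `age_params` | shifted gammas | per-sex age model (below) |
| `seed` | 0 | PRNG seed; same config ⇒ byte-identical CSV |

The truncated normal is the simplest distribution matching the
reported mean, SD and range; it is sampled by rejection (exact, and
cheap at an ~99.97% acceptance rate for the default bounds). Each
subject's three recorded measurements add independent N(0,
`measurement_sd`) noise to the true angle and are averaged, mirroring
a triplicate measurement protocol; 0.5° is a deliberately small
default against the 8.2° between-subject SD, since no repeatability
figure is published, and it is freely overridable. Ages follow
`loc + Gamma(shape, scale)` per sex — a right-skewed shape typical of
adult imaging cohorts — parameterized so the overall median lands near
34 years with the female median above the male median (male: loc 10,
shape 2.0, scale 12.5; female: loc 10, shape 2.6, scale 11.5). The
generator does not enforce an adult-age floor (the emulated study's
stated inclusion criterion and reported age range disagree; the config
is authoritative). Per-subject inlet/outlet areas and tunnel length
are *not* simulated: the geometric reference set (216 mm², 304 mm²,
19.4 mm) was measured once, and simulating anatomy the source never
measured would manufacture structure.

What passing tests show — and do not show — about real data: the
generator reproduces the *marginal* summaries of the emulated cohort
(sex split, angle mean/SD/range, age skew and ordering) and makes
angle independent of sex by construction. Real measurement error may
be non-Gaussian or angle-dependent, real angle–sex or angle–age
associations may exist, and real tunnels are not frusta; conclusions
from the synthetic pipeline are about the model and the statistical
machinery, not about wrists.

## Statistical stage

- **Descriptives:** n, mean, sample SD (n−1 denominator), median
  (midpoint for even n), min, max.
- **Normality:** Shapiro–Wilk via `scipy.stats.shapiro`, with the
  accept/reject decision at the configured α level recorded in the
  result. Constant samples and n < 3 are rejected as degenerate.
- **Mann–Whitney U:** authored in-package from midranks. *Exact* mode
  enumerates every assignment of the pooled observations to the two
  groups and reports P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|), valid with
  ties because the enumeration is over the observed data (the
  permutation distribution of U is symmetric about n₁n₂/2: negating
  the pooled values maps each assignment's U to n₁n₂ − U).
  *Approximate* mode uses the normal approximation with the midrank
  tie correction and a 0.5 continuity correction. *Auto* (default)
  picks exact while C(n₁+n₂, n₁) ≤ 20 000 assignments. Two-sided
  p-values throughout, as everywhere in the package.
- **Correlation:** Pearson and Spearman (Pearson on midranks) via
  scipy, both reported since neither is canonical for this design;
  Spearman is the one that is exactly 1 for the deterministic
  angle→volume map.
- **Cutoff search:** candidate thresholds are midpoints between
  consecutive distinct values (plus open ends); the report carries the
  Youden-J–maximizing threshold, the empirical AUC
  (`sklearn.metrics.roc_auc_score`, orientation-corrected when
  AUC < 0.5), and a "no suitable cutoff" verdict when the Mann–Whitney
  test of the two classes does not reject at the α level — the
  operational reading of a failed cutoff search, justified by the
  identity AUC = U/(n₁n₂). The label column defaults to sex (male = 1)
  and is the caller's choice.
- **Cohort analysis:** per-subject volumes from the calibrated model
  applied to each mean angle, summaries overall and by sex,
  normality decisions, sex comparisons of angle and age, angle–volume
  correlations, and the sex-label cutoff search, as one JSON-ready
  report. Procedures needing both sexes or a minimum n are marked
  `skipped` instead of raising. A paired t-test is deliberately absent:
  the emulated analysis plan names one but reports no paired
  comparison, so there is nothing to mirror.

## Verification design

Every closed form is checked against an independent route: frustum
volume against quadrature of the solid of revolution π·r(z)² dz
(100 random geometries, relative error ≤ 1e−6); exact Mann–Whitney
against a brute-force pair-counting enumeration (and the approximate
mode against scipy's asymptotic test); Spearman against
rank-then-Pearson; the cutoff AUC against U/(n₁n₂); the generator's
truncated-normal moments against `scipy.stats.truncnorm` (mean within
0.1°, SD within 2% at n = 10⁵). Stochastic calibration checks use the
study's group sizes: rank-sum type-I error in [0.03, 0.07] at nominal
0.05 over 2000 null simulations at 40 vs 51, and the null uniformity
of the sex-vs-angle p-value over 500 seeded cohorts (Kolmogorov
distance < 0.1). These simulation sizes keep the full suite under half
a minute while leaving comfortable statistical margins.

## Known limitations

- The frustum idealization ignores non-circular cross-sections,
  nonlinear taper, and soft-tissue contents; the angle→volume map is
  exact only within the model.
- The calibration inherits the reference measurement's print precision;
  `cos_decimals`/`b_decimals` make that inheritance explicit but cannot
  remove it.
- The cohort generator matches marginal summaries only; it encodes no
  angle–sex, angle–age, or angle–anatomy dependence.
- The cutoff search's "suitable" criterion (AUC significance gate) is
  one reasonable operationalization among several; with very small
  classes no cutoff can ever be declared (the minimum attainable p
  exceeds α).
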