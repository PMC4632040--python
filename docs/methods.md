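# Methods

`spinedyn` quantifies the dynamics and morphology of dendritic
protrusions — spines and filopodia — from tabular annotations of
time-lapse imaging, the way in vivo two-photon spine-imaging studies
analyse their data: classify each protrusion, re-identify it across two
imaging sessions, and summarise formation, elimination and turnover per
dendrite and per condition. A synthetic-data generator with known ground
truth makes every stage verifiable without microscopy data.

## Data model

A protrusion observation is a point on a 1-D dendrite backbone arc
(position in μm) with three morphometric measurements: head width, neck
width and total length (μm). A dendrite frame is the set of observations
for one dendrite at one timepoint, with genotype (control vs mutant),
age (weeks) and imaging interval metadata. The backbone is treated as a
1-D arc; projections are analysed as measured, with no z-correction.
Optional SWC reconstructions supply backbone arc length for unbranched
paths.

## Classification

A protrusion is a **filopodium** iff head/neck width ratio < 1.2 *and*
length/neck ratio > 3; every other protrusion is a **spine**. Both
comparisons are strict, so boundary values fall to the spine class, and
the rule is invariant to common rescaling of the three measurements.
Both criteria are combined with AND because they jointly describe the
"long, thin" filopodial phenotype; the thresholds are configurable
(`head_neck_ratio_max`, `length_neck_ratio_min`).

Per-dendrite statistics (density per μm, class percentages) are computed
per dendrite and then averaged across dendrites with SEM over n
dendrites — the unit of analysis throughout is the dendrite, which is
why a mean of per-dendrite ratios need not equal the ratio of pooled
counts. Dendrites with no protrusions have defined densities (0) but
undefined percentages and rates; they are excluded from those group
means and logged.

## Identity tracking

Two sessions of the same dendrite are first brought into register by a
global arc offset: the shift minimising the median absolute distance
from each frame-2 protrusion to its nearest frame-1 protrusion (a
piecewise-linear objective minimised over the candidate pairwise
differences), then polished by two rounds of re-estimation as the mean
displacement of the optimal within-cap assignment. The polish matters:
the raw median-objective minimiser has roughly twice the dispersion of
the assignment-mean estimator, which leaves |offset| < 0.1 μm in ≈97% of
default-jitter simulations.

After alignment, identity is a one-to-one assignment that (1) maximises
the number of pairs with displacement ≤ the cap (0.7 μm by default:
protrusions further from their expected position are different
protrusions) and (2) minimises total displacement among those — i.e. the
fewest events compatible with the cap, most parsimoniously. It is solved
as a rectangular assignment problem with a prohibitive cost on
out-of-cap pairs; exact cost ties break deterministically towards pairs
of smaller arc positions. Unmatched frame-1 protrusions are eliminated,
unmatched frame-2 protrusions formed.

**Matching scope.** By default the pipeline matches identity *within*
each measured class (`matching_scope: by_class`, after a single
alignment of the full frames). Position-only pooled matching swaps the
identities of adjacent protrusions whose jitter makes them cross; when
the neighbours differ in class, such a swap fabricates a formation plus
an elimination under within-class accounting (at default densities and
jitter this inflates 1 h spine rates by ≈2 percentage points). Manual
analysts use morphology to maintain identity, and class-scoped matching
encodes exactly that. A protrusion that changes class is then an
elimination in the old class and a formation in the new one, keeping the
per-class conservation identities exact. `matching_scope: pooled`
retains position-only matching over all protrusions, with the
class-transition convention (`within_class` or `persistence`) applied to
class-changing matched pairs.

**Known limitation.** Any distance-cap rule — manual or automated —
cannot distinguish a protrusion that persisted from an independent
elimination plus a formation within the cap window. At 1 h control event
rates this ambiguity touches ≈3% of dendrites; at 48 h mutant rates
(≈2.3 spines formed and ≈2.8 eliminated per dendrite) it cancels ≈9% of
true events, so measured 48 h rates sit slightly below the generating
probabilities. This is a property of the measurement rule, not an
implementation artifact.

## Rates

With F formed, E eliminated and N total protrusions of the relevant
class (frame-1 count by default; a "union" denominator is available):

- formation rate = 100·F/N, elimination rate = 100·E/N (percent),
- turnover rate = 100·(F+E)/(2N) ≡ the mean of the two rates.

The frame-1 denominator keeps elimination ≤ 100% and makes the turnover
identity exact; dendrites with N = 0 in a class are excluded from that
class's averages and logged. Condition summaries are mean ± SEM over
dendrites; a single-dendrite condition reports SEM 0 with a warning.

## Statistics

- **Unpaired Student t-test**, pooled variance, two-tailed (Welch behind
  a flag); zero pooled variance degenerates to t = 0, p = 1 (equal
  means) or p = 0 flagged (unequal).
- **Two-sample Kolmogorov–Smirnov** on pooled morphometric
  distributions: D = sup |ECDF₁ − ECDF₂|, p from the asymptotic
  Kolmogorov distribution at √(n₁n₂/(n₁+n₂))·D. Pooled protrusion
  samples in this setting are in the hundreds, so the asymptotic p is
  adequate.
- **Two-way ANOVA** (genotype × age, with interaction) via an OLS
  sums-of-squares decomposition — Type I on balanced designs (where all
  types coincide), Type II fallback on unbalanced ones, logged —
  followed by **Bonferroni-corrected genotype contrasts within each
  age** using the pooled ANOVA error term; the family size defaults to
  the number of ages and is configurable. One-way ANOVA + Tukey HSD are
  provided as companions.

The t statistic, KS statistic, contrasts and Bonferroni adjustment are
computed directly; tail probabilities come from scipy and the ANOVA
table from statsmodels OLS/anova_lm.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
per dendrite:

1. **Frame 1**: protrusion count ~ Poisson(density × length) — the
   maximum-entropy choice given that only mean densities are reported —
   positions uniform on the arc, class ~ Bernoulli(filopodium fraction),
   morphometry from class-conditional log-normals (widths and lengths
   are positive and right-skewed). Defaults centre spines at head/neck ≈
   1.8 and filopodia at head/neck ≈ 1.0 with length/neck ≈ 5.5, giving
   ≈99% agreement between generating class and the ratio classifier.
2. **Frame 2**: each protrusion is independently eliminated with its
   class probability; survivors keep identity and morphometry and
   receive zero-mean Gaussian positional jitter (default SD 0.15 μm,
   well under half the 0.7 μm cap so correspondences are recoverable).
   New protrusions arrive with per-class Poisson budgets with mean =
   class formation probability × class count in frame 1, uniform
   positions, fresh morphometry. A newborn carries the class of its
   budget, which makes the per-class rate estimators unbiased for the
   generating probabilities; `nascent_filopodium_fraction` optionally
   re-mixes newborn classes for sensitivity analyses (at the cost of
   that unbiasedness), since the class of nascent protrusions is not an
   observable of the two-frame design.
3. Morphometry is retained across frames for survivors because
   protrusion shape is stable relative to the imaging interval; this
   also keeps classification consistent between frames.

Packaged condition presets carry the reported group values of a
developmental SCA1 imaging study: cortical densities ≈0.28–0.38/μm,
filopodium fractions 10–24%, 1 h spine formation/elimination
probabilities 2–13% (control vs mutant, 4/6/8 weeks), 48 h spine rates
8–28%, 1 h filopodium rates 14–42%, and hippocampal cross-sections at
1.28–1.66/μm with morphometry scale shifts for the mutant groups (head
width × 0.85 at 12 weeks emulating the left-shifted width distribution;
length × 1.05–1.10 emulating the right-shifted length distribution —
magnitudes chosen as plausible, since only distribution curves are
reported). An optional `rate_dispersion` parameter Beta-disperses the
event probabilities between dendrites (animal-level heterogeneity); it
defaults to 0.

Randomness: one global seed; per-dendrite substreams are derived
deterministically from (seed, condition label, dendrite id), so partial
re-runs reproduce identical dendrites and a fixed seed fixes the whole
dataset byte-for-byte.

**What the generator does not emulate:** spatial clustering of
protrusions along the dendrite (placement is uniform), within-interval
birth-then-death at 48 h, correlated elimination among neighbours,
measurement error on morphometry beyond the log-normal draw, and 3-D
geometry (the backbone is a 1-D arc). Passing tests therefore validate
the estimators under these idealisations, not the imaging or tracing
steps that precede annotation in real data.

## Numerical choices

- Assignment ties are broken by a lexicographic-rank perturbation ~1e-9,
  far below any physical displacement scale.
- Densities, rates and percentages keep full precision internally; the
  human-readable report rounds to 2 significant figures.
- Tables are tab-delimited UTF-8, comma sniffed on read, '.' decimal,
  full-precision (%.10g) floats on write; every pipeline table carries a
  12-hex config hash and tables from different configurations refuse to
  mix.
- Problem sizes: simulation-backed tests use 200–1000 dendrites per
  check and the acceptance script 2000 per condition, enough to pin
  cohort means to a few tenths of a percentage point while keeping runs
  in seconds to minutes.

## Known limitations

- Two frames only; no multi-session trajectory linking or lifetime
  survival analysis.
- The 0.7 μm rule's birth–death ambiguity biases high-event-rate (48 h)
  measurements downward by up to ~10% relative, as quantified above.
- Neck width must be positive; stubby protrusions without a measurable
  neck need an imputation convention upstream of the annotation table.
- The statistics treat dendrites as independent; animal-level clustering
  is not modelled (no mixed effects), matching the analysis convention
  of the source study design.
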