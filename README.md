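# spinedyn

Quantification of dendritic-protrusion dynamics from time-lapse imaging
annotations: spine/filopodium classification, longitudinal identity
tracking, formation/elimination/turnover statistics, and the group
comparisons used in in vivo two-photon spine-imaging studies — plus a
synthetic-data generator with known ground truth so every stage of the
pipeline can be validated without microscopy data.

## The problem

In vivo two-photon imaging of fluorescently labelled neurons lets one
follow the same dendrite across sessions and watch individual
postsynaptic protrusions appear and disappear. Disease models — e.g. the
*Sca1* 154Q knock-in mouse of spinocerebellar ataxia type 1 — can show
*synaptic instability* (elevated protrusion turnover) long before
densities change or neurons die. Detecting that requires a reproducible
chain from manually traced protrusion annotations to per-dendrite rates
and group statistics. `spinedyn` implements that chain for tabular
annotations (one row per protrusion per frame: arc position, head width,
neck width, length, all in μm).

## The method

**Classification.** A protrusion is a *filopodium* iff
head/neck width < 1.2 **and** length/neck > 3 (strict comparisons);
otherwise it is a *spine*.

**Tracking.** Frames are registered by a global arc offset, then
identity between two sessions is the one-to-one assignment that first
maximises the number of pairs with displacement ≤ 0.7 μm and then
minimises total displacement; protrusions further than 0.7 μm from their
expected position are different protrusions. By default identity is
matched within each morphological class, the way a human tracer uses
morphology to keep identity. Unmatched frame-1 protrusions are
*eliminated*, unmatched frame-2 protrusions *formed*.

**Rates.** With F formed, E eliminated and N initial protrusions of a
class:

```
formation  = 100 · F / N            (%)
elimination = 100 · E / N           (%)
turnover   = 100 · (F + E) / (2N)   (%)  ≡ (formation + elimination) / 2
```

Per-condition summaries are mean ± SEM over dendrites. Group
comparisons: unpaired pooled-variance Student t-tests, two-way
(genotype × age) ANOVA with Bonferroni-corrected per-age contrasts, and
two-sample Kolmogorov–Smirnov tests on pooled morphometric
distributions.

**Simulation.** The generator places protrusions as a Poisson process on
a 1-D arc, draws class-conditional log-normal morphometry, eliminates
each protrusion with a per-class probability, jitters survivors (SD
0.15 μm), and adds per-class Poisson formation budgets — with packaged
presets carrying the densities, class mixtures and event probabilities
of a developmental SCA1 cortical/hippocampal imaging study. See
`docs/methods.md` for the full model and its limitations.

## Worked example

Simulate a 4-week control vs mutant cohort (100 dendrites per genotype,
1 h imaging interval) and run the full pipeline:

```python
import spinedyn as sd
from spinedyn.io import PipelineConfig

config = PipelineConfig(
    seed=7,
    conditions={
        "ctrl": sd.get_condition("cortex_4wk_control_1h", n_dendrites=100),
        "mut": sd.get_condition("cortex_4wk_mutant_1h", n_dendrites=100),
    },
)
tables = sd.run_pipeline(config, "simulate", "out/")
spine = tables["condition_summary"].query("`class` == 'spine'")
print(spine[["genotype", "formation_mean", "formation_sem",
             "elimination_mean", "elimination_sem", "n_dendrites"]].round(2))
```

```
genotype  formation_mean  formation_sem  elimination_mean  elimination_sem  n_dendrites
 control            2.86           0.56              5.51             0.67          100
  mutant            8.57           0.82             11.46             1.03          100
```

The control cohort's spine formation (2.9 ± 0.6%/h) and elimination
(5.5 ± 0.7%/h) sit near the configured generating probabilities (3.6%
and 4.5%), while the mutant cohort (8.6% and 11.5% vs generating 9% and
12%) is clearly less stable; the statistics table confirms the genotype
difference:

```
spine_formation_rate_pct_age4_1h_control_vs_mutant:   t = -5.74, p = 3.6e-08 ***
spine_elimination_rate_pct_age4_1h_control_vs_mutant: t = -4.84, p = 2.6e-06 ***
```

The same analysis runs stage-by-stage from the shell on any annotation
table:

```bash
spinedyn simulate --config config.yaml --out out/
spinedyn analyze --annotations out/annotations.tsv --config config.yaml --out out/
spinedyn report --in out/
```

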