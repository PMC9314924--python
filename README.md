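# camoevolve

Headless, scriptable camouflage-evolution experiments. A tailored real-coded
genetic algorithm drives procedural animal- and egg-style target phenotypes
through simulated visual-search predation against photographic or synthetic
backgrounds; camouflage is quantified with CIELAB statistics and GabRat edge
disruption.

## What's inside

| module | role |
| --- | --- |
| `camoevolve.imagega` | decimal-gene GA: overdispersed initialization, rank-based selection, weighted-average ("incomplete") crossover, Poisson point mutation with reflective bounds, tag-aware swap/scramble/duplication mutations, adaptive per-individual mutation rates, elite lifeline rescue |
| `camoevolve.pattern_animal` | Gray-Scott reaction-diffusion pattern gamut; gene-addressed window sampling, stripes via Y-stretch, gradient shading, binarization/mirroring, CIELAB coloration within configurable channel limits, edge enhancement, speckling |
| `camoevolve.pattern_egg` | two-layer thresholded-noise maculation (layer 2 smeared by a seeded random walk) and a deposition x biliverdin:protoporphyrin pigment model mapped to CIELAB within avian bounds |
| `camoevolve.camo_metrics` | target-vs-local-background CIELAB mean/SD differences (local region = circle of 2x the target's max diameter, target excluded) and per-channel GabRat edge disruption from a quadrature Gabor filter bank |
| `camoevolve.predation_sim` | slide construction (1478x1130 center crops, random placement/rotation), a simulated observer with response/capture timing, 15 s timeout and the 600 ms hybrid survival-time rule, warm-up targets, and the generational evolution loop |
| `camoevolve.io_interface` | chromosome text logs, YAML run configuration, synthetic background generator, CSV outputs |

## CLI

```bash
# packaged example experiment: 24 triangle targets (150x75 px), 15
# generations, CIELAB limits L 0..100 / A -60..60 / B -10..70, synthetic
# backgrounds
camoevolve demo-box1 --outdir box1_demo --seed 7

# a custom run described by a YAML config (flags override file values)
camoevolve evolve --config run.yaml --seed 7 --outdir out

# batch-score rendered targets against saved slides
camoevolve measure --targets out/targets_gen000 --slides out/slides_gen000 \
    --out metrics.csv
```

Each run writes per-generation target PNGs, slide PNGs, chromosome `.txt`
logs, `metrics_genNNN.csv` (placement, six CIELAB difference metrics, three
GabRat values, fitness) and `history.csv` (per-generation summaries). Runs
are fully reproducible from (config, seed).

A config file mirrors `camoevolve.io_interface.RunConfig`; write a template
with:

```python
from camoevolve import box1_config
box1_config(seed=0).to_yaml("run.yaml")
```

## Library use

```python
import numpy as np
from camoevolve import GAConfig, RunConfig, ObserverConfig, run_evolution

cfg = RunConfig(
    ga=GAConfig(N=24, seed=0),
    observer=ObserverConfig(noise_sigma=0.2),
    phenotype="animal",          # or "egg"
    generations=15,
    seed=0,
)
history = run_evolution(cfg)
best = history.records[-1].best_fitness
```

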