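# seed2seedling

Set-algebra analysis of microbiota transmission from seeds and soil to
seedlings, with the supporting diversity statistics and a community-coalescence
simulator that carries ground truth.

## The problem

When a seed germinates in soil, the seedling's bacterial community assembles
from three pools: the seed's own microbiota, the surrounding soil, and taxa
detectable in neither (unknown origin). Amplicon surveys of such experiments
produce a sample × ASV count table spanning the source compartments (seed
lots, soils) and the recipient compartments (seedling roots and stems) across
a factorial design of soil, plant genotype, seed harvest year and growth
stage. The questions this package answers:

- **Where do seedling ASVs come from?** Each seedling ASV is assigned an
  origin — `seed_only`, `soil_only`, `both` or `unknown` — by exhaustive
  presence/absence set algebra against the matching source pools, on
  non-rarefied counts (an ASV is "present" with ≥ 1 read in ≥ 1 replicate;
  both thresholds configurable).
- **How successful is transmission?** For each source pool, the percentage of
  its ASVs detected in the seedling compartment, per replicate
  (mean ± SE) and pooled, and broken down by the source ASV's abundance
  class: rare (< 0.01 % mean relative abundance), intermediate (0.01–1 %,
  boundaries inclusive) or abundant (> 1 %).
- **What structures the community?** Alpha diversity (Chao1, Faith's PD,
  observed richness) on rarefied counts, Bray–Curtis distances of
  log10(x+1)-transformed counts, PCoA, multivariate dispersion
  (betadisper with the negative-eigenvalue correction), and a sequential
  (type-I) PERMANOVA with per-term R² over an ordered term list such as
  `soil + stage + genotype:year + soil:genotype:year`.

The simulator (`seed2seedling.simulate`) generates the full factorial
experiment from lognormal source pools — including a dilution-to-extinction
soil treatment — with class-dependent Bernoulli transmission, an
unknown-origin taxon pool and multinomial read sampling, and returns the
complete ground truth, so every estimator can be tested for parameter
recovery.

## Worked example

```python
import numpy as np
from seed2seedling import (SimConfig, generate_dataset, detect, assign_origin,
                           origin_membership_fraction, transmission_success)

table, truth = generate_dataset(SimConfig(seed=42))
print(f"{table.shape[0]} samples x {table.shape[1]} ASVs")
# 114 samples x 1457 ASVs

soil = detect(table, {"compartment": "soil", "soil": "S1"})
seed = detect(table, {"compartment": "seed", "genotype": "Boston", "year": "Y1"})
root = detect(table, {"compartment": "root", "soil": "S1", "genotype": "Boston",
                      "year": "Y1", "stage": "d14"})
print(f"detected: soil_S1={len(soil)}, seed_Boston_Y1={len(seed)}, root={len(root)}")
# detected: soil_S1=791, seed_Boston_Y1=100, root=397

om = assign_origin(root, seed, soil)
print({k: round(v, 3) for k, v in origin_membership_fraction(om).items()})
# {'seed_only': 0.003, 'soil_only': 0.713, 'both': 0.005, 'unknown': 0.28,
#  'soil_detected': 0.718, 'seed_detected': 0.008}

reps = [detect(table, {"compartment": "root", "soil": "S1", "genotype": "Boston",
                       "year": "Y1", "stage": "d14", "replicate": r}) for r in "ABC"]
ts = transmission_success(soil, reps)
print(f"soil_S1 -> root: {ts.mean:.1f}% +- {ts.se:.1f}% (pooled {ts.percentage:.1f}%)")
# soil_S1 -> root: 28.8% +- 0.2% (pooled 36.0%)
```

The same pipeline runs from the shell on real or simulated data:

```sh
seed2seedling simulate --seed 42 --out data/
seed2seedling run-all --table data/feature_table.tsv --metadata data/metadata.tsv \
    --out results/ --seed 42
# or in one step:
seed2seedling run-all --simulate --seed 42 --out results/
```

Each subcommand writes one TSV per result table plus a `manifest.json`
recording the configuration and seed; reruns with the same seed are
byte-identical.

## Layout

- `src/seed2seedling/tables_io.py` — feature-table / metadata / tree I/O,
  validation, result writing, named RNG streams
- `src/seed2seedling/diversity.py` — rarefaction, Chao1, Faith's PD,
  group difference tests
- `src/seed2seedling/structure.py` — Bray–Curtis, PCoA, betadisper,
  sequential PERMANOVA
- `src/seed2seedling/transmission.py` — detection, prevalence/UpSet,
  origin assignment, transmission success, abundance classes
- `src/seed2seedling/simulate.py` — coalescence simulator with ground truth
- `src/seed2seedling/pipeline.py`, `cli.py` — stage orchestration and the
  `seed2seedling` command

Methodological details, parameter defaults and limitations are documented in
[`docs/methods.md`](docs/methods.md).
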