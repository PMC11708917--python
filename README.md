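# recland

Recombination-landscape analysis for pedigree + population genomic data,
modelled on the kind of study done for the barn owl (*Tyto alba*):
sex-specific genetic maps built from observed crossovers, intrachromosomal
shuffling statistics, fine-scale LD-based recombination maps windowed at
multiple scales, landscape inequality (Lorenz/Gini), hotspot/coldspot
annotation with genomic covariates, and comparison of landscapes across
populations. A synthetic-data module generates every input with known
ground truth, so the whole pipeline is testable end to end.

## Who this is for

Researchers combining two complementary estimates of recombination:

- **linkage maps** from family data — crossovers observed in transmitted
  gametes give sex-specific, broad-scale rates;
- **LD-based inference** (pyrho-style per-bp tracks) — fine-scale
  population rates, confounded by effective population size and
  therefore scaled to the linkage map per chromosome.

## The statistics at the core

- Map distance between adjacent markers: c = (# meioses with an odd
  number of crossovers in the interval)/n, d = 100·c cM or Haldane's
  d = −50 ln(1−2c). One obligate crossover per tetrad implies a map of
  at least 50 cM (a tetrad crossover reaches the sampled gamete with
  probability 1/2).
- Intrachromosomal shuffling: r̄_intra = Σ_k ḡ_k (L_k/ΣL)², with ḡ_k the
  mean over 10 kb pseudomarker pairs of the probability a crossover
  separates the pair.
- Windowed maps: per-interval p = r·len converted once by Haldane and
  split pro-rata at window boundaries, so window cM are additive across
  scales (1 kb … 1 Mb).
- Gini coefficient of the landscape: twice the area between the
  rate-ordered Lorenz curve and the diagonal (equivalently
  Σ|x_i−x_j|/(2n²μ)); 0 = perfectly even landscape.
- RRR80: a 1 kb window's rate divided by the mean rate in the 40 kb
  flanks each side; local hotspots are runs of ≥2 windows with
  RRR80 ≥ 5, rate 1–10 cM/Mb and ≤500 bp repeats.

See `docs/methods.md` for the full model description and the synthetic
generator's assumptions.

## Layout

- `src/recland/` — the library: `core_io` (layout, intervals, rate
  tracks, BED/FASTA, mappability mask), `synthetic_data` (ground-truth
  generator), `genetic_map`, `shuffling`, `landscape`, `hotspots`,
  `popcompare`, `study` (published summary constants).
- `analysis/` — numbered drivers that run the study on synthetic data
  and write tables to `results/` (large intermediates to `scratch/`):
  `01_simulate_inputs` → `02_linkage_maps` → `03_shuffling` →
  `04_ld_landscape` → `05_inequality` → `06_hotspots` →
  `07_populations`. Each can also run standalone.

## Worked example

```python
import numpy as np
from recland.core_io import GenomeLayout
from recland.genetic_map import build_map
from recland.synthetic_data import (
    CoModel, LandscapeModel, SimParams, simulate_landscape, simulate_meioses,
)

params = SimParams(
    seed=1,
    layout=GenomeLayout([("lg1", 50_000_000, True)]),
    n_meioses_per_sex=5_000,
    landscape=LandscapeModel(log_sd=0.0, hotspot_density_per_mb=0.0),
    co=CoModel(extra_co_rate=0.0, telomere_weight_male=0.0,
               telomere_weight_female=0.0),
)
truth = simulate_landscape(params)
cos = simulate_meioses(truth, params)          # transmitted crossovers
markers = {"lg1": np.linspace(0, 50_000_000, 500).astype(np.int64)}
gmap = build_map(cos, markers, n_meioses=10_000)
print(f"{gmap.total_cm():.2f} cM")
```

prints

```
50.25 cM
```

— 10,000 meioses each carrying exactly one obligate crossover yield a
~50 cM map: half the tetrad crossovers are transmitted, so segregation
sees one recombinant gamete in two. Running the full analysis
(`python analysis/02_linkage_maps.py` after `01`) prints, among other
things, the genetic-vs-physical length regression for the 8 synthetic
linkage groups (intercept 41.4 cM, 95% CI 31.9–51.0, consistent with
the 50 cM obligate-crossover expectation; slope 0.78 cM/Mb) and a KS
comparison of male vs female crossover placement (D = 0.064,
p ≈ 0.026 at ~2,000 crossovers).

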