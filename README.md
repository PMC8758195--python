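# eggmatch

Maternal eggshell-signature analysis for rails: match egg photographs by
maculation pattern, score percent pigmentation, test whether clutches are
statistically distinguishable, and combine inter-clutch matches with nest
locations and dates to infer **returning breeders**, **conspecific brood
parasitism (CBP)** and **renesting attempts**.

## The problem

Secretive marsh birds such as the King Rail (*Rallus elegans*) are almost
never resighted even when banded, so individual breeding histories are
effectively invisible to standard field methods.  Many rails, however, lay
protoporphyrin-maculated eggs whose spotting is far more variable among
females than within a clutch — a *maternal signature*.  If eggs can be
assigned to hens from standardized clutch photographs alone, nest
monitoring yields individual-level biology (site fidelity, renesting,
reproductive interference) non-invasively.

`eggmatch` implements that workflow end to end:

1. **imageprep** — grayscale conversion, egg segmentation, large-pole
   orientation, focus/exposure quality gates;
2. **features** — scale-space keypoint descriptors of the maculation,
   augmented with appearance channels (spot scale in mm, spot tone, shell
   ground tone, axial position, egg aspect); egg-to-egg dissimilarity is
   the modified-Hausdorff distance between descriptor sets, and each egg is
   ranked against every other egg in its batch (year, region, or all);
3. **pigment** — Bernsen local thresholding and the percentage of black
   pixels inside a standardized 3.4 × 2.4 cm oval at the large pole;
4. **stats** — PERMANOVA (implemented from the squared-distance partition,
   with label permutations), non-metric MDS, and linear discriminant
   classification of eggs into clutches from pattern + dimension
   covariates;
5. **infer** — the tiered decision tree: Tier I (symmetrical matching or
   physical proximity, ≥ 2 matching eggs, flagged for visual review),
   Tier IIa/IIb (repeated one-directional matching with a top-*k* tally
   ≥ 4, split by between-year versus within-season), then link
   classification from years, first-egg dates and nest fates;
6. **synth** — a generator of egg images and nest metadata with known
   ground truth (hen-specific spot density, size, tone, polar bias, egg
   shape; planted returning-breeder/CBP/renest links), so every stage is
   testable without the original field photographs.

## Worked example

```python
from pathlib import Path
from eggmatch.synth import ScenarioConfig, generate_population, write_dataset
from eggmatch.pipeline import RunConfig, run_all

ds = generate_population(ScenarioConfig(n_hens=6, rng_seed=1))
write_dataset(ds, "run/data")
report = run_all(RunConfig(dataset_dir=Path("run/data"),
                           output_dir=Path("run/out"), seed=1))
print(ds.truth.planted_links)
print(report[["tier", "nest_a", "nest_b", "distance_m", "inferred_link"]])
```

prints

```
[('19-07', '20-08', 'returning_breeder'), ('19-09', '19-10', 'CBP'), ('19-11', '19-12', 'renest')]
tier nest_a nest_b  distance_m     inferred_link
   I  19-11  19-12  313.788263            renest
   I  19-07  20-08   67.595290 returning_breeder
 IIb  19-09  19-10  292.164334               CBP
```

All three planted links are recovered with the correct label and no false
pairs: the hen that returned in 2020 nested 68 m from her 2019 nest
(Tier I, symmetrical matching), the renest was detected from reciprocal
matches plus a > 6-week gap after a failed first nest, and the parasitized
clutch was flagged by repeated one-directional matching into the
parasite's own nest with synchronous first-egg dates (Tier IIb).  The same
run writes `run/out/stats.json` with the discrimination statistics
(PERMANOVA R² by clutch ≈ 0.63, p = 0.001 on this dataset — clutch
identity explains most of the pattern variance, as a maternal signature
should).

The same pipeline is available from the shell:

```bash
eggmatch simulate run/data --seed 1 --hens 6
eggmatch run-all run/data run/out --seed 1
```

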