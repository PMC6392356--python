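# reefranges

Trait-based analysis of geographic range size for reef fishes, with
diagnostics for the bias introduced by incomplete trait datasets.

## The problem

Dispersal ability should shape how large a geographic range a species can
attain, yet for tropical reef fishes the evidence has long been mixed. One
underappreciated reason is that the classic dispersal proxy — pelagic
larval duration (PLD) — has been measured for only a minority of species,
and the measured subset is not a random sample of the regional pool:
well-studied species tend to be pelagic-spawning, mobile, diurnal and
aggregative, and to come from a few popular families. Models fitted to
that subset can miss trait–range relationships that the full assemblage
clearly shows.

`reefranges` packages the full analysis chain needed to study — and
diagnose — this problem:

1. **Range metric** — range size as the maximum linear distance: the
   largest great-circle distance (km) between any two occurrence records
   of a species (spherical Earth, R = 6,371 km).
2. **Trait models** — Gaussian linear mixed models of logit-transformed
   range size with standardized predictors (body size, spawning mode,
   adult mobility, circadian activity, aggregation behaviour, optionally
   PLD, plus a spawning × mobility interaction), nested taxonomic random
   intercepts (genus ⊂ family ⊂ order) and ocean-basin / coastline-vs-
   island intercepts, fitted by ML. All submodels of the global model
   obeying marginality are enumerated, weighted by AICc
   (w_i ∝ exp(−Δᵢ/2)), and coefficients are model-averaged with
   unconditional standard errors.
3. **Subset null model** — 13 trait characteristics of a focal species
   subset (family count, mean body size, and the level proportions of
   four behavioural factors) compared against constrained random subsets
   of equal size (every factor level represented); a characteristic is
   nonrepresentative when ≥ 97.5% of draws fall on one side of the focal
   value (two-sided α = 0.05).
4. **Subset sensitivity** — the complete-data model refitted on many
   constrained random subsets of focal-subset size, locating the focal
   subset's effect sizes and p-values inside the replicate distributions.
5. **Synthetic data** — a generator with known ground truth (trait
   effects on the logit scale, taxonomic variance components, a biased
   availability mask) so every stage is testable without downloads.

## Worked example

```python
import reefranges as rr

pool   = rr.make_species_pool(rr.default_pool_config(seed=1))   # 497 species
ranges = rr.simulate_range_sizes(pool, rr.default_effect_config(), seed=2)
res    = rr.full_analysis(pool, ranges, d_ref_km=6000.0)
print(res.effects.table[["estimate", "se", "p", "stars"]].round(3))
```

prints (standardized logit-scale effects, complete data):

```
                                     estimate     se      p stars
intercept                               0.280  0.788  0.722
body_size                               0.617  0.105  0.000   ***
spawning_pelagic                        0.645  0.112  0.000   ***
mobility_medium                         0.301  0.115  0.009     *
mobility_high                           0.606  0.144  0.000   ***
circadian_crepuscular                   0.072  0.154  0.642
circadian_nocturnal                    -0.471  0.128  0.000    **
spawning_pelagic:mobility_medium       -0.000  0.081  0.996
spawning_pelagic:mobility_high         -0.014  0.105  0.896
aggregation_temporarily_aggregative    -0.077  0.115  0.503
aggregation_aggregative                 0.102  0.127  0.422
```

Pelagic spawning, mobility and body size increase range size and
nocturnality decreases it — recovering the generator's ground truth. On
the biased 148-species focal subset
(`rr.full_analysis(..., subset_col="in_focal_subset")`) the spawning-mode
p-value rises to ~0.15–0.96 depending on the draw: the trait signal
vanishes, not because n = 148 is too small but because the subset retains
almost no spawning-mode contrast. `rr.null_model_test` flags 9–10 of the
13 characteristics as nonrepresentative, and in
`rr.sensitivity_analysis` the large majority of *random* 148-species
subsets recover a significant positive spawning effect with a lower
p-value than the focal subset's.

The `examples/` directory walks through each capability
(`01_simulate_pool.py` … `06_full_pipeline.py`); each script prints the
numbers it computes and a line on what they mean.

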