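"""Random-subset sensitivity analysis: why the focal subset misleads.

Refits the complete-data model on 100 constrained random subsets of
focal-subset size and compares the distribution of averaged effects and
p-values with (a) the complete-data fit and (b) the biased focal subset.
A biased subset loses the spawning-mode signal that ordinary random
subsets of identical size retain.
"""

import reefranges as rr

pool = rr.make_species_pool(rr.default_pool_config(seed=1))
ranges = rr.simulate_range_sizes(pool, rr.default_effect_config(), seed=2)
species = rr.assign_focal_subset(pool, rr.headline_bias_config(), seed=3)

focal = rr.full_analysis(species, ranges, subset_col="in_focal_subset",
                         d_ref_km=6000.0)
sens = rr.sensitivity_analysis(pool, ranges, n_replicates=100,
                               subset_size=148, seed=5, d_ref_km=6000.0)
comp = rr.compare_to_focal(sens, focal.effects, strict=False)

cols = ["complete_p", "focal_p", "frac_p_below_focal",
        "replicate_frac_significant", "replicate_modal_sig"]
print(comp[cols].round(4).to_string())
# 'frac_p_below_focal' near 1 means nearly every random subset of the same
# size detects the effect more strongly than the focal subset does -- the
# signature of a nonrandom (biased) focal subset rather than small n.
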