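"""Sensitivity of the trait -> range-size model to species subsampling.

The complete-data model is refitted on many constrained random subsets of
the same size as the focal (PLD-measured) subset.  If the focal subset
were an ordinary random sample, its averaged effect sizes and p-values
would look like one more draw from the replicate distributions; a focal
subset whose p-values sit far in the upper tail of the replicate p-value
distribution is losing power for reasons beyond sample size — the
signature of a nonrandom subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .range_metrics import DEFAULT_D_REF_KM, DEFAULT_EPS
from .schema import significance_class
from .subset_nullmodel import DEFAULT_CONSTRAINT_FACTORS, _PoolIndex, _draw_valid_indices
from .trait_model import AveragedEffects, FullAnalysisResult, full_analysis

__all__ = ["SensitivityResult", "sensitivity_analysis", "compare_to_focal"]

logger = logging.getLogger(__name__)

_MAX_FAILED_FRACTION = 0.10


@dataclass
class SensitivityResult:
    """Replicate distributions of averaged effects and p-values.

    ``effects`` / ``p_values`` hold the full-average estimates and
    p-values (one row per converged replicate, one column per
    coefficient); the conditional-average counterparts are kept alongside
    because reports may show either flavour.
    """

    effects: pd.DataFrame
    p_values: pd.DataFrame
    effects_cond: pd.DataFrame
    p_values_cond: pd.DataFrame
    complete: FullAnalysisResult
    n_replicates: int
    n_failed: int
    subset_size: int

    def modal_significance(self) -> pd.Series:
        """Most frequent significance class per coefficient across
        replicates (classes: <0.0001, <0.001, <0.05, ns)."""
        classes = self.p_values.map(significance_class)
        return classes.apply(lambda col: col.mode().iloc[0], axis=0)


def sensitivity_analysis(
    species: pd.DataFrame,
    ranges: pd.DataFrame,
    n_replicates: int = 1000,
    subset_size: int = 148,
    seed: int = 0,
    include_interaction: bool = True,
    weight_floor: float = 0.001,
    d_ref_km: float = DEFAULT_D_REF_KM,
    eps: float = DEFAULT_EPS,
    constraint_factors: tuple[str, ...] = DEFAULT_CONSTRAINT_FACTORS,
) -> SensitivityResult:
    """Refit the complete-data model on constrained random subsets.

    Replicate ``r`` draws its subset with seed ``seed XOR r``, so any
    execution order (or partial rerun) reproduces the same subsets.  A
    replicate whose model fit fails is skipped and counted; more than 10%
    failures aborts, since that signals a misconfigured model rather than
    occasional numerical bad luck.
    """
    complete = full_analysis(
        species, ranges, include_pld=False, include_interaction=include_interaction,
        weight_floor=weight_floor, d_ref_km=d_ref_km, eps=eps,
    )
    index = _PoolIndex(species, constraint_factors)

    eff, pv, eff_c, pv_c = [], [], [], []
    n_failed = 0
    for r in range(n_replicates):
        rng = np.random.default_rng((seed ^ r) & 0x7FFFFFFF)
        idx = _draw_valid_indices(index, subset_size, 1, rng)[0]
        ids = index.species[idx]
        sub = species.loc[species["species_id"].isin(ids)]
        try:
            res = full_analysis(
                sub, ranges, include_pld=False,
                include_interaction=include_interaction,
                weight_floor=weight_floor, d_ref_km=d_ref_km, eps=eps,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.info("replicate %d failed: %s", r, exc)
            continue
        t = res.effects.table
        eff.append(t["estimate"].rename(r))
        pv.append(t["p"].rename(r))
        eff_c.append(t["estimate_cond"].rename(r))
        pv_c.append(t["p_cond"].rename(r))
    if n_failed > _MAX_FAILED_FRACTION * n_replicates:
        raise RuntimeError(
            f"{n_failed}/{n_replicates} replicates failed — model misconfigured?"
        )
    return SensitivityResult(
        effects=pd.DataFrame(eff), p_values=pd.DataFrame(pv),
        effects_cond=pd.DataFrame(eff_c), p_values_cond=pd.DataFrame(pv_c),
        complete=complete, n_replicates=n_replicates, n_failed=n_failed,
        subset_size=subset_size,
    )


def compare_to_focal(
    sens: SensitivityResult,
    focal_effects: AveragedEffects,
    complete_effects: AveragedEffects | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Per coefficient: where does the focal subset sit among replicates?

    ``frac_p_below_focal`` is the fraction of replicates whose p-value is
    strictly lower (more significant) than the focal subset's; values near
    1 mean nearly every ordinary random subset of the same size detects
    the effect more strongly than the focal subset does.
    """
    complete_effects = complete_effects or sens.complete.effects
    coefs = [c for c in sens.p_values.columns if c != "intercept"]
    missing = [c for c in coefs if c not in focal_effects.table.index]
    if missing and strict:
        raise ValueError(f"focal effects missing coefficients: {missing}")
    rows = []
    for c in coefs:
        p_rep = sens.p_values[c].to_numpy(float)
        if c in missing:
            # coefficient inestimable in the focal subset (e.g. dropped
            # interaction): report the replicate side only
            p_focal, e_focal = np.nan, np.nan
        else:
            p_focal = float(focal_effects.table.loc[c, "p"])
            e_focal = float(focal_effects.table.loc[c, "estimate"])
        e_rep = sens.effects[c].to_numpy(float)
        rows.append({
            "coefficient": c,
            "focal_p": p_focal,
            "frac_p_below_focal": float(np.mean(p_rep < p_focal)),
            "focal_estimate": e_focal,
            "complete_estimate": float(complete_effects.table.loc[c, "estimate"]),
            "complete_p": float(complete_effects.table.loc[c, "p"]),
            "replicate_estimate_mean": float(e_rep.mean()),
            "replicate_estimate_p2.5": float(np.percentile(e_rep, 2.5)),
            "replicate_estimate_p97.5": float(np.percentile(e_rep, 97.5)),
            "replicate_modal_sig": sens.modal_significance()[c],
            "replicate_frac_significant": float(np.mean(p_rep < 0.05)),
        })
    return pd.DataFrame(rows).set_index("coefficient")
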