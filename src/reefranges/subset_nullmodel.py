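"""Representativeness test for a focal species subset.

Is the subset of species for which a trait has been measured a random
sample of the regional pool?  The test compares 13 characteristics of the
focal subset (number of families, mean body size, and the level
proportions of spawning mode, mobility, aggregation and circadian
activity) against the same characteristics of many constrained random
subsets of equal size.  Random subsets are constrained to contain at
least one species of every level of every modelled categorical factor,
because the models fitted downstream require every level to be present.

A characteristic is significantly nonrepresentative when the focal value
lies in the extreme tails of the null distribution: with 10,000 draws and
a two-sided alpha of 0.05, when at least 9,750 draws fall on one side of
the focal value (ties counting half to each side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import TRAIT_LEVELS

__all__ = [
    "CHARACTERISTICS", "NullModelResult",
    "draw_valid_subset", "trait_summary", "null_model_test",
]

#: Default constraint: every modelled categorical factor.
DEFAULT_CONSTRAINT_FACTORS = tuple(TRAIT_LEVELS)

#: The 13 compared characteristics, in reporting order.
CHARACTERISTICS = (
    "n_families",
    "mean_body_size",
    "prop_spawning_pelagic", "prop_spawning_nonpelagic",
    "prop_mobility_low", "prop_mobility_medium", "prop_mobility_high",
    "prop_aggregation_nonaggregative", "prop_aggregation_temporarily_aggregative",
    "prop_aggregation_aggregative",
    "prop_circadian_diurnal", "prop_circadian_crepuscular", "prop_circadian_nocturnal",
)

_PROP_SPEC = [
    ("spawning_mode", "pelagic", "prop_spawning_pelagic"),
    ("spawning_mode", "nonpelagic", "prop_spawning_nonpelagic"),
    ("mobility", "low", "prop_mobility_low"),
    ("mobility", "medium", "prop_mobility_medium"),
    ("mobility", "high", "prop_mobility_high"),
    ("aggregation", "nonaggregative", "prop_aggregation_nonaggregative"),
    ("aggregation", "temporarily_aggregative", "prop_aggregation_temporarily_aggregative"),
    ("aggregation", "aggregative", "prop_aggregation_aggregative"),
    ("circadian", "diurnal", "prop_circadian_diurnal"),
    ("circadian", "crepuscular", "prop_circadian_crepuscular"),
    ("circadian", "nocturnal", "prop_circadian_nocturnal"),
]


@dataclass
class NullModelResult:
    """Per-characteristic comparison of the focal subset with the null.

    ``table`` is indexed by characteristic with columns: observed,
    null_mean, null_sd, z (= (null_mean - observed)/null_sd, so positive
    means random subsets exceed the focal subset), count_above,
    count_below (ties split half/half), significant, direction, stars,
    and the 2.5/97.5 null percentiles.
    """

    table: pd.DataFrame
    n_draws: int
    threshold: int
    null_draws: pd.DataFrame | None = None

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def _missing_trait_check(pool: pd.DataFrame) -> None:
    cols = ["family", "body_size_cm"] + list(TRAIT_LEVELS)
    for c in cols:
        if c not in pool.columns:
            raise ValueError(f"pool is missing column {c!r}")
        if pool[c].isna().any():
            raise ValueError(f"missing values in trait column {c!r}")


class _PoolIndex:
    """Precomputed per-species indicators for fast batched summaries."""

    def __init__(self, pool: pd.DataFrame, constraint_factors: tuple[str, ...]):
        _missing_trait_check(pool)
        self.n = len(pool)
        self.species = pool["species_id"].to_numpy()
        # 12 mean-type characteristics as one indicator/value matrix
        cols = [pool["body_size_cm"].to_numpy(float)]
        for trait, level, _ in _PROP_SPEC:
            cols.append((pool[trait] == level).to_numpy(float))
        self.T = np.column_stack(cols)                       # n x 12
        fam, self.fam_codes = np.unique(pool["family"], return_inverse=True)
        self.n_fam = len(fam)
        self.fam_oh = np.zeros((self.n, self.n_fam), dtype=bool)
        self.fam_oh[np.arange(self.n), self.fam_codes] = True
        # constraint-level one-hot (only levels present in the pool)
        blocks = []
        for f in constraint_factors:
            levels, codes = np.unique(pool[f].to_numpy(), return_inverse=True)
            oh = np.zeros((self.n, len(levels)), dtype=bool)
            oh[np.arange(self.n), codes] = True
            blocks.append(oh)
        self.L = np.concatenate(blocks, axis=1) if blocks else np.zeros((self.n, 0), bool)

    def summaries(self, idx: np.ndarray) -> np.ndarray:
        """Characteristic matrix for subset index rows ``idx`` (B, m)."""
        sub = self.T[idx]                                    # B x m x 12
        means = sub.mean(axis=1)
        nfam = self.fam_oh[idx].any(axis=1).sum(axis=1)
        return np.column_stack([nfam.astype(float), means])

    def valid(self, idx: np.ndarray) -> np.ndarray:
        return self.L[idx].any(axis=1).all(axis=1)


def _draw_valid_indices(
    index: _PoolIndex, n_subset: int, n_draws: int, rng: np.random.Generator,
    max_retries: int = 10_000,
) -> np.ndarray:
    """(n_draws, n_subset) row indices of uniform constrained subsets,
    drawn by batched rejection sampling."""
    if n_subset < 1 or n_subset > index.n:
        raise ValueError("n_subset must lie in [1, pool size]")
    out = np.empty((n_draws, n_subset), dtype=np.intp)
    got = 0
    attempts = 0
    batch = max(64, min(2048, n_draws))
    while got < n_draws:
        b = min(batch, max(n_draws - got, 64))
        idx = np.argsort(rng.random((b, index.n)), axis=1)[:, :n_subset]
        ok = index.valid(idx)
        take = idx[ok][: n_draws - got]
        out[got: got + len(take)] = take
        got += len(take)
        attempts += b
        if attempts > max_retries * max(n_draws, 1) and got == 0:
            present = index.L[idx[0]].any(axis=0)
            raise ValueError(
                f"could not draw a valid subset in {attempts} attempts; "
                f"{int((~present).sum())} constraint level(s) unattainable"
            )
    return out


def draw_valid_subset(
    pool: pd.DataFrame,
    n_subset: int,
    seed: int | np.random.Generator,
    constraint_factors: tuple[str, ...] = DEFAULT_CONSTRAINT_FACTORS,
) -> np.ndarray:
    """One uniform random subset of species ids, conditioned on every
    level of every constraint factor being represented."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = _PoolIndex(pool, constraint_factors)
    idx = _draw_valid_indices(index, n_subset, 1, rng)[0]
    return index.species[idx]


def trait_summary(pool: pd.DataFrame) -> pd.Series:
    """The 13 characteristics of a (subset of a) species table."""
    if len(pool) == 0:
        raise ValueError("trait_summary of an empty subset")
    _missing_trait_check(pool)
    vals = {"n_families": float(pool["family"].nunique()),
            "mean_body_size": float(pool["body_size_cm"].mean())}
    for trait, level, name in _PROP_SPEC:
        vals[name] = float((pool[trait] == level).mean())
    return pd.Series(vals, name="trait_summary").reindex(list(CHARACTERISTICS))


def null_model_test(
    pool: pd.DataFrame,
    focal_ids: np.ndarray,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    constraint_factors: tuple[str, ...] = DEFAULT_CONSTRAINT_FACTORS,
    keep_draws: bool = False,
) -> NullModelResult:
    """Rank the focal subset's characteristics within the null distribution
    of constrained random subsets of equal size."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    focal_ids = np.asarray(focal_ids)
    in_pool = np.isin(focal_ids, pool["species_id"].to_numpy())
    if not in_pool.all():
        raise ValueError(f"focal ids not in pool: {focal_ids[~in_pool][:5].tolist()}")
    if len(np.unique(focal_ids)) != len(focal_ids):
        raise ValueError("duplicate focal ids")

    index = _PoolIndex(pool, constraint_factors)
    focal_idx = pd.Index(index.species).get_indexer(focal_ids)
    observed = index.summaries(focal_idx[None, :])[0]
    draws = index.summaries(
        _draw_valid_indices(index, len(focal_ids), n_draws, rng)
    )                                                        # n_draws x 13

    threshold = int(np.ceil(0.975 * n_draws))
    tied = np.isclose(draws, observed, rtol=1e-9, atol=1e-12)
    above = ((draws > observed) & ~tied).sum(axis=0).astype(float)
    below = ((draws < observed) & ~tied).sum(axis=0).astype(float)
    ties = n_draws - above - below
    count_above = above + ties / 2.0
    count_below = below + ties / 2.0
    null_mean = draws.mean(axis=0)
    null_sd = draws.std(axis=0, ddof=1)
    degenerate = null_sd <= 1e-9 * np.maximum(1.0, np.abs(null_mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(~degenerate, (null_mean - observed) / np.where(degenerate, 1.0, null_sd), 0.0)
    significant = np.maximum(count_above, count_below) >= threshold
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)

    table = pd.DataFrame({
        "observed": observed, "null_mean": null_mean, "null_sd": null_sd,
        "z": z, "count_above": count_above, "count_below": count_below,
        "significant": significant, "direction": np.sign(z).astype(int),
        "null_p2.5": lo, "null_p97.5": hi,
    }, index=pd.Index(CHARACTERISTICS, name="characteristic"))
    return NullModelResult(
        table=table, n_draws=n_draws, threshold=threshold,
        null_draws=pd.DataFrame(draws, columns=list(CHARACTERISTICS))
        if keep_draws else None,
    )
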