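"""Trait -> range-size mixed modelling with AICc multimodel inference.

The workflow mirrors standard practice in trait-based macroecology:

1. standardize predictors (continuous: centred and divided by 2 SD, so a
   binary contrast and a 2-SD continuous change are comparable; two-level
   factors: centred 0/1; multi-level factors: dummies against reference
   levels nonpelagic / low mobility / nonaggregative / diurnal),
2. screen collinearity with variance inflation factors (flag >= 2.5),
3. fit Gaussian linear mixed models of logit range size with nested
   taxonomic random intercepts (genus in family in order) plus ocean-basin
   and coastline-vs-island intercepts, by full ML,
4. enumerate every fixed-effect submodel of the global model obeying
   marginality (the spawning x mobility interaction only alongside both
   main effects),
5. weight models by AICc and model-average coefficients, dropping models
   with Akaike weight <= 0.001.

Both full-model averages (a coefficient counts 0 in models that exclude
its term) and conditional averages (over models containing the term) are
reported, with unconditional standard errors combining within-model
variance and between-model spread.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm
from .range_metrics import DEFAULT_D_REF_KM, DEFAULT_EPS, logit_transform
from .schema import RANDOM_FACTORS, TERM_COLUMNS, TRAIT_LEVELS, significance_class, stars

__all__ = [
    "ModelSpec", "FittedModel", "AveragedEffects", "FullAnalysisResult",
    "standardize_predictors", "compute_vif", "build_design", "fit_lmm",
    "enumerate_submodels", "akaike_weights", "model_average", "full_analysis",
    "VIF_THRESHOLD",
]

logger = logging.getLogger(__name__)

VIF_THRESHOLD = 2.5

_MAIN_TERMS = ("body_size", "spawning", "mobility", "circadian", "aggregation")
_INTERACTION = "spawning:mobility"
_INTERACTION_PARENTS = ("spawning", "mobility")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: an ordered set of fixed terms plus the (held
    fixed) random-intercept structure."""

    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...] = RANDOM_FACTORS
    response: str = "y_logit"

    def __post_init__(self):
        unknown = set(self.fixed_terms) - set(TERM_COLUMNS)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        if _INTERACTION in self.fixed_terms and not all(
            p in self.fixed_terms for p in _INTERACTION_PARENTS
        ):
            raise ValueError("interaction requires both parent main effects (marginality)")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(c for t in self.fixed_terms for c in TERM_COLUMNS[t])


@dataclass
class FittedModel:
    """A single mixed-model fit of one candidate ModelSpec."""

    spec: ModelSpec
    result: lmm.MixedLMResult

    @property
    def converged(self) -> bool:
        return self.result.converged and np.isfinite(self.result.loglik)

    @property
    def aicc(self) -> float:
        return self.result.aicc

    @property
    def loglik(self) -> float:
        return self.result.loglik

    def coef(self) -> dict[str, tuple[float, float]]:
        """Coefficient name -> (estimate, SE)."""
        return {
            n: (float(b), float(s))
            for n, b, s in zip(self.result.names, self.result.params, self.result.bse)
        }


@dataclass
class AveragedEffects:
    """Akaike-weight-averaged coefficients.

    ``table`` is indexed by coefficient name with columns: estimate / se /
    z / p / stars (full averages, the headline), estimate_cond / se_cond /
    z_cond / p_cond (conditional averages), and ``weight`` (summed Akaike
    weight of models containing the term).
    """

    table: pd.DataFrame
    model_set_size: int
    weights: np.ndarray

    def p_values(self, flavor: str = "full") -> pd.Series:
        return self.table["p" if flavor == "full" else "p_cond"]


@dataclass
class FullAnalysisResult:
    effects: AveragedEffects
    vif: pd.Series
    vif_flagged: list[str]
    model_table: pd.DataFrame        # per candidate model: terms, k, logLik, AICc, weight
    n_models: int
    n_unconverged: int
    dropped_random: list[str]
    n_obs: int


# ---------------------------------------------------------------------------
# design construction


def standardize_predictors(
    table: pd.DataFrame,
    continuous_names: tuple[str, ...] = (),
    binary_names: tuple[str, ...] = (),
    factor_levels: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Standardized design columns from raw predictors.

    Continuous columns are centred and divided by twice their SD (the
    resulting SD is 0.5); two-level factors become centred 0/1 indicators
    of the non-reference level; multi-level factors are dummy-coded
    against their reference (first) level and left unscaled.
    """
    out = pd.DataFrame(index=table.index)
    for name in continuous_names:
        x = table[name].to_numpy(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"continuous predictor {name!r} has zero variance")
        out[name] = (x - x.mean()) / (2.0 * sd)
    for name in binary_names:
        levels = (factor_levels or {}).get(name) or tuple(sorted(table[name].unique()))
        if len(levels) != 2:
            raise ValueError(f"{name!r} is not a two-level factor")
        ind = (table[name] == levels[1]).to_numpy(float)
        out[f"{name}_{levels[1]}"] = ind - ind.mean()
    for name, levels in (factor_levels or {}).items():
        if name in binary_names or len(levels) <= 2:
            continue
        for level in levels[1:]:
            out[f"{name}_{level}"] = (table[name] == level).to_numpy(float)
    return out


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1/(1-R^2) from regressing
    each column on the others (with intercept)."""
    X = design.to_numpy(float)
    names = list(design.columns)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictors")
    Xc = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xc) < p + 1:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        bad = [names[j] for j in range(p) if np.any(np.abs(corr[j]) > 1 - 1e-10)]
        raise ValueError(f"design is rank deficient; collinear columns: {bad or names}")
    vifs = []
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
        vifs.append(1.0 / max(1.0 - r2, 1e-12))
    return pd.Series(vifs, index=names, name="vif")


def build_design(
    species: pd.DataFrame,
    ranges: pd.DataFrame,
    include_pld: bool = False,
    d_ref_km: float = DEFAULT_D_REF_KM,
    eps: float = DEFAULT_EPS,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Merge traits with ranges and build the standardized design.

    Returns ``(y, X, rand)``: the logit response, the full standardized
    fixed-effect design (all candidate columns), and the random-factor
    label columns.
    """
    data = species.merge(ranges, on="species_id", how="inner", validate="1:1")
    if len(data) == 0:
        raise ValueError("species and range tables share no species_id")
    y = pd.Series(
        logit_transform(data["range_km"].to_numpy(float), d_ref_km, eps),
        index=data.index, name="y_logit",
    )
    data = data.assign(log_body_size=np.log(data["body_size_cm"].to_numpy(float)))
    continuous = ["log_body_size"]
    if include_pld:
        if data["pld_days"].isna().any():
            raise ValueError("include_pld requires PLD values for every analysed species")
        # PLD = 0 (viviparous species) is legitimate; standardization handles it
        continuous.append("pld_days")
    X = standardize_predictors(
        data,
        continuous_names=tuple(continuous),
        binary_names=("spawning_mode",),
        factor_levels={
            "spawning_mode": TRAIT_LEVELS["spawning_mode"],
            "mobility": TRAIT_LEVELS["mobility"],
            "circadian": TRAIT_LEVELS["circadian"],
            "aggregation": TRAIT_LEVELS["aggregation"],
        },
    )
    X = X.rename(columns={
        "log_body_size": "body_size", "pld_days": "pld",
        "spawning_mode_pelagic": "spawning_pelagic",
    })
    for level in TRAIT_LEVELS["mobility"][1:]:
        X[f"spawning_pelagic:mobility_{level}"] = (
            X["spawning_pelagic"] * X[f"mobility_{level}"]
        )
    rand = data[list(RANDOM_FACTORS)].copy()
    return y, X, rand


# ---------------------------------------------------------------------------
# model enumeration, fitting, averaging


def enumerate_submodels(global_spec: ModelSpec) -> list[ModelSpec]:
    """All fixed-term subsets of the global model obeying marginality,
    including the intercept-only model; random structure held fixed."""
    mains = [t for t in global_spec.fixed_terms if t != _INTERACTION]
    has_int = _INTERACTION in global_spec.fixed_terms
    specs = []
    for r in range(len(mains) + 1):
        for combo in itertools.combinations(mains, r):
            specs.append(ModelSpec(combo, global_spec.random_terms, global_spec.response))
            if has_int and all(p in combo for p in _INTERACTION_PARENTS):
                specs.append(ModelSpec(
                    combo + (_INTERACTION,), global_spec.random_terms, global_spec.response
                ))
    return specs


def _make_factors(rand: pd.DataFrame, random_terms: tuple[str, ...]):
    """Random-factor code arrays; factors with < 2 observed levels are
    dropped (they are inestimable in that data subset)."""
    factors, dropped = [], []
    for name in random_terms:
        levels, codes = np.unique(rand[name].to_numpy(), return_inverse=True)
        if len(levels) < 2:
            dropped.append(name)
            continue
        factors.append(lmm.RandomFactor(name, codes, len(levels)))
    return factors, dropped


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit one candidate model from a frame holding the response, the
    standardized design columns and the random-factor label columns."""
    y = data[spec.response].to_numpy(float)
    cols = list(spec.columns)
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in cols])
    factors, _ = _make_factors(data, spec.random_terms)
    res = lmm.fit_ml(y, X, factors, names=["intercept"] + cols)
    return FittedModel(spec, res)


def akaike_weights(aicc: np.ndarray) -> np.ndarray:
    """w_i = exp(-(AICc_i - min AICc)/2), normalized to sum to 1."""
    aicc = np.asarray(aicc, float)
    finite = np.isfinite(aicc)
    if not finite.any():
        raise ValueError("no finite AICc values")
    w = np.zeros_like(aicc)
    delta = aicc[finite] - aicc[finite].min()
    w[finite] = np.exp(-delta / 2.0)
    return w / w.sum()


def model_average(fits: list[FittedModel], weight_floor: float = 0.001) -> AveragedEffects:
    """Akaike-weight model averaging with unconditional standard errors.

    Models with weight <= ``weight_floor`` are dropped and the remaining
    weights renormalized.  The full average treats a coefficient as 0
    (variance 0) in models whose term set excludes it; the conditional
    average renormalizes over models containing it.  Unconditional SE is
    sqrt(sum_i w_i (se_i^2 + (b_i - bbar)^2)); p-values are two-sided
    normal on estimate/SE.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("model averaging needs at least one converged fit")
    w = akaike_weights(np.array([f.aicc for f in fits]))
    keep = w > weight_floor
    if not keep.any():
        raise ValueError("no models above the weight floor")
    fits = [f for f, k in zip(fits, keep) if k]
    w = w[keep] / w[keep].sum()

    all_names: list[str] = []
    for f in fits:
        for n in f.result.names:
            if n not in all_names:
                all_names.append(n)
    rows = []
    for name in all_names:
        est = np.zeros(len(fits))
        se = np.zeros(len(fits))
        present = np.zeros(len(fits), bool)
        for i, f in enumerate(fits):
            c = f.coef().get(name)
            if c is not None:
                est[i], se[i] = c
                present[i] = True
        b_full = float(w @ est)
        se_full = float(np.sqrt(w @ (se ** 2 + (est - b_full) ** 2)))
        pw = w[present]
        if pw.sum() > 0:
            pwn = pw / pw.sum()
            b_cond = float(pwn @ est[present])
            se_cond = float(np.sqrt(
                pwn @ (se[present] ** 2 + (est[present] - b_cond) ** 2)
            ))
        else:
            b_cond, se_cond = 0.0, np.nan
        z_full = b_full / se_full if se_full > 0 else np.nan
        z_cond = b_cond / se_cond if se_cond and np.isfinite(se_cond) and se_cond > 0 else np.nan
        p_full = float(2 * stats.norm.sf(abs(z_full))) if np.isfinite(z_full) else np.nan
        p_cond = float(2 * stats.norm.sf(abs(z_cond))) if np.isfinite(z_cond) else np.nan
        rows.append({
            "estimate": b_full, "se": se_full, "z": z_full, "p": p_full,
            "stars": stars(p_full) if np.isfinite(p_full) else "",
            "sig_class": significance_class(p_full) if np.isfinite(p_full) else "ns",
            "estimate_cond": b_cond, "se_cond": se_cond, "z_cond": z_cond, "p_cond": p_cond,
            "weight": float(pw.sum()),
        })
    table = pd.DataFrame(rows, index=pd.Index(all_names, name="coefficient"))
    return AveragedEffects(table=table, model_set_size=len(fits), weights=w)


def full_analysis(
    species: pd.DataFrame,
    ranges: pd.DataFrame,
    include_pld: bool = False,
    subset_col: str | None = None,
    include_interaction: bool = True,
    weight_floor: float = 0.001,
    d_ref_km: float = DEFAULT_D_REF_KM,
    eps: float = DEFAULT_EPS,
) -> FullAnalysisResult:
    """The complete modelling stage: standardize -> VIF screen -> enumerate
    -> fit all candidate models -> model-average.

    ``subset_col`` restricts the analysis to rows where that boolean
    column of ``species`` is true (e.g. the focal PLD subset).
    """
    if subset_col is not None:
        species = species.loc[species[subset_col].astype(bool)]
    y, X, rand = build_design(species, ranges, include_pld, d_ref_km, eps)

    main_cols = [c for t in _MAIN_TERMS for c in TERM_COLUMNS[t]]
    if include_pld:
        main_cols += list(TERM_COLUMNS["pld"])
    vif = compute_vif(X[main_cols])
    flagged = [c for c in vif.index if vif[c] >= VIF_THRESHOLD]
    if flagged:
        logger.warning("VIF >= %.1f for predictors: %s", VIF_THRESHOLD, flagged)

    terms = list(_MAIN_TERMS) + (["pld"] if include_pld else [])
    if include_interaction:
        terms.append(_INTERACTION)
    global_spec = ModelSpec(tuple(terms))
    # a severely unbalanced subset can make the interaction columns exactly
    # collinear with the mains (e.g. every medium-mobility species pelagic);
    # the interaction is then inestimable and is dropped, as lmer would
    def _rank_ok(spec: ModelSpec) -> bool:
        M = np.column_stack(
            [np.ones(len(X))] + [X[c].to_numpy(float) for c in spec.columns]
        )
        return np.linalg.matrix_rank(M) == M.shape[1]

    if not _rank_ok(global_spec):
        if include_interaction and _rank_ok(ModelSpec(tuple(t for t in terms if t != _INTERACTION))):
            logger.warning("interaction inestimable in this subset; dropped")
            terms.remove(_INTERACTION)
            global_spec = ModelSpec(tuple(terms))
        else:
            raise ValueError("fixed-effect design is rank deficient")
    factors, dropped = _make_factors(rand, global_spec.random_terms)
    if dropped:
        logger.info("random factors dropped (<2 levels): %s", dropped)

    all_cols = list(global_spec.columns)
    X_full = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in all_cols])
    cp = lmm.CrossProducts(y.to_numpy(float), X_full, factors)
    col_pos = {c: i + 1 for i, c in enumerate(all_cols)}

    # global fit first: its variance ratios warm-start every submodel
    glob = lmm.fit_ml(
        y.to_numpy(float), X_full, factors,
        names=["intercept"] + all_cols, cross_products=cp,
        col_idx=np.arange(X_full.shape[1]),
    )
    theta0 = np.maximum(glob.theta, 1e-6) if glob.converged else None

    fits: list[FittedModel] = []
    n_unconverged = 0
    for spec in enumerate_submodels(global_spec):
        idx = np.array([0] + [col_pos[c] for c in spec.columns], dtype=int)
        try:
            res = lmm.fit_ml(
                y.to_numpy(float), X_full, factors,
                names=["intercept"] + list(spec.columns),
                theta0=theta0, cross_products=cp, col_idx=idx,
            )
        except np.linalg.LinAlgError:
            n_unconverged += 1
            continue
        fm = FittedModel(spec, res)
        if fm.converged:
            fits.append(fm)
        else:
            n_unconverged += 1
    if n_unconverged:
        logger.info("%d submodels failed to converge and were excluded", n_unconverged)

    effects = model_average(fits, weight_floor=weight_floor)
    aiccs = np.array([f.aicc for f in fits])
    wts = akaike_weights(aiccs)
    model_table = pd.DataFrame({
        "terms": [" + ".join(f.spec.fixed_terms) or "(intercept)" for f in fits],
        "k": [f.result.k_params for f in fits],
        "logLik": [f.loglik for f in fits],
        "aicc": aiccs,
        "weight": wts,
    }).sort_values("aicc", ignore_index=True)
    return FullAnalysisResult(
        effects=effects, vif=vif, vif_flagged=flagged, model_table=model_table,
        n_models=len(fits) + n_unconverged, n_unconverged=n_unconverged,
        dropped_random=dropped, n_obs=len(y),
    )
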