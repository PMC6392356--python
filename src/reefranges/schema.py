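"""Shared trait vocabularies, reference levels and design-column naming.

Reference levels follow the convention used throughout the analysis:
nonpelagic eggs, low adult mobility, nonaggregative, diurnal.
"""

from __future__ import annotations

#: Categorical trait vocabularies (first entry = reference level).
TRAIT_LEVELS: dict[str, tuple[str, ...]] = {
    "spawning_mode": ("nonpelagic", "pelagic"),
    "mobility": ("low", "medium", "high"),
    "circadian": ("diurnal", "crepuscular", "nocturnal"),
    "aggregation": ("nonaggregative", "temporarily_aggregative", "aggregative"),
    "basin": ("TEP_endemic", "transpacific"),
    "structure": ("coastline", "island"),
}

#: Behavioural traits entering the fixed-effect structure.
FIXED_FACTORS = ("spawning_mode", "mobility", "circadian", "aggregation")

#: Grouping factors entering as random intercepts (plus taxonomy).
RANDOM_FACTORS = ("order", "family", "genus", "basin", "structure")

#: Design-column names per selectable model term.  "spawning" is a centred
#: binary column; multi-level factors are dummy-coded against the
#: reference level; the interaction crosses centred spawning with the
#: mobility dummies.
TERM_COLUMNS: dict[str, tuple[str, ...]] = {
    "body_size": ("body_size",),
    "spawning": ("spawning_pelagic",),
    "mobility": ("mobility_medium", "mobility_high"),
    "circadian": ("circadian_crepuscular", "circadian_nocturnal"),
    "aggregation": ("aggregation_temporarily_aggregative", "aggregation_aggregative"),
    "pld": ("pld",),
    "spawning:mobility": (
        "spawning_pelagic:mobility_medium",
        "spawning_pelagic:mobility_high",
    ),
}

#: Columns a species table must carry.
SPECIES_COLUMNS = (
    "species_id", "order", "family", "genus", "body_size_cm",
    "spawning_mode", "mobility", "circadian", "aggregation",
    "basin", "structure", "pld_days",
)

#: Significance star classes used in reports (p thresholds).
STAR_THRESHOLDS = ((1e-4, "***"), (1e-3, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for thr, mark in STAR_THRESHOLDS:
        if p < thr:
            return mark
    return ""


def significance_class(p: float) -> str:
    """Bin a p-value into the star classes: '<0.0001', '<0.001', '<0.05', 'ns'."""
    if p < 1e-4:
        return "<0.0001"
    if p < 1e-3:
        return "<0.001"
    if p < 0.05:
        return "<0.05"
    return "ns"
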