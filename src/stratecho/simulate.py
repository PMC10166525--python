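"""Synthetic longitudinal echo-feature cohorts.

Generates wild-type (WT) vs diabetic (DB) animal-by-feature tables with the
statistical structure the downstream analysis assumes: Gaussian features,
class-mean shifts expressed as standardized effect sizes, equicorrelated
deformation-metric blocks, and randomly injected missing values and
outliers.  Each timepoint is simulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .schema import (
    GLOBAL_LOCALE,
    METRICS,
    PHASES,
    VIEW_DIMENSIONS,
    VIEWS,
    FeatureSchema,
)

CLASS_WT = "WT"
CLASS_DB = "DB"


@dataclass
class FeatureTable:
    """Animals x features values with class labels and a missing mask.

    ``values`` is ``(n_animals, n_features)`` float; cells with
    ``missing_mask`` True hold NaN and are undefined.
    """

    animal_ids: list[str]
    class_labels: np.ndarray  # (n,) of "WT"/"DB"
    timepoint_weeks: int
    feature_names: list[str]
    values: np.ndarray  # (n, p) float
    missing_mask: np.ndarray  # (n, p) bool

    def __post_init__(self):
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if len(self.animal_ids) != n or len(self.class_labels) != n:
            raise ValueError("animal_ids/class_labels length must match row count")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must match column count")
        if self.missing_mask.shape != (n, p):
            raise ValueError("missing_mask shape must match values")

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_index(self, features) -> np.ndarray:
        idx = {name: j for j, name in enumerate(self.feature_names)}
        missing = [f for f in features if f not in idx]
        if missing:
            raise KeyError(f"unknown feature names: {missing}")
        return np.array([idx[f] for f in features], dtype=int)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            animal_ids=list(self.animal_ids),
            class_labels=self.class_labels.copy(),
            timepoint_weeks=self.timepoint_weeks,
            feature_names=list(self.feature_names),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
        )

    def restrict(self, features) -> "FeatureTable":
        """New table holding only the listed feature columns (in that order)."""
        cols = self.column_index(features)
        return FeatureTable(
            animal_ids=list(self.animal_ids),
            class_labels=self.class_labels.copy(),
            timepoint_weeks=self.timepoint_weeks,
            feature_names=list(features),
            values=self.values[:, cols].copy(),
            missing_mask=self.missing_mask[:, cols].copy(),
        )

    def class_rows(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.class_labels == label)


@dataclass(frozen=True)
class EffectSpec:
    """Where, when and how strongly the diabetic phenotype shifts features.

    ``effects`` maps ``(locale, timepoint_weeks)`` to a standardized effect
    size d (DB minus WT class mean, in within-class SD units).  A locale may
    be a segment name, a region name (applied to every member segment's
    features), ``"global"``, ``"mmode"``, ``"pwd"``, or an exact feature
    name.  Overlapping effects add.
    """

    effects: Mapping[tuple[str, int], float] = field(default_factory=dict)
    within_class_sd: float = 1.0
    metric_correlation: float = 0.5
    missing_rate: float = 0.02
    outlier_rate: float = 0.01
    outlier_magnitude: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not self.within_class_sd > 0:
            raise ValueError("within_class_sd must be > 0")
        if not 0.0 <= self.metric_correlation < 1.0:
            raise ValueError("metric_correlation must be in [0, 1)")
        for name, rate in (("missing_rate", self.missing_rate), ("outlier_rate", self.outlier_rate)):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for (locale, week), d in self.effects.items():
            if not np.isfinite(d):
                raise ValueError(f"effect for ({locale}, {week}) is not finite")


#: Baseline class means for conventional features, on scales typical of
#: conscious-mouse echo (HR in BPM, dimensions in mm, volumes in uL, ...).
_MMODE_BASELINES = {
    "mmode_HR": 700.0,
    "mmode_EF": 95.0,
    "mmode_FS": 70.0,
    "mmode_CO": 10.0,
    "mmode_SV": 15.0,
    "mmode_LV_Mass": 100.0,
    "mmode_LV_Mass_Cor": 80.0,
    "mmode_LVAW_s": 1.8,
    "mmode_LVAW_d": 1.1,
    "mmode_LVPW_s": 1.9,
    "mmode_LVPW_d": 1.3,
    "mmode_LVED_s": 0.7,
    "mmode_LVED_d": 2.1,
    "mmode_LVEV_s": 1.0,
    "mmode_LVEV_d": 16.0,
    "mmode_MPI": 0.7,
    "mmode_Endo_Area_d": 18.0,
}

#: STE deformation baselines by dimension.  Radial thickening reads positive;
#: circumferential and longitudinal shortening read negative, so that the
#: downstream absolute-value step is sign-consistent.
_STE_DIM_BASELINE = {"radial": 10.0, "circumferential": -10.0, "longitudinal": -10.0}


def _baseline_mean(feature: str, schema: FeatureSchema) -> float:
    if feature.startswith("mmode_"):
        return _MMODE_BASELINES.get(feature, 5.0)
    if feature.startswith("pwd_"):
        return 1.0
    parts = feature.split("_")
    if len(parts) >= 5 and parts[0] in VIEWS and parts[1] in PHASES:
        return _STE_DIM_BASELINE.get(parts[3], 10.0)
    return 10.0  # global whole-trace fillers


def resolve_effects(
    schema: FeatureSchema, spec: EffectSpec, timepoint_weeks: int
) -> np.ndarray:
    """Per-feature standardized effect d at one timepoint.

    Segment, region, family ("global"/"mmode"/"pwd") and exact-feature
    locales are resolved against the schema; overlapping locales sum.
    """
    features = schema.all_features
    d = np.zeros(len(features))
    name_to_col = {f: j for j, f in enumerate(features)}
    for (locale, week), effect in spec.effects.items():
        if week != timepoint_weeks:
            continue
        if locale in name_to_col:
            d[name_to_col[locale]] += effect
            continue
        if locale in schema.segments:
            targets = schema.segment_features[locale]
        elif locale in schema.region_map:
            targets = [
                f
                for seg in schema.region_map[locale]
                for f in schema.segment_features[seg]
            ]
        elif locale in ("global", GLOBAL_LOCALE):
            targets = schema.global_features
        elif locale == "mmode":
            targets = schema.mmode_features
        elif locale == "pwd":
            targets = schema.pwd_features
        else:
            raise ValueError(f"effect locale {locale!r} matches no schema locale or feature")
        for f in targets:
            d[name_to_col[f]] += effect
    return d


def _correlation_blocks(schema: FeatureSchema) -> list[np.ndarray]:
    """Column groups sharing one latent factor: the deformation metrics of a
    segment/Global locale within one view and phase (8 features each)."""
    features = schema.all_features
    name_to_col = {f: j for j, f in enumerate(features)}
    blocks = []
    locales = list(schema.segments) + [GLOBAL_LOCALE]
    for locale in locales:
        for view in VIEWS:
            for phase in PHASES:
                cols = []
                for dim in VIEW_DIMENSIONS[view]:
                    for metric in METRICS:
                        name = f"{view}_{phase}_{locale}_{dim}_{metric}"
                        if name in name_to_col:
                            cols.append(name_to_col[name])
                if len(cols) > 1:
                    blocks.append(np.array(cols, dtype=int))
    return blocks


def simulate_cohort(
    schema: FeatureSchema,
    spec: EffectSpec,
    n_wt: int = 14,
    n_db: int = 13,
    timepoint_weeks: int = 20,
    seed: int | None = None,
) -> FeatureTable:
    """Simulate one timepoint of a WT/DB cohort.

    Feature values are Gaussian with within-class SD ``spec.within_class_sd``;
    DB-class means are shifted by ``d x SD`` on features of affected locales.
    Deformation-metric blocks within one segment/view/phase share a latent
    factor giving pairwise correlation ``spec.metric_correlation``.  Missing
    values and additive outliers (``+/- outlier_magnitude x SD``) are
    injected uniformly at random over cells; the LV-mass column is exempt
    because it is the divisor of downstream mass normalization.

    Deterministic for fixed (schema, spec, counts, timepoint, seed); the seed
    defaults to ``spec.seed`` and is mixed with the timepoint so different
    weeks draw independent noise.
    """
    if n_wt < 2 or n_db < 2:
        raise ValueError("need at least 2 animals per class for class-wise statistics")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(timepoint_weeks)]))

    features = schema.all_features
    n = n_wt + n_db
    p = len(features)
    rho = spec.metric_correlation

    z = rng.standard_normal((n, p))
    if rho > 0:
        for cols in _correlation_blocks(schema):
            shared = rng.standard_normal(n)
            z[:, cols] = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * z[:, cols]

    sd = spec.within_class_sd
    baseline = np.array([_baseline_mean(f, schema) for f in features])
    values = baseline[None, :] + sd * z

    d = resolve_effects(schema, spec, timepoint_weeks)
    labels = np.array([CLASS_WT] * n_wt + [CLASS_DB] * n_db, dtype=object)
    db_rows = labels == CLASS_DB
    values[db_rows] += d[None, :] * sd

    exempt = np.zeros(p, dtype=bool)
    if schema.lv_mass_feature in features:
        exempt[features.index(schema.lv_mass_feature)] = True

    outlier_cells = (rng.random((n, p)) < spec.outlier_rate) & ~exempt[None, :]
    signs = np.where(rng.random((n, p)) < 0.5, -1.0, 1.0)
    values = values + outlier_cells * signs * spec.outlier_magnitude * sd

    missing = (rng.random((n, p)) < spec.missing_rate) & ~exempt[None, :]
    values[missing] = np.nan

    ids = [f"WT{i + 1:02d}" for i in range(n_wt)] + [f"DB{i + 1:02d}" for i in range(n_db)]
    return FeatureTable(
        animal_ids=ids,
        class_labels=labels,
        timepoint_weeks=timepoint_weeks,
        feature_names=list(features),
        values=values,
        missing_mask=missing,
    )


def progressive_preset(seed: int = 0) -> EffectSpec:
    """Default effect layout emulating progressive diabetic cardiac dysfunction.

    Week 5: no conventional M-mode differences (in particular no EF/FS
    effect); mild septal-wall STE effects, AntSeptum-dominant.  Week 12:
    structural M-mode remodeling (LV mass, wall thicknesses, volumes) and
    anterior-free/lateral STE dominance.  Weeks 20 and 25: contractile
    dysfunction (EF/FS decrease) on top of maintained structural changes,
    with AntSeptum-dominant STE effects.
    """
    effects: dict[tuple[str, int], float] = {
        # week 5 — subclinical, septal-dominant STE only
        ("AntSeptum", 5): 1.0,
        ("InfFreeWall", 5): 0.8,
        ("PostSeptal", 5): 0.5,
        ("mmode_MPI", 5): 0.8,
        # week 12 — structural remodeling; AnteriorFree/LatWall STE dominance
        ("LatWall", 12): 1.5,
        ("AntFree", 12): 1.2,
        ("AntSeptum", 12): 1.0,
        ("mmode_LV_Mass", 12): 2.0,
        ("mmode_LVAW_s", 12): 1.2,
        ("mmode_LVPW_s", 12): 1.2,
        ("mmode_LVPW_d", 12): 1.0,
        ("mmode_SV", 12): 1.0,
        ("mmode_LVED_d", 12): 0.8,
        ("mmode_LVEV_d", 12): 0.8,
        # week 20 — overt contractile dysfunction; AntSeptum-dominant STE
        ("AntSeptum", 20): 1.5,
        ("LatWall", 20): 1.0,
        ("PostSeptal", 20): 0.9,
        ("PostWall", 20): 0.8,
        ("global", 20): 0.5,
        ("mmode_LV_Mass", 20): 2.0,
        ("mmode_EF", 20): -1.5,
        ("mmode_FS", 20): -1.5,
        ("mmode_HR", 20): -1.0,
        ("mmode_LVAW_d", 20): 1.0,
        ("mmode_LVED_s", 20): 1.2,
        ("mmode_LVEV_s", 20): 1.2,
        ("mmode_SV", 20): 1.2,
        # week 25 — maintained dysfunction; anterior-wall STE spread
        ("AntSeptum", 25): 1.5,
        ("AntFree", 25): 1.3,
        ("LatWall", 25): 1.1,
        ("global", 25): 1.0,
        ("mmode_LV_Mass", 25): 2.2,
        ("mmode_EF", 25): -1.5,
        ("mmode_FS", 25): -1.5,
        ("mmode_HR", 25): -0.8,
        ("mmode_LVAW_d", 25): 1.0,
        ("mmode_LVAW_s", 25): 1.0,
        ("mmode_LVEV_s", 25): 1.2,
        ("mmode_SV", 25): 1.0,
    }
    return EffectSpec(effects=effects, seed=seed)


def null_spec(seed: int = 0, **overrides) -> EffectSpec:
    """Effect spec with no class differences (d = 0 everywhere)."""
    return replace(EffectSpec(effects={}, seed=seed), **overrides)
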