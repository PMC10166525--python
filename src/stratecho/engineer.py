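"""Feature engineering: from raw echo features to analysis-ready datasets.

The pipeline order mirrors the analysis this package implements: STE values
are taken as absolute, normalized to LV mass, averaged into regional
features, cleaned (outlier detection + mean imputation), min-max scaled,
and finally partitioned into 17 named datasets (Complete plus 16 feature
subsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schema import FeatureSchema, ste_feature_names, VIEWS, PHASES, VIEW_DIMENSIONS, METRICS
from .simulate import FeatureTable

#: The 17 dataset partition names, in reporting order.
PARTITION_NAMES = (
    "Complete",
    "PWD",
    "M-mode",
    "Global",
    "Segmental",
    "Anterior",
    "Posterior",
    "Septal",
    "Free",
    "AnteriorFree",
    "PosteriorFree",
    "AntFree",
    "LatWall",
    "PostWall",
    "InfFreeWall",
    "PostSeptal",
    "AntSeptum",
)


class EngineeringError(ValueError):
    pass


def absolutize(table: FeatureTable, ste_features) -> FeatureTable:
    """Replace the listed columns by their absolute values.

    STE velocity/displacement/strain values are signed by direction of
    motion; magnitude is the quantity of interest.  Other columns and the
    missing mask are untouched.
    """
    out = table.copy()
    cols = out.column_index(ste_features)
    out.values[:, cols] = np.abs(out.values[:, cols])
    return out


def normalize_to_lv_mass(
    table: FeatureTable, ste_features, lv_mass_feature: str = "mmode_LV_Mass"
) -> FeatureTable:
    """Divide each listed STE value by that animal's LV mass.

    The LV-mass column itself is unchanged and must be strictly positive and
    non-missing for every animal.
    """
    out = table.copy()
    (mass_col,) = out.column_index([lv_mass_feature])
    mass = out.values[:, mass_col]
    bad_missing = out.missing_mask[:, mass_col]
    bad_value = ~bad_missing & ~(mass > 0)
    if bad_missing.any() or bad_value.any():
        offenders = [
            table.animal_ids[i]
            for i in np.flatnonzero(bad_missing | bad_value)
        ]
        raise EngineeringError(
            f"LV mass missing or non-positive for animals {offenders}"
        )
    cols = out.column_index(ste_features)
    out.values[:, cols] = out.values[:, cols] / mass[:, None]
    return out


def derive_regions(
    table: FeatureTable, schema: FeatureSchema, strict_missing: bool = False
) -> FeatureTable:
    """Append region-average features for every region in the schema.

    For each region and each (view, phase, dimension, metric) the new
    feature is the arithmetic mean of the member segments' values.  By
    default a region value is computed from the non-missing members and is
    flagged missing only if all members are missing (cleaning happens
    downstream); ``strict_missing=True`` propagates any member missingness.
    """
    out = table.copy()
    new_names: list[str] = []
    new_vals: list[np.ndarray] = []
    new_miss: list[np.ndarray] = []
    for region, members in schema.region_map.items():
        for view in VIEWS:
            for phase in PHASES:
                for dim in VIEW_DIMENSIONS[view]:
                    for metric in METRICS:
                        member_feats = [
                            f"{view}_{phase}_{seg}_{dim}_{metric}" for seg in members
                        ]
                        try:
                            cols = out.column_index(member_feats)
                        except KeyError as exc:
                            raise EngineeringError(
                                f"region {region}: missing member feature column ({exc})"
                            ) from exc
                        vals = out.values[:, cols]
                        miss = out.missing_mask[:, cols]
                        if strict_missing:
                            region_miss = miss.any(axis=1)
                        else:
                            region_miss = miss.all(axis=1)
                        n_obs = (~miss).sum(axis=1)
                        region_val = np.where(miss, 0.0, vals).sum(axis=1) / np.maximum(n_obs, 1)
                        region_val[region_miss] = np.nan
                        new_names.append(f"{view}_{phase}_{region}_{dim}_{metric}")
                        new_vals.append(region_val)
                        new_miss.append(region_miss)
    return FeatureTable(
        animal_ids=list(out.animal_ids),
        class_labels=out.class_labels,
        timepoint_weeks=out.timepoint_weeks,
        feature_names=out.feature_names + new_names,
        values=np.column_stack([out.values] + new_vals),
        missing_mask=np.column_stack([out.missing_mask] + new_miss),
    )


def detect_outliers(
    table: FeatureTable, rule: str = "tukey", factor: float = 1.5
) -> np.ndarray:
    """Boolean mask of outlier cells, computed per feature within each class.

    ``rule="tukey"`` flags values outside [Q1 - f*IQR, Q3 + f*IQR]
    (f = ``factor``, default 1.5); ``rule="mean_sd"`` flags values more than
    ``factor`` SDs from the class mean (use factor=2 for the common +/-2SD
    rule).  A feature/class with fewer than 3 non-missing values yields no
    flags there.
    """
    if rule not in ("tukey", "mean_sd"):
        raise EngineeringError(f"unknown outlier rule {rule!r}")
    mask = np.zeros_like(table.missing_mask)
    for label in np.unique(table.class_labels):
        rows = table.class_rows(label)
        for j in range(table.n_features):
            obs = rows[~table.missing_mask[rows, j]]
            if obs.size < 3:
                continue
            x = table.values[obs, j]
            if rule == "tukey":
                q1, q3 = np.percentile(x, [25, 75])
                iqr = q3 - q1
                lo, hi = q1 - factor * iqr, q3 + factor * iqr
            else:
                mu, sd = x.mean(), x.std(ddof=1)
                lo, hi = mu - factor * sd, mu + factor * sd
            flag = (x < lo) | (x > hi)
            mask[obs[flag], j] = True
    return mask


@dataclass
class CleaningReport:
    """Bookkeeping for the imputation step.

    ``imputed_cells`` lists (animal_id, feature, kind, new_value) where kind
    is "missing" or "outlier"; counts are per feature per class.
    """

    rule: str
    scope: str
    missing_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    outlier_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    imputed_cells: list[tuple[str, str, str, float]] = field(default_factory=list)

    @property
    def n_imputed(self) -> int:
        return len(self.imputed_cells)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "scope": self.scope,
            "missing_counts": self.missing_counts,
            "outlier_counts": self.outlier_counts,
            "imputed_cells": [
                {"animal_id": a, "feature": f, "kind": k, "value": v}
                for a, f, k, v in self.imputed_cells
            ],
        }


def impute(
    table: FeatureTable,
    outlier_mask: np.ndarray | None = None,
    scope: str = "per-class",
    rule: str = "tukey",
) -> tuple[FeatureTable, CleaningReport]:
    """Replace missing and outlier cells with the mean of clean values.

    The mean is taken over clean (neither missing nor flagged) values within
    the imputation scope: the animal's class by default, or the pooled
    cohort with ``scope="pooled"``.  The output table has an empty missing
    mask; the report enumerates every replacement.
    """
    if scope not in ("per-class", "pooled"):
        raise EngineeringError(f"unknown imputation scope {scope!r}")
    if outlier_mask is None:
        outlier_mask = np.zeros_like(table.missing_mask)
    outlier_mask = np.asarray(outlier_mask, dtype=bool)
    if outlier_mask.shape != table.values.shape:
        raise EngineeringError("outlier mask shape must match table")

    out = table.copy()
    report = CleaningReport(rule=rule, scope=scope)
    dirty = table.missing_mask | outlier_mask
    labels = np.unique(table.class_labels)

    class_rows = {str(lab): table.class_rows(lab) for lab in labels}
    for j, f in enumerate(table.feature_names):
        report.missing_counts[f] = {
            lab: int(table.missing_mask[rows, j].sum()) for lab, rows in class_rows.items()
        }
        report.outlier_counts[f] = {
            lab: int(outlier_mask[rows, j].sum()) for lab, rows in class_rows.items()
        }

    groups = (
        [(str(lab), table.class_rows(lab)) for lab in labels]
        if scope == "per-class"
        else [("pooled", np.arange(table.n_animals))]
    )
    for _, rows in groups:
        for j, fname in enumerate(table.feature_names):
            cell_dirty = dirty[rows, j]
            if not cell_dirty.any():
                continue
            clean = rows[~cell_dirty]
            if clean.size == 0:
                raise EngineeringError(
                    f"feature {fname!r} has no clean values in imputation scope"
                )
            fill = table.values[clean, j].mean()
            for i in rows[cell_dirty]:
                kind = "missing" if table.missing_mask[i, j] else "outlier"
                report.imputed_cells.append((table.animal_ids[i], fname, kind, float(fill)))
                out.values[i, j] = fill
    out.missing_mask[:] = False
    return out, report


def minmax_scale(
    table: FeatureTable, fit_rows: np.ndarray | None = None
) -> FeatureTable:
    """Map each feature to (x - min) / (max - min).

    Extremes are taken over ``fit_rows`` (all rows by default, matching a
    scale-before-split workflow; pass training rows for the leakage-safe
    variant — values outside the fitted range then map outside [0, 1]).
    Constant features map to 0.  Requires a fully observed table.
    """
    if table.missing_mask.any():
        raise EngineeringError("minmax_scale requires an imputed (fully observed) table")
    out = table.copy()
    rows = np.arange(table.n_animals) if fit_rows is None else np.asarray(fit_rows)
    lo = out.values[rows].min(axis=0)
    hi = out.values[rows].max(axis=0)
    span = hi - lo
    constant = span == 0
    span_safe = np.where(constant, 1.0, span)
    out.values = (out.values - lo[None, :]) / span_safe[None, :]
    out.values[:, constant] = 0.0
    return out


@dataclass
class DatasetPartition:
    """One named feature subset with its restricted table."""

    name: str
    member_features: list[str]
    table: FeatureTable


def partition_features(table_features: list[str], schema: FeatureSchema) -> dict[str, list[str]]:
    """Feature membership for each of the 17 named partitions.

    Segment partitions hold that segment's STE features; region partitions
    hold the member segments' STE features plus the region's derived
    averages; Segmental is the union of the six segment partitions;
    Complete is everything in original column order.
    """
    have = set(table_features)
    missing = [f for f in schema.all_features if f not in have]
    if missing:
        raise EngineeringError(f"table lacks schema features: {missing[:8]}{'...' if len(missing) > 8 else ''}")

    def ordered(feats) -> list[str]:
        want = set(feats)
        return [f for f in table_features if f in want]

    members: dict[str, list[str]] = {}
    members["Complete"] = list(table_features)
    members["PWD"] = ordered(schema.pwd_features)
    members["M-mode"] = ordered(schema.mmode_features)
    members["Global"] = ordered(schema.global_features)
    members["Segmental"] = ordered(schema.all_ste_segment_features)
    for seg in schema.segments:
        members[seg] = ordered(schema.segment_features[seg])
    for region, segs in schema.region_map.items():
        feats = [f for s in segs for f in schema.segment_features[s]]
        region_avgs = [f for f in schema.region_feature_names(region) if f in have]
        if len(region_avgs) < len(schema.region_feature_names(region)):
            raise EngineeringError(
                f"region partition {region} requires derived region-average features; run derive_regions first"
            )
        members[region] = ordered(feats) + ordered(region_avgs)
    return {name: members[name] for name in PARTITION_NAMES}


def partition_datasets(table: FeatureTable, schema: FeatureSchema) -> list[DatasetPartition]:
    """Split an engineered table into the 17 named dataset partitions."""
    membership = partition_features(table.feature_names, schema)
    return [
        DatasetPartition(name=name, member_features=feats, table=table.restrict(feats))
        for name, feats in membership.items()
    ]


def prepare_table(table: FeatureTable, schema: FeatureSchema) -> FeatureTable:
    """Pre-cleaning stage: absolutize STE -> normalize to LV mass -> derive
    regions.  Missing cells are preserved; this is the "raw" table the
    univariate statistics run on (cleaning happens only for the classifier
    path)."""
    ste = schema.all_ste_segment_features + [
        f for f in schema.global_features if schema.locale_of(f) == "Global"
    ]
    ste = [f for f in ste if f in table.feature_names]
    t = absolutize(table, ste)
    t = normalize_to_lv_mass(t, ste, schema.lv_mass_feature)
    return derive_regions(t, schema)


def engineer_table(
    table: FeatureTable,
    schema: FeatureSchema,
    outlier_rule: str = "tukey",
    impute_scope: str = "per-class",
) -> tuple[FeatureTable, CleaningReport]:
    """Full engineering chain on one raw cohort table.

    absolutize STE -> normalize to LV mass -> derive regions -> detect
    outliers -> impute -> min-max scale.  Returns the scaled table (with
    region-average columns appended) and the cleaning report.
    """
    t = prepare_table(table, schema)
    outliers = detect_outliers(t, rule=outlier_rule)
    t, report = impute(t, outliers, scope=impute_scope, rule=outlier_rule)
    t = minmax_scale(t)
    return t, report
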