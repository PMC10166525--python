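"""Spatial readouts: prevalence and strongest-identifier rankings.

Two complementary views of where dysfunction concentrates:

* **Most prevalent** — which segments and regions occupy the largest share
  of the top-k ReliefF-ranked features.  Region scores are normalized by
  member-segment count (a two-segment region is not rewarded for being
  larger) and renormalized to sum to 100% across the six regions.
* **Strongest identifier** — which dataset partitions classify animals
  with the highest held-out accuracy, averaged across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .engineer import DatasetPartition
from .relieff import ReliefFResult, select_relevant, select_top_k
from .schema import FeatureSchema


class StratifyError(ValueError):
    pass


def round1(x: float) -> float:
    """Round to one decimal, ties away from zero (reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _mean1(values) -> float:
    """One-decimal half-away-from-zero mean of printed-precision inputs."""
    total = sum(Decimal(repr(float(v))) for v in values)
    return float((total / len(values)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PrevalenceReport:
    """Top-k occupancy of segments and regions.

    Segment percentages are counts over ``top_k``.  Region raw counts sum
    member-segment counts; the normalized score is (raw / top_k) divided by
    the member-segment count, and reported region percentages renormalize
    those scores to sum to 100.  ``region_decomposition`` gives each member
    segment's percentage share of its region's raw count.
    ``locale_of_greatest_impact`` is the (region, segment) pair with the
    maximal reported percentage / count.
    """

    top_k: int
    segment_counts: dict[str, int]
    segment_percentages: dict[str, float]
    region_raw_counts: dict[str, int]
    region_normalized_scores: dict[str, float]
    region_percentages: dict[str, float]
    region_decomposition: dict[str, dict[str, float]]
    locale_of_greatest_impact: tuple[str, str]
    non_segmental_count: int = 0

    def to_dict(self) -> dict:
        return {
            "top_k": self.top_k,
            "segment_counts": self.segment_counts,
            "segment_percentages": self.segment_percentages,
            "region_raw_counts": self.region_raw_counts,
            "region_normalized_scores": self.region_normalized_scores,
            "region_percentages": self.region_percentages,
            "region_decomposition": self.region_decomposition,
            "locale_of_greatest_impact": list(self.locale_of_greatest_impact),
            "non_segmental_count": self.non_segmental_count,
        }


def prevalence_report(
    top_features, schema: FeatureSchema, top_k: int | None = None
) -> PrevalenceReport:
    """Full segment + region prevalence accounting for a top-feature list.

    Only features attributed to a single segment enter segment counts;
    region-average, global, M-mode and PWD features are tallied separately
    (``non_segmental_count``) to avoid double counting.
    """
    top_features = list(top_features)
    if not top_features:
        raise StratifyError("top_features must be non-empty")
    k = top_k if top_k is not None else len(top_features)
    seg_counts = {seg: 0 for seg in schema.segments}
    non_segmental = 0
    for f in top_features:
        locale = schema.locale_of(f)  # raises for unparseable names
        if locale in seg_counts:
            seg_counts[locale] += 1
        else:
            non_segmental += 1
    seg_pct = {seg: 100.0 * c / k for seg, c in seg_counts.items()}

    raw = {
        region: sum(seg_counts[s] for s in members)
        for region, members in schema.region_map.items()
    }
    norm = {
        region: (raw[region] / k) / len(members)
        for region, members in schema.region_map.items()
    }
    total_norm = sum(norm.values())
    if total_norm > 0:
        pct = {region: 100.0 * s / total_norm for region, s in norm.items()}
    else:
        pct = {region: 0.0 for region in norm}

    decomposition = {}
    for region, members in schema.region_map.items():
        if raw[region] > 0:
            decomposition[region] = {
                s: 100.0 * seg_counts[s] / raw[region] for s in members
            }
        else:
            decomposition[region] = {s: 0.0 for s in members}

    top_region = max(pct, key=lambda r: (pct[r], r))
    top_segment = max(seg_counts, key=lambda s: (seg_counts[s], s))
    return PrevalenceReport(
        top_k=k,
        segment_counts=seg_counts,
        segment_percentages=seg_pct,
        region_raw_counts=raw,
        region_normalized_scores=norm,
        region_percentages=pct,
        region_decomposition=decomposition,
        locale_of_greatest_impact=(top_region, top_segment),
        non_segmental_count=non_segmental,
    )


def segment_prevalence(top_features, schema: FeatureSchema, top_k: int | None = None) -> PrevalenceReport:
    """Segment-level occupancy of the top-k feature list (full report returned)."""
    return prevalence_report(top_features, schema, top_k)


def region_prevalence(top_features, schema: FeatureSchema, top_k: int | None = None) -> PrevalenceReport:
    """Region-level normalized occupancy of the top-k feature list."""
    return prevalence_report(top_features, schema, top_k)


@dataclass
class StrongestIdentifierRanking:
    """Datasets ordered by cross-timepoint average test accuracy.

    ``entries`` holds (dataset, {week: accuracy}, average, flagged) with the
    average rounded half-away-from-zero to one decimal; ties in the ordering
    break by dataset name.  ``threshold`` marks high-accuracy datasets.
    """

    entries: list[tuple[str, dict[int, float], float, bool]]
    threshold: float = 85.0
    timepoints: list[int] = field(default_factory=list)

    @property
    def order(self) -> list[str]:
        return [name for name, *_ in self.entries]

    def average_of(self, dataset: str) -> float:
        for name, _, avg, _ in self.entries:
            if name == dataset:
                return avg
        raise KeyError(dataset)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "timepoints": self.timepoints,
            "entries": [
                {
                    "dataset": name,
                    "per_timepoint": {str(w): a for w, a in tp.items()},
                    "average": avg,
                    "high_accuracy": flag,
                }
                for name, tp, avg, flag in self.entries
            ],
        }


def rank_strongest_identifiers(
    accuracies: dict[str, dict[int, float]],
    threshold: float = 85.0,
) -> StrongestIdentifierRanking:
    """Rank datasets by the mean of their per-timepoint test accuracies.

    ``accuracies`` maps dataset name -> {timepoint_weeks: mean test
    accuracy}; every dataset must cover the same timepoints.  Averages are
    rounded to one decimal, half away from zero.
    """
    if not accuracies:
        raise StratifyError("no datasets given")
    timepoints = None
    for name, per_tp in accuracies.items():
        tps = sorted(per_tp)
        if timepoints is None:
            timepoints = tps
        elif tps != timepoints:
            raise StratifyError(
                f"dataset {name!r} timepoints {tps} differ from {timepoints}"
            )
    entries = []
    for name, per_tp in accuracies.items():
        avg = _mean1([per_tp[w] for w in timepoints])
        entries.append((name, dict(per_tp), avg, avg >= threshold))
    entries.sort(key=lambda e: (-e[2], e[0]))
    return StrongestIdentifierRanking(entries=entries, threshold=threshold, timepoints=timepoints)


@dataclass
class FeatureReductionReport:
    """Test-accuracy effect of ReliefF-based dimensionality reduction."""

    dataset: str
    full_accuracy: float
    full_n_features: int
    relevant_accuracy: float | None
    relevant_n_features: int
    top_k_accuracy: float
    top_k_n_features: int
    notes: list[str] = field(default_factory=list)

    @property
    def relevant_delta(self) -> float | None:
        if self.relevant_accuracy is None:
            return None
        return self.relevant_accuracy - self.full_accuracy

    @property
    def top_k_delta(self) -> float:
        return self.top_k_accuracy - self.full_accuracy

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "full": {"accuracy": self.full_accuracy, "n_features": self.full_n_features},
            "relevant": {
                "accuracy": self.relevant_accuracy,
                "n_features": self.relevant_n_features,
                "delta": self.relevant_delta,
            },
            "top_k": {
                "accuracy": self.top_k_accuracy,
                "n_features": self.top_k_n_features,
                "delta": self.top_k_delta,
            },
            "notes": self.notes,
        }


def feature_reduction_eval(
    complete: DatasetPartition,
    relieff_result: ReliefFResult,
    top_k: int = 50,
    n_iterations: int = 5,
    cv_folds: int = 5,
    seed: int = 0,
    train_frac: float = 0.65,
) -> FeatureReductionReport:
    """Compare the full feature set against weight>0 and top-k reductions.

    All three evaluations share the harness seed and therefore identical
    split plans, so accuracy deltas reflect the feature sets alone.  An
    empty weight>0 subset is noted and skipped.
    """
    from .classify import evaluate_partition  # local import to avoid cycle

    def run(features, name):
        part = DatasetPartition(
            name=name,
            member_features=list(features),
            table=complete.table.restrict(features),
        )
        return evaluate_partition(
            part, n_iterations=n_iterations, cv_folds=cv_folds, seed=seed, train_frac=train_frac
        )

    full_eval = run(complete.member_features, complete.name)
    relevant = select_relevant(relieff_result)
    notes: list[str] = []
    if relevant:
        relevant_acc = run(relevant, f"{complete.name}|relevant").mean_test_accuracy
    else:
        relevant_acc = None
        notes.append("no features with weight > 0; relevant-subset evaluation skipped")
    top = select_top_k(relieff_result, top_k)
    top_eval = run(top, f"{complete.name}|top{top_k}")
    return FeatureReductionReport(
        dataset=complete.name,
        full_accuracy=full_eval.mean_test_accuracy,
        full_n_features=len(complete.member_features),
        relevant_accuracy=relevant_acc,
        relevant_n_features=len(relevant),
        top_k_accuracy=top_eval.mean_test_accuracy,
        top_k_n_features=len(top),
        notes=notes,
    )
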