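"""One-command reproduction of the full synthetic experiment.

Simulates all four timepoints with the progressive preset, runs the whole
pipeline (engineering, ReliefF, SVM evaluation of all 17 partitions,
prevalence, feature-reduction and univariate statistics) and prints the
cross-timepoint strongest-identifier summary.
"""

import stratecho as se

config = se.PipelineConfig(seed=1, n_iterations=2)  # 2 iterations to keep this quick
report = se.run_full_experiment(config)

print("regional ranking (cross-timepoint average test accuracy):")
for entry in report["summary"]["region_ranking"]["entries"]:
    flag = "*" if entry["high_accuracy"] else " "
    per_tp = "  ".join(f"w{w}:{a:.0f}" for w, a in sorted(entry["per_timepoint"].items(),
                                                          key=lambda kv: int(kv[0])))
    print(f" {flag} {entry['dataset']:>12}: {entry['average']:5.1f}%   ({per_tp})")

w20 = report["timepoints"]["20"]
region, segment = w20["prevalence"]["locale_of_greatest_impact"]
print(f"\nweek-20 locale of greatest impact: {region} / {segment}")
red = w20["feature_reduction"]
print(f"week-20 top-50 reduction: {red['full']['n_features']} -> "
      f"{red['top_k']['n_features']} features, "
      f"accuracy {red['full']['accuracy']:.1f}% -> {red['top_k']['accuracy']:.1f}%")
print("\nweek-20 top-5 feature t-tests (raw values, missing/outliers excluded):")
for r in w20["top_feature_stats"]:
    mark = "*" if r["significant"] else " "
    print(f"  {mark} {r['feature']:50s} p={r['p']:.2e}")
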