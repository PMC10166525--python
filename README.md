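# stratecho

Spatial stratification of progressive cardiac dysfunction from
echocardiography feature tables.

In type 2 diabetes, cardiac contractile dysfunction develops regionally
and progressively: some walls of the left ventricle deteriorate before
ejection fraction or fractional shortening move at all. `stratecho`
implements a machine-learning pipeline for locating that dysfunction in
murine cohorts phenotyped by conventional echocardiography (M-mode,
pulse-wave Doppler) and speckle-tracking strain imaging (STE): it ranks
hundreds of deformation features by class relevance, scores anatomical
datasets by their ability to separate diabetic (Db/Db) from wild-type
animals, and reduces both readouts to two spatial summaries — the *most
prevalent* locale (which wall segment/region occupies the largest share of
the top-ranked features) and the *strongest identifier* (which dataset
classifies animals most accurately). A synthetic cohort generator with
implanted, locale-specific effect sizes makes the whole pipeline testable
end to end, with parameter recovery on simulated data as the main
validation surface.

It is aimed at researchers analyzing small-cohort echo feature panels who
want a reproducible, scriptable alternative to spreadsheet-and-toolbox
workflows — and a quantified account of what those workflows'
preprocessing choices do to accuracy estimates.

## The method

Feature tables (27 animals × ~450 features after engineering) flow through:

1. **Engineering** — STE values taken absolute, normalized to LV mass,
   averaged into six region features per deformation channel; outliers
   (Tukey fences, per feature within class) and missing values mean-imputed;
   min-max scaling to [0, 1]; partition into 17 named datasets (Complete,
   PWD, M-mode, Global, Segmental, six segments, six regions).
2. **ReliefF ranking** — for each instance R, the k = 10 nearest same-class
   hits H and other-class misses M update each feature weight

   `W_f ← W_f − Σ_j diff(f,R,H_j)/(m·k) + Σ_C [P(C)/(1−P(cls R))]·Σ_j diff(f,R,M_Cj)/(m·k)`

   with `diff(f,a,b) = |a_f − b_f|/(max_f − min_f)`, weights in [−1, 1].
   Implemented from scratch and verified against an independent exhaustive
   oracle to 1e-10.
3. **SVM evaluation** — 5 iterations of stratified 65/35 holdout
   (⌊0.65·n_class⌋ per class: 9 WT + 8 DB training animals), linear-kernel
   C = 1 SVM, stratified 5-fold cross-validated training accuracy, held-out
   test accuracy and F-score (DB positive), averaged across iterations.
4. **Stratification** — top-50 occupancy per segment; region scores
   normalized by member-segment count and renormalized to 100%; datasets
   ranked by cross-timepoint average accuracy (one decimal, ties away from
   zero) with an 85% high-accuracy flag.
5. **Confirmation statistics** — two-tailed pooled-variance t-tests on the
   top-ranked features, computed on raw values with missing/outlier cells
   excluded.

## Worked example

```python
import stratecho as se

schema = se.build_schema()                  # 257 raw features, 6 segments
spec = se.progressive_preset(seed=1)        # staged diabetic phenotype
raw = se.simulate_cohort(schema, spec, n_wt=14, n_db=13, timepoint_weeks=20)
table, cleaning = se.engineer_table(raw, schema)
parts = {p.name: p for p in se.partition_datasets(table, schema)}

seg = parts["Segmental"]
ranking = se.relieff_weights(seg.table.values, seg.table.class_labels,
                             seg.member_features, k=10)
report = se.prevalence_report(se.select_top_k(ranking, 50), schema, top_k=50)
print(report.segment_counts)
print(report.locale_of_greatest_impact)
```

prints

```
{'AntSeptum': 17, 'AntFree': 2, 'LatWall': 15, 'PostWall': 8, 'InfFreeWall': 1, 'PostSeptal': 7}
('Septal', 'AntSeptum')
```

— of the 50 most class-relevant segmental features, 17 belong to the
anterior septal wall, and after per-segment normalization the Septal
region carries the largest share: the pipeline recovers the AntSeptum-
dominant effects that `progressive_preset` implants at 20 weeks. The
`examples/` directory has one narrative script per capability (simulation,
engineering, ranking, SVM evaluation, spatial readouts, full experiment),
and the `stratecho` command exposes the same steps as shell subcommands
(`simulate`, `engineer`, `rank`, `classify`, `stratify`, `stats`,
`run-all`).

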