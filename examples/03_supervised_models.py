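"""Train the three constitution-type classifiers on a fixed 90/10 split.

LASSO and elastic-net multinomial models are tuned by 10-fold cross
validation along a lambda path (the elastic net over an 11-point alpha grid
as well); the random forest is preceded by Boruta shadow-feature selection
and tuned over ntree/mtry grids by median out-of-bag error.  This example
uses a reduced cohort and reduced forest grids to finish in about a minute.
"""

import phenostrat as ps

spec = ps.default_spec(
    seed=1,
    n_per_class=(40, 30, 30),
    n_features=60,
    n_informative=36,
    n_blocks=8,
)
model = ps.CohortModel(spec)
raw = ps.inject_missing(model.generate_extreme(), spec.missing_rate, seed=spec.seed)
clean, _ = ps.preprocess_pipeline(raw)
train, test = ps.split_train_test(clean, 0.9, seed=1)
print(f"train {train.n_samples} / test {test.n_samples} "
      f"({test.labels.value_counts().to_dict()})")

lasso = ps.fit_lasso(train, seed=1)
print(f"lasso:  lambda*={lasso.lambda_star:.4g}, "
      f"{len(lasso.selected_features)} features, "
      f"hold-out accuracy {ps.evaluate(lasso, test).overall_accuracy:.0%}")

enet = ps.fit_enet(train, seed=1)
print(f"enet:   alpha*={enet.alpha}, lambda*={enet.lambda_star:.4g}, "
      f"{len(enet.selected_features)} features, "
      f"hold-out accuracy {ps.evaluate(enet, test).overall_accuracy:.0%}")

sel = ps.boruta(train, max_runs=30, seed=1, n_trees=200)
print(f"boruta: {len(sel.confirmed)} confirmed, {len(sel.rejected)} rejected, "
      f"{len(sel.tentative)} tentative")
forest = ps.tune_forest(train, sel.confirmed, seed=1,
                        ntree_grid=(250, 500, 1000), n_repeats=3)
rep = ps.evaluate(forest, test)
print(f"forest: ntree*={forest.ntree_star}, mtry*={forest.mtry_star}, "
      f"OOB error {forest.oob_error:.3f}, "
      f"hold-out accuracy {rep.overall_accuracy:.0%}")

core = set(lasso.selected_features) & set(enet.selected_features) \
    & set(forest.selected_features)
print(f"features shared by all three methods: {len(core)}")

# Per-class sensitivity/specificity mirror a confusion-matrix report:
for cls in sorted(rep.sensitivity):
    print(f"  {cls}: sensitivity {rep.sensitivity[cls]:.0%}, "
          f"specificity {rep.specificity[cls]:.0%}")
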