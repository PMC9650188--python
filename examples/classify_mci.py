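"""Small end-to-end classification run: cohort -> 280 features -> LOSO AUC.

Twelve subjects per arm are streamed through the nocturnal pipeline into
the record x 280 feature matrix; random-forest permutation importance
selects the strongest features (top-5 per group, above-median retention); a
gradient boosting classifier is tuned and evaluated by subject-based
leave-one-out with pooled held-out probabilities.  Runs in a few minutes; a
production run would use larger arms and the full hyperparameter grid.
"""

from circawear import model as mdl
from circawear.cohort import generate_cohort
from circawear.pipeline import cohort_feature_matrix

cohort = generate_cohort(n_mci=12, n_control=12, days_per_subject=1,
                         seed=99, preset="separable")
fm = cohort_feature_matrix(cohort, mode="P")
print(f"feature matrix: {fm.X.shape[0]} records x {fm.X.shape[1]} features")

selection = mdl.run_feature_selection(fm, seed=0, n_splits=5, n_repeats=5, n_trees=100)
print(f"retained {len(selection.retained)} features: {selection.retained[:6]} ...")

folds = mdl.loso_folds(fm.subject_ids)
grid = {"n_estimators": [100], "learning_rate": [0.05, 0.1], "max_depth": [2, 3]}
best, _ = mdl.grid_search("gbdt", grid, fm, folds, seed=0, columns=selection.retained)
report = mdl.evaluate("gbdt", best, fm, folds, seed=0, columns=selection.retained)

print(f"best hyperparameters: {best}")
print(
    f"pooled LOSO metrics (%): accuracy {report.accuracy:.1f}, precision "
    f"{report.precision:.1f}, recall {report.recall:.1f}, F1 {report.f1:.1f}, "
    f"AUC {report.auc:.1f}"
)
top = report.importances.sort_values(ascending=False).head(3)
print("top features (importance normalized to 100):")
for name, v in top.items():
    print(f"  {name:>22} {v:6.1f}")
print(
    "\nThe retained features are LF/HF windows — the planted sympathovagal "
    "contrast.\nAUC is near-perfect; the fixed 0.5 threshold trades recall "
    "for precision, since\nthresholded metrics are threshold-dependent."
)
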