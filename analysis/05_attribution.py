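"""Explain the fitted model and propose design-space expansions.

Fits the tuned kernel-ridge model on the complete dataset, computes
factor-level permutation importance and exact Shapley values for every
training design, aggregates the Shapley values per (factor, level), and
derives expansion advice: factors that dominate the landscape and whose
best level already uses the strongest buildable promoter are candidates
for stronger expression or an extra gene copy in the next cycle.
"""

from pathlib import Path

from dbtlopt import io as dio
from dbtlopt.attribution import (
    permutation_importance,
    shapley_values,
    suggest_expansion,
    summarize_shapley,
)
from dbtlopt.benchmarks import BENCHMARK_GRIDS
from dbtlopt.design_space import pal_library
from dbtlopt.models import fit, tune_hyperparameters

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    library = pal_library(reduced=True)
    ds = dio.read_dataset(RESULTS / "dataset_complete.tsv", library)
    spec = tune_hyperparameters(
        "kernel_ridge", ds, library,
        grid=BENCHMARK_GRIDS["kernel_ridge"], seed=SEED,
    )
    fitted = fit(spec, ds, library, seed=SEED)

    imp = permutation_importance(fitted, ds, library, n_repeats=10, seed=SEED)
    dio.write_table(imp.frame, RESULTS / "permutation_importance.tsv")
    print("permutation importance (R^2 drop per shuffled factor):")
    for _, row in imp.frame.sort_values(
        "importance_mean", ascending=False
    ).iterrows():
        print(f"  {row['factor']}: {row['importance_mean']:.3f} "
              f"+/- {row['importance_sd']:.3f}")

    designs = ds.designs
    results = [shapley_values(fitted, d, ds, library) for d in designs]
    summary = summarize_shapley(results)
    dio.write_table(summary, RESULTS / "shapley_summary.tsv")
    top = summary.sort_values("mean_phi", ascending=False).head(3)
    print("most positive mean Shapley values:")
    for _, row in top.iterrows():
        print(f"  {row['factor']} {row['level']}: {row['mean_phi']:+.3f} au")

    report = suggest_expansion(imp, summary, library)
    dio.write_table(report.frame, RESULTS / "expansion_suggestions.tsv")
    (RESULTS / "expansion_suggestions.txt").write_text(report.text + "\n")
    print("expansion advice:")
    print(report.text)


if __name__ == "__main__":
    main()
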