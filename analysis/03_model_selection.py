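"""Compare the four regression families on both datasets.

Repeats the small-data evaluation protocol ten times per dataset:
stratified 90/10 split, LOOCV max-error hyperparameter tuning on the
training rows, test-set R^2.  Also runs the training-size sweep at a 40%
training fraction to contrast the stratified protocol against the
unstratified one.
Reads the datasets written by 02_simulate_screen.py.
"""

from pathlib import Path

from dbtlopt import io as dio
from dbtlopt.benchmarks import BENCHMARK_GRIDS
from dbtlopt.design_space import pal_library
from dbtlopt.models import data_size_sweep, evaluate_families

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    library = pal_library(reduced=True)
    for kind in ("complete", "producers"):
        ds = dio.read_dataset(RESULTS / f"dataset_{kind}.tsv", library)
        report = evaluate_families(
            ds, n_repeats=10, seed=SEED, grids=BENCHMARK_GRIDS
        )
        dio.write_table(report.frame, RESULTS / f"evaluation_{kind}.tsv")
        summary = report.summary()
        dio.write_table(summary, RESULTS / f"evaluation_{kind}_summary.tsv")
        print(f"\n{kind} dataset ({len(ds)} designs), R^2 over 10 repeats:")
        for _, row in summary.iterrows():
            print(f"  {row['family']:>14}: {row['mean_r2']:.2f} "
                  f"+/- {row['sd_r2']:.2f}")

    ds = dio.read_dataset(RESULTS / "dataset_complete.tsv", library)
    sweep = data_size_sweep(
        ds, fractions=(0.4,), stratified_options=(True, False),
        n_repeats=10, seed=SEED, grids=BENCHMARK_GRIDS,
    )
    dio.write_table(sweep, RESULTS / "sweep_fraction40.tsv")
    print("\n40% training fraction (36 designs = 5.4% of the space):")
    g = sweep.groupby(["family", "stratified"])["r2"].mean().unstack()
    for fam, row in g.iterrows():
        print(f"  {fam:>14}: stratified {row[True]:.2f} "
              f"vs unstratified {row[False]:.2f}")


if __name__ == "__main__":
    main()
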