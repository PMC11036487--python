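"""Produce the four design rankings (CO/CR/PO/PR) and evaluate them.

Trains the default model ensemble for each dataset (linear + kernel
ridge on the complete dataset; all four families on the producers
dataset) under both the one-time and the recurrent (100 x 90% resamples)
strategies, ranks all 672 designs by top-1/5/10 nomination frequency,
and reports where the best measured producer (BMP) and the measured
nonproducers land, plus the predicted improvement of the top 10 designs
over the BMP.
"""

from pathlib import Path

from dbtlopt import io as dio
from dbtlopt.benchmarks import BENCHMARK_GRIDS
from dbtlopt.design_space import enumerate_designs, pal_library
from dbtlopt.recommend import (
    evaluate_ranking,
    predicted_improvement,
    rank_designs,
    train_one_time,
    train_recurrent,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    library = pal_library(reduced=True)
    space = enumerate_designs(library)
    for kind in ("complete", "producers"):
        ds = dio.read_dataset(RESULTS / f"dataset_{kind}.tsv", library)
        for strategy in ("one_time", "recurrent"):
            if strategy == "one_time":
                preds = train_one_time(
                    ds, seed=SEED, grids=BENCHMARK_GRIDS, space=space
                )
            else:
                preds = train_recurrent(
                    ds, n_resamples=100, seed=SEED,
                    grids=BENCHMARK_GRIDS, space=space,
                )
            ranking = rank_designs(preds)
            dio.write_ranking(ranking, RESULTS / f"ranking_{ranking.label}.tsv")
            rep = evaluate_ranking(ranking, ds)
            imp = predicted_improvement(ranking, preds, ds)
            dio.write_table(imp, RESULTS / f"improvement_{ranking.label}.tsv")
            print(
                f"{ranking.label}: BMP rank {rep.bmp_rank:>3} of {rep.space_size} "
                f"(in top 10: {rep.bmp_in_top10}); "
                f"nonproducer median rank {rep.nonproducer_median_rank:.0f}; "
                f"top-10 predicted improvement "
                f"{imp['improvement_mean_pct'].mean():.0f} "
                f"+/- {imp['improvement_mean_pct'].std(ddof=0):.0f}%"
            )


if __name__ == "__main__":
    main()
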