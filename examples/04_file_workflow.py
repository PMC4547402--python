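"""File-based workflow: write a cohort to TSV, load it back, evaluate.

The same TSV dialects feed the `driverank` command-line tool
(`driverank rank/evaluate/sweep/simulate`); this script drives the
identical loaders from Python and prints a top-1% evaluation table.
"""

import tempfile
from pathlib import Path

from driverank import (
    GroundTruthSet, SyntheticParams, generate, load_cohort, rank,
    scores_to_ranks, top_percent_report, write_dataset,
)

ds = generate(SyntheticParams(
    n_genes=100, n_patients=50, n_samples=25, n_modules=5, n_drivers=10,
    p_driver_mut=0.2, p_passenger_mut=0.04, seed=17,
))

with tempfile.TemporaryDirectory() as tmp:
    paths = write_dataset(ds, Path(tmp) / "cohort")
    print("wrote:", ", ".join(Path(p).name for p in paths.values()))

    cohort = load_cohort(paths["ppi"], paths["expression"], paths["mutations"])
    truth = GroundTruthSet.from_file(paths["truth"])
    print(f"reloaded {len(cohort.universe)} genes after alignment\n")

    print(f"{'model':10s} {'drivers in top 1%':>18s} {'their mean rank':>16s}")
    for model_id in ("RW-MMGCS", "RW-AM", "FREQ"):
        res = rank(cohort, model_id)
        ranking = scores_to_ranks(res.mu, cohort.universe)
        rep = top_percent_report(ranking, truth, percent=1.0, model_id=model_id)
        avg = "-" if rep.average_rank is None else f"{rep.average_rank:.1f}"
        print(f"{model_id:10s} {rep.appearances:14d}/{len(truth.genes)} {avg:>16s}")
    print("\n'drivers in top 1%' counts planted drivers within the first "
          "1% of the ranked list (cutoff rounds up).")
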