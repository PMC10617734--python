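"""Simulate two seasons of knockdown cohorts and write monitor fixtures.

Generates three dsRNAi groups (control yfpi, bmal1i, cry2i) × two
collections per season, with ground-truth labels, and writes
Trikinetics-dialect monitor files plus metadata and tide-table CSVs
under scratch/analysis/<season>/.  Ground truth goes to results/.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from cohorts import RESULTS, SCRATCH, season_configs
from tidecycle.simulate import simulate_cohort, tide_table, write_monitor_fixture


def main(seed: int = 2016) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    for season, base in (("s2016", seed), ("s2022", seed + 100)):
        out_dir = SCRATCH / season
        truths = []
        for i, cfg in enumerate(season_configs(season, base)):
            records, truth = simulate_cohort(cfg)
            write_monitor_fixture(records, out_dir / cfg.collection_id,
                                  tide_tables=tide_table(cfg))
            truths.append(truth)
            print(f"{season}/{cfg.collection_id}: {len(records)} animals "
                  f"({int(truth.rhythmic.sum())} rhythmic by construction)")
        pd.concat(truths).to_csv(RESULTS / f"ground_truth_{season}.csv", index=False)
    print(f"monitor fixtures under {SCRATCH}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 2016)
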