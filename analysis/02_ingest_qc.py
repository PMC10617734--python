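"""Read the monitor fixtures back and apply trimming + inclusion criteria.

Demonstrates the ingest path on the files written by 01: parses each
Trikinetics-dialect file through the cohort metadata, trims leading
zeros and >12-h trailing zero runs, applies the 5-cycle / 400-event /
zero-run inclusion rules, and writes per-season QC reports to results/.
Included, trimmed records are stored as canonical per-animal CSVs under
scratch/analysis/<season>/qc/.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from cohorts import RESULTS, SCRATCH
from tidecycle.io_monitor import CohortMetadata, read_monitor_file, write_record_csv
from tidecycle.pipeline import qc_cohort


def ingest_season(season_dir: Path):
    records = []
    for coll_dir in sorted(p for p in season_dir.iterdir() if p.is_dir() and p.name != "qc"):
        meta = CohortMetadata.from_csv(coll_dir / "cohort_metadata.csv",
                                       coll_dir / "tide_table.csv")
        meta_df = pd.read_csv(coll_dir / "cohort_metadata.csv")
        for mf, grp in meta_df.groupby("monitor_file"):
            cmap = {int(r.channel): str(r.animal_id) for r in grp.itertuples()}
            records += read_monitor_file(coll_dir / mf, cmap, meta)
    return records


def main() -> None:
    for season_dir in sorted(SCRATCH.iterdir()):
        if not season_dir.is_dir():
            continue
        records = ingest_season(season_dir)
        kept, report = qc_cohort(records)
        qc_dir = season_dir / "qc"
        qc_dir.mkdir(exist_ok=True)
        for rec in kept:
            write_record_csv(rec, qc_dir / f"{rec.animal_id}.csv")
        report.to_csv(RESULTS / f"qc_report_{season_dir.name}.csv", index=False)
        excl = report.loc[~report.included, "reasons"].value_counts().to_dict()
        print(f"{season_dir.name}: {len(kept)}/{len(records)} animals pass QC; "
              f"exclusions {excl}")


if __name__ == "__main__":
    main()
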