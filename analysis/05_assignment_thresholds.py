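"""Diagnostic performance at different identification thresholds.

Gates each specimen's held-out PGMPs at no threshold, 0.95 and 0.99 and
tabulates the proportion of consistently assigned specimens per prior
group (discarded specimens count against the rate). Raising the
threshold trades the identified fraction for confidence: the assigned
set can only shrink.

Writes results/tables/consistency_<sex>_<grouping>.csv.
"""

from pathlib import Path

import pandas as pd

from wingmorph import assignment, data_model

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meta = data_model.metadata_frame(
        data_model.read_metadata(ROOT / "data" / "cohort_metadata.csv")
    )
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    for sex in ("male", "female"):
        for grouping in ("morphospecies", "genotypic_cluster"):
            pgmp = pd.read_csv(
                ROOT / "pgmp" / f"pgmp_{sex}_{grouping}.csv"
            ).set_index("specimen_id").dropna()
            labels = meta.loc[pgmp.index, grouping]
            table = assignment.consistency_by_threshold(
                pgmp, labels, per_group=True
            )
            table.to_csv(out / f"consistency_{sex}_{grouping}.csv")
            overall = assignment.consistency_by_threshold(pgmp, labels)
            print(f"\n{sex} / {grouping} (n={len(pgmp)}):")
            print(table.round(3).to_string())
            print("overall:", ", ".join(
                f"{t}={c:.3f}" for t, c in zip(overall["threshold"],
                                               overall["consistency"])))


if __name__ == "__main__":
    main()
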