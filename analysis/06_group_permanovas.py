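"""Do morphospecies and genotypic clusters differ in wing shape?

One-way PERMANOVAs on Euclidean distances between Procrustes
coordinates, run separately by sex, on balanced random subsets (31/19
specimens per species for males/females, 10/3 per cluster) to avoid
unbalanced-design bias, with 10^4 unrestricted permutations. Significant
terms are followed by pairwise PERMANOVA t-tests with FDR correction.

Writes results/tables/group_permanova_<sex>_<grouping>.csv and
results/tables/pairwise_<sex>_<grouping>.csv.
"""

from pathlib import Path

import pandas as pd

from wingmorph import data_model, permanova

SEED = 20151126
ROOT = Path(__file__).resolve().parent.parent / "results"

# balanced replicate counts per stratum (constrained by the smallest group)
LAYOUTS = [
    ("male", "morphospecies", 31),
    ("female", "morphospecies", 19),
    ("male", "genotypic_cluster", 10),
    ("female", "genotypic_cluster", 3),
]


def main() -> None:
    coords = pd.read_csv(ROOT / "data" / "cohort_procrustes.csv").set_index(
        "specimen_id"
    )
    meta = data_model.metadata_frame(
        data_model.read_metadata(ROOT / "data" / "cohort_metadata.csv")
    ).loc[coords.index]
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)

    for i, (sex, grouping, n_rep) in enumerate(LAYOUTS):
        stratum = meta[meta.sex == sex]
        ids = permanova.balanced_subsample(stratum, grouping, n_rep,
                                           seed=SEED + i)
        feats = coords.loc[ids].to_numpy()
        labels = meta.loc[ids, grouping].to_numpy()
        table = permanova.one_way_permanova(feats, labels, n_perm=10_000,
                                            seed=SEED + 10 + i)
        table.to_csv(out / f"group_permanova_{sex}_{grouping}.csv")
        p = table.loc["group", "p_perm"]
        print(f"\n{sex} / {grouping}: {n_rep} per group "
              f"(df {table.loc['group', 'df']}/{table.loc['Residual', 'df']}), "
              f"pseudo-F = {table.loc['group', 'F']:.2f}, p = {p:.4f}")
        if p <= 0.05:
            pw = permanova.pairwise_tests(feats, labels, n_perm=10_000,
                                          seed=SEED + 20 + i)
            pw.to_csv(out / f"pairwise_{sex}_{grouping}.csv", index=False)
            sig = pw[pw.p_fdr <= 0.05]
            print(pw.round(4).to_string(index=False))
            print(f"{len(sig)}/{len(pw)} pairs significant after FDR")


if __name__ == "__main__":
    main()
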