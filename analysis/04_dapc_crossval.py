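"""Cross-validated DAPC and membership probabilities, per sex stratum.

For each sex and each prior grouping (morphospecies, genotypic cluster),
picks the PC retention level by replicated stratified cross-validation
(90% training / 10% held out), then writes the per-specimen held-out
PGMP tables and a summary of chosen retention levels and held-out
success. Also freezes a male morphospecies reference library for later
identification of unknowns.

Writes results/pgmp/pgmp_<sex>_<grouping>.csv,
results/tables/dapc_crossval_summary.csv and
results/library_male_morphospecies.json.
"""

from pathlib import Path

import pandas as pd

from wingmorph import dapc, data_model, procrustes

SEED = 20151126
ROOT = Path(__file__).resolve().parent.parent / "results"
REPLICATES = 200  # per PC-retention level


def main() -> None:
    coords = pd.read_csv(ROOT / "data" / "cohort_procrustes.csv").set_index(
        "specimen_id"
    )
    meta = data_model.metadata_frame(
        data_model.read_metadata(ROOT / "data" / "cohort_metadata.csv")
    ).loc[coords.index]

    (ROOT / "pgmp").mkdir(parents=True, exist_ok=True)
    (ROOT / "tables").mkdir(parents=True, exist_ok=True)
    summary = []
    for sex in ("male", "female"):
        for grouping in ("morphospecies", "genotypic_cluster"):
            ids = meta.index[(meta.sex == sex) & meta[grouping].notna()]
            feats = coords.loc[ids].to_numpy()
            labels = meta.loc[ids, grouping].to_numpy()
            report = dapc.crossval_dapc(
                feats, labels, replicates=REPLICATES, seed=SEED,
                specimen_ids=list(ids),
            )
            report.pgmp.to_csv(ROOT / "pgmp" / f"pgmp_{sex}_{grouping}.csv")
            success = report.mean_success[report.chosen_n_pca]
            summary.append({
                "sex": sex, "grouping": grouping, "n": len(ids),
                "pc_grid": ",".join(map(str, report.pc_grid)),
                "chosen_n_pca": report.chosen_n_pca,
                "heldout_success": round(float(success), 3),
            })
            print(f"{sex} / {grouping}: n={len(ids)}, retained "
                  f"{report.chosen_n_pca} PCs, held-out success {success:.3f}")

    pd.DataFrame(summary).to_csv(ROOT / "tables" / "dapc_crossval_summary.csv",
                                 index=False)

    # frozen male morphospecies library for diagnosing new specimens
    configs = data_model.read_tps(ROOT / "data" / "cohort_landmarks.tps")
    males = meta.index[meta.sex == "male"]
    male_configs = [c for c in configs if c.specimen_id in set(males)]
    aligned = procrustes.gpa(male_configs)
    feats = procrustes.tangent_project(aligned)
    labels = meta.loc[aligned.specimen_ids, "morphospecies"].tolist()
    chosen = next(s["chosen_n_pca"] for s in summary
                  if s["sex"] == "male" and s["grouping"] == "morphospecies")
    model = dapc.fit_dapc(feats, labels, n_pca=chosen)
    lib = data_model.ReferenceLibrary(
        feature_kind="landmarks", grouping="morphospecies", sex="male",
        features=feats, specimen_ids=list(aligned.specimen_ids), labels=labels,
        model=model, consensus=aligned.consensus,
        notes=f"male wing landmarks, {chosen} PCs (cross-validated)",
    )
    data_model.save_library(lib, ROOT / "library_male_morphospecies.json")
    print("reference library written "
          f"({len(labels)} males, {chosen} PCs retained)")


if __name__ == "__main__":
    main()
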