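"""Superimpose the cohort and look at unconstrained ordination.

Runs generalized Procrustes analysis on all 227 wings (left wings
mirrored), writes the Procrustes coordinate matrix used by every later
stage, and reports how much wing-shape variance the first principal
components carry within each sex stratum.

Writes results/data/cohort_procrustes.csv and
results/tables/pca_variance.csv.
"""

from pathlib import Path

import pandas as pd

from wingmorph import dapc, data_model, procrustes

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    configs = data_model.read_tps(ROOT / "data" / "cohort_landmarks.tps")
    meta = data_model.metadata_frame(
        data_model.read_metadata(ROOT / "data" / "cohort_metadata.csv")
    )
    aligned = procrustes.gpa(configs)
    feats = procrustes.tangent_project(aligned)
    print(
        f"GPA: {aligned.n} wings, {aligned.k} landmarks, "
        f"{aligned.iterations_run} iterations, converged={aligned.converged}"
    )

    cols = [f"{ax}{i + 1}" for i in range(aligned.k) for ax in ("x", "y")]
    coords = pd.DataFrame(feats, columns=cols,
                          index=pd.Index(aligned.specimen_ids, name="specimen_id"))
    coords.to_csv(ROOT / "data" / "cohort_procrustes.csv")

    rows = []
    for sex in ("male", "female"):
        ids = meta.index[meta.sex == sex]
        centered, _ = dapc.center_features(coords.loc[ids].to_numpy())
        res = dapc.pca(centered, r=5)
        frac = res.explained_variance_fraction
        rows.append({"sex": sex, "n": len(ids),
                     **{f"PC{i + 1}": round(float(f), 4)
                        for i, f in enumerate(frac)}})
        print(f"{sex}: first two PCs explain "
              f"{frac[0]:.1%} + {frac[1]:.1%} of wing-shape variance (n={len(ids)})")
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "pca_variance.csv", index=False)


if __name__ == "__main__":
    main()
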