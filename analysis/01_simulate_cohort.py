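"""Generate the synthetic study data.

Writes two datasets under results/data/:

* the main cohort — 227 specimens (80 anonae / 97 fasciventris / 50 rosa,
  163 males / 64 females, five genotypic clusters) with wing landmarks
  (TPS), band areas and metadata (CSV);
* the measurement-error experiment — 7 males + 7 females, both wings,
  2 images per wing, 2 scorings per image (112 observations).

Group shape effects are small (RMS 0.01 in unit-size shape space), the
sex effect is four times larger, the wing-side effect is zero and the
imaging/scoring noise an order of magnitude below individual variation.
"""

from pathlib import Path

from wingmorph import data_model, synthetic

SEED = 20151126  # shared by the whole analysis chain
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cohort = synthetic.simulate_dataset(synthetic.SimulationSpec(seed=SEED))
    data_model.write_tps(cohort.landmarks, OUT / "cohort_landmarks.tps")
    data_model.write_areas_csv(cohort.areas, OUT / "cohort_areas.csv")
    data_model.write_metadata_csv(cohort.meta_records(), OUT / "cohort_metadata.csv")
    counts = cohort.meta.groupby(["morphospecies", "sex"]).size()
    print("cohort written:", len(cohort.landmarks), "specimens")
    print(counts.to_string())

    configs, meta = synthetic.simulate_replicate_dataset(seed=SEED + 1)
    data_model.write_tps(configs, OUT / "replicate_landmarks.tps")
    meta.rename_axis("specimen_id").to_csv(OUT / "replicate_metadata.csv")
    print("replicate experiment written:", len(configs), "observations")


if __name__ == "__main__":
    main()
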