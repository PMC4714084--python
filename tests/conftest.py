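import numpy as np
import pytest

from wingmorph import procrustes, synthetic


@pytest.fixture(scope="session")
def separated_dataset():
    """Three well-separated single-sex groups (between-centroid distance
    ≫ within-group spread), aligned; used by DAPC and assignment tests."""
    spec = synthetic.SimulationSpec(
        seed=71,
        groups={"g1": 0.08, "g2": 0.08, "g3": 0.08},
        n_per_group={g: {"male": 20, "female": 0} for g in ("g1", "g2", "g3")},
        sex_effect=0.0,
        landmark_noise=0.008,
    )
    ds = synthetic.simulate_dataset(spec)
    aligned = procrustes.gpa(ds.landmarks)
    features = procrustes.tangent_project(aligned)
    labels = ds.meta.loc[aligned.specimen_ids, "group"].to_numpy()
    return ds, aligned, features, labels


@pytest.fixture(scope="session")
def cohort_dataset():
    """Default study-structured cohort (80/97/50 species, 163 M / 64 F)."""
    return synthetic.simulate_dataset(synthetic.SimulationSpec(seed=42))


def random_configuration(rng, k=8, scale=1.0):
    """A random non-degenerate landmark configuration."""
    return rng.standard_normal((k, 2)) * scale
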