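"""Synthetic wing-morphometric datasets.

The generator emulates the statistical structure the pipeline assumes for
a cryptic-species complex: several groups (morphospecies or genotypic
clusters) whose mean wing shapes differ by *small* smooth displacements, a
sex effect larger than any group effect, a null wing-side effect, and
negligible imaging / re-measurement error. The default cohort mirrors the
study system's imbalance: 80 anonae (cluster A), 97 fasciventris (F1/F2)
and 50 rosa (R1/R2) specimens, 163 males to 64 females, with ~19% of
specimens measured from the (mirrored) left wing.

Shapes are built on a wing-like polygon template of unit centroid size;
group and sex effects are smooth low-frequency displacement fields of a
prescribed root-mean-square magnitude, and individual variation is
isotropic Gaussian landmark noise in shape space. Configurations are
emitted in mm at a realistic centroid size with random rotation and
translation, so the Procrustes stage has real work to do. Wing-band areas
are log-normal (hence strictly positive) with group and sex shifts on the
log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    CLUSTER_TO_SPECIES,
    BandAreaVector,
    LandmarkConfiguration,
    SpecimenMeta,
)
from .procrustes import normalize, reflect

#: Template band areas in mm² (m = 6).
BASE_AREAS = np.array([0.82, 0.54, 0.31, 0.63, 0.42, 0.21])

#: Default per-cluster (male, female) counts matching the study cohort:
#: species 80/97/50 and sexes 163/64 overall, with every species keeping
#: ≥ 31 males and ≥ 19 females and every cluster ≥ 10 males and ≥ 3
#: females — the balanced-subsample sizes the one-way analyses draw.
DEFAULT_COHORT = {
    "A": {"male": 58, "female": 22},
    "F1": {"male": 37, "female": 12},
    "F2": {"male": 37, "female": 11},
    "R1": {"male": 16, "female": 9},
    "R2": {"male": 15, "female": 10},
}


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort. ``seed`` is mandatory.

    All magnitudes are in dimensionless shape units (the landmark space of
    unit-centroid-size configurations) except areas, whose effects act on
    the log scale. Defaults encode the assumed study structure: group
    effects small, sex effect dominant, side effect null, imaging and
    re-measurement noise an order of magnitude below individual variation.
    """

    seed: int
    k: int = 17
    #: group label -> mean-shape displacement RMS from the template
    groups: dict = field(default_factory=lambda: {g: 0.01 for g in DEFAULT_COHORT})
    #: group label -> {'male': n, 'female': n}
    n_per_group: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_COHORT.items()
    })
    sex_effect: float = 0.04
    side_effect: float = 0.0
    image_noise: float = 0.002
    measurement_noise: float = 0.001
    landmark_noise: float = 0.012
    left_wing_fraction: float = 0.193
    mean_centroid_size_mm: float = 4.0
    size_sd_mm: float = 0.25
    area_group_effect: float | None = None  # defaults to the group shape RMS
    area_sex_effect: float | None = None  # defaults to sex_effect
    area_noise: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        mags = [self.sex_effect, self.side_effect, self.image_noise,
                self.measurement_noise, self.landmark_noise, *self.groups.values()]
        if any(m < 0 for m in mags):
            raise ValueError("effect magnitudes must be ≥ 0")
        if set(self.groups) != set(self.n_per_group):
            raise ValueError("groups and n_per_group must list the same labels")
        for g, by_sex in self.n_per_group.items():
            if any(n < 0 for n in by_sex.values()) or sum(by_sex.values()) < 1:
                raise ValueError(f"group {g}: needs ≥ 1 specimen, counts ≥ 0")


@dataclass
class SimulatedDataset:
    landmarks: list  # LandmarkConfiguration
    areas: list  # BandAreaVector
    meta: pd.DataFrame  # indexed by specimen_id: sex, group, morphospecies, ...
    mean_shapes: dict  # group label -> (k, 2) mean shape

    def meta_records(self) -> list:
        """Metadata as validated SpecimenMeta records (cluster labels only)."""
        out = []
        for sid, row in self.meta.iterrows():
            out.append(
                SpecimenMeta(
                    specimen_id=str(sid),
                    sex=row["sex"],
                    morphospecies=row["morphospecies"],
                    genotypic_cluster=row["genotypic_cluster"],
                    side_used=row["side_used"],
                )
            )
        return out


def wing_template(k: int = 17) -> np.ndarray:
    """A wing-like k-point polygon of unit centroid size.

    Points lie on an elongated rounded outline (aspect ≈ 2.6:1, a blunter
    trailing edge) — enough geometry to make rotations and reflections
    non-trivial; no claim of anatomical realism.
    """
    if k < 3:
        raise ValueError("k must be ≥ 3")
    t = 2 * np.pi * np.arange(k) / k
    x = 1.3 * np.cos(t) + 0.15 * np.cos(2 * t)
    y = 0.5 * np.sin(t) + 0.08 * np.sin(3 * t) + 0.05 * np.cos(t)
    coords = np.column_stack([x, y])
    unit, _ = normalize(coords)
    return unit


def _smooth_field(k: int, rms: float, rng: np.random.Generator,
                  n_modes: int = 4) -> np.ndarray:
    """Random smooth displacement field over landmark index, RMS-scaled."""
    if rms == 0:
        return np.zeros((k, 2))
    t = 2 * np.pi * np.arange(k) / k
    field_xy = np.zeros((k, 2))
    for axis in range(2):
        coef = rng.standard_normal(2 * n_modes)
        for j in range(1, n_modes + 1):
            field_xy[:, axis] += coef[2 * j - 2] * np.cos(j * t)
            field_xy[:, axis] += coef[2 * j - 1] * np.sin(j * t)
    field_xy -= field_xy.mean(axis=0)  # no net translation
    scale = np.sqrt(np.mean(np.sum(field_xy**2, axis=1)))
    return field_xy * (rms / scale) if scale > 0 else field_xy


def make_mean_shapes(
    k: int, n_groups: int, separation: float, seed: int
) -> np.ndarray:
    """Group mean shapes: template + smooth per-group displacements.

    Displacement fields have RMS magnitude ``separation``; all means are
    re-normalized to unit centroid size. Deterministic given ``seed``.
    """
    if separation < 0:
        raise ValueError("separation must be ≥ 0")
    rng = np.random.default_rng(seed)
    template = wing_template(k)
    means = np.empty((n_groups, k, 2))
    for g in range(n_groups):
        disp = _smooth_field(k, separation, rng)
        shifted = template + disp
        means[g], _ = normalize(shifted)
    return means


def _emit_config(
    shape: np.ndarray, side: str, rng: np.random.Generator,
    size_mm: float, specimen_id: str,
) -> LandmarkConfiguration:
    """Place a unit shape into mm coordinates: scale, rotate, translate,
    and mirror if it is a left wing."""
    angle = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    coords = shape @ rot.T * size_mm + rng.uniform(-5, 5, size=2)
    if side == "left":
        coords = reflect(coords)
    return LandmarkConfiguration(specimen_id, coords, side=side)


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate one cohort of wing landmarks, band areas and metadata.

    Specimen shape = group mean + sex displacement + isotropic landmark
    noise. Group labels that are genotypic clusters (A, F1, F2, R1, R2)
    are linked to their morphospecies in the metadata; other labels leave
    the taxonomic columns empty. Bit-identical given the same spec.
    """
    rng = np.random.default_rng(spec.seed)
    labels = sorted(spec.groups)
    template = wing_template(spec.k)
    mean_shapes = {}
    for g in labels:
        disp = _smooth_field(spec.k, spec.groups[g], rng)
        mean_shapes[g], _ = normalize(template + disp)
    sex_disp = _smooth_field(spec.k, spec.sex_effect, rng)
    side_disp = _smooth_field(spec.k, spec.side_effect, rng)

    area_group_rms = (
        spec.area_group_effect
        if spec.area_group_effect is not None
        else float(np.mean(list(spec.groups.values())))
    )
    area_sex_rms = (
        spec.area_sex_effect if spec.area_sex_effect is not None else spec.sex_effect
    )
    m = BASE_AREAS.shape[0]
    area_group_shift = {g: rng.standard_normal(m) * area_group_rms for g in labels}
    area_sex_shift = rng.standard_normal(m) * area_sex_rms

    landmarks, areas, meta_rows = [], [], []
    for g in labels:
        species = CLUSTER_TO_SPECIES.get(g)
        for sex in ("male", "female"):
            n = spec.n_per_group[g].get(sex, 0)
            for i in range(n):
                sid = f"{g}_{sex[0]}{i + 1:03d}"
                shape = mean_shapes[g] + spec.landmark_noise * rng.standard_normal(
                    (spec.k, 2)
                )
                if sex == "male":
                    shape = shape + sex_disp
                side = "left" if rng.random() < spec.left_wing_fraction else "right"
                if side == "left":
                    shape = shape + side_disp
                shape = shape + spec.image_noise * rng.standard_normal((spec.k, 2))
                shape = shape + spec.measurement_noise * rng.standard_normal(
                    (spec.k, 2)
                )
                size = max(0.5, rng.normal(spec.mean_centroid_size_mm, spec.size_sd_mm))
                landmarks.append(_emit_config(shape, side, rng, size, sid))
                log_area = (
                    np.log(BASE_AREAS)
                    + area_group_shift[g]
                    + (area_sex_shift if sex == "male" else 0.0)
                    + spec.area_noise * rng.standard_normal(m)
                )
                areas.append(BandAreaVector(sid, np.exp(log_area)))
                meta_rows.append(
                    {
                        "specimen_id": sid,
                        "sex": sex,
                        "group": g,
                        "morphospecies": species,
                        "genotypic_cluster": g if species is not None else None,
                        "side_used": side,
                    }
                )
    meta = pd.DataFrame(meta_rows).set_index("specimen_id")
    return SimulatedDataset(landmarks, areas, meta, mean_shapes)


def simulate_replicate_dataset(
    seed: int,
    n_per_sex: int = 7,
    n_images: int = 2,
    n_measures: int = 2,
    sex_effect: float = 0.04,
    side_effect: float = 0.0,
    image_noise: float = 0.002,
    measurement_noise: float = 0.001,
    landmark_noise: float = 0.012,
    k: int = 17,
) -> tuple[list, pd.DataFrame]:
    """Replicated measurement-error experiment.

    Each of ``2·n_per_sex`` specimens is measured on both wings, each wing
    photographed ``n_images`` times and each image scored ``n_measures``
    times: a sex × wing × image(wing) × measure(image×wing) design with
    specimens as replicates (112 observations at the defaults). Returns
    the landmark configurations (one per observation) and a metadata
    DataFrame with columns sex, wing, image, measure, specimen.
    """
    rng = np.random.default_rng(seed)
    template = wing_template(k)
    sex_disp = _smooth_field(k, sex_effect, rng)
    side_disp = _smooth_field(k, side_effect, rng)

    configs, rows = [], []
    for sex in ("male", "female"):
        for i in range(n_per_sex):
            spec_id = f"{sex[0]}{i + 1:02d}"
            indiv = template + landmark_noise * rng.standard_normal((k, 2))
            if sex == "male":
                indiv = indiv + sex_disp
            for wing in ("right", "left"):
                wing_shape = indiv + (side_disp if wing == "left" else 0.0)
                for img in range(1, n_images + 1):
                    img_shape = wing_shape + image_noise * rng.standard_normal((k, 2))
                    for meas in range(1, n_measures + 1):
                        obs = img_shape + measurement_noise * rng.standard_normal(
                            (k, 2)
                        )
                        size = max(0.5, rng.normal(4.0, 0.25))
                        oid = f"{spec_id}_{wing[0]}_i{img}_m{meas}"
                        configs.append(_emit_config(obs, wing, rng, size, oid))
                        rows.append(
                            {
                                "obs_id": oid,
                                "specimen": spec_id,
                                "sex": sex,
                                "wing": wing,
                                "image": str(img),
                                "measure": "AB"[meas - 1],
                            }
                        )
    meta = pd.DataFrame(rows).set_index("obs_id")
    return configs, meta
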