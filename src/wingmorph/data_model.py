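"""Domain types and file I/O for wing-morphometric datasets.

Three kinds of records circulate through the pipeline:

* :class:`LandmarkConfiguration` — one wing's ``k`` 2-D landmarks in mm;
* :class:`BandAreaVector` — the wing-band areas of one wing in mm²;
* :class:`SpecimenMeta` — sex, morphospecies, genotypic cluster and which
  wing side was measured.

Landmark data are read and written in TPS (the geometric-morphometrics
interchange format: ``LM=``, coordinate lines, ``IMAGE=``, ``ID=``,
``SCALE=``) and in a flat CSV layout (``x1,y1,…,xk,yk``). The
:class:`ReferenceLibrary` bundles an aligned feature matrix, metadata and
fitted DAPC models and serializes to JSON so that unknown specimens can be
diagnosed later against a frozen library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEXES = ("male", "female")
MORPHOSPECIES = ("anonae", "fasciventris", "rosa")
GENOTYPIC_CLUSTERS = ("A", "F1", "F2", "R1", "R2")
SIDES = ("left", "right")

#: Genotypic cluster -> compatible morphospecies.
CLUSTER_TO_SPECIES: Mapping[str, str] = {
    "A": "anonae",
    "F1": "fasciventris",
    "F2": "fasciventris",
    "R1": "rosa",
    "R2": "rosa",
}

LIBRARY_SCHEMA_VERSION = 1


class DataValidationError(ValueError):
    """A record violates a structural or domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed in the named dialect."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One wing's landmark configuration.

    Parameters
    ----------
    specimen_id : str
        Unique specimen identifier.
    coords : ndarray of shape (k, 2)
        Landmark coordinates in mm, y increasing upward.
    side : {'left', 'right'}
        Which wing the landmarks were digitized from.
    """

    specimen_id: str
    coords: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise DataValidationError(
                f"{self.specimen_id}: coords must be (k, 2), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise DataValidationError(
                f"{self.specimen_id}: non-finite landmark coordinates"
            )
        if self.side not in SIDES:
            raise DataValidationError(
                f"{self.specimen_id}: side must be one of {SIDES}, got {self.side!r}"
            )
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        """Number of landmarks."""
        return self.coords.shape[0]


@dataclass(frozen=True)
class BandAreaVector:
    """Ordered wing-band areas (mm²) of one wing; all strictly positive."""

    specimen_id: str
    areas: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if areas.ndim != 1:
            raise DataValidationError(
                f"{self.specimen_id}: areas must be a flat vector"
            )
        if not np.all(np.isfinite(areas)) or np.any(areas <= 0):
            raise DataValidationError(
                f"{self.specimen_id}: areas must be finite and strictly positive"
            )
        object.__setattr__(self, "areas", areas)

    @property
    def m(self) -> int:
        return self.areas.shape[0]


@dataclass(frozen=True)
class SpecimenMeta:
    """Specimen-level metadata.

    ``morphospecies`` and ``genotypic_cluster`` may be ``None`` (unknown,
    e.g. for query specimens awaiting diagnosis); when both are present
    they must be compatible (A↔anonae, F1/F2↔fasciventris, R1/R2↔rosa).
    """

    specimen_id: str
    sex: str
    morphospecies: str | None = None
    genotypic_cluster: str | None = None
    side_used: str = "right"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataValidationError(
                f"{self.specimen_id}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.morphospecies is not None and self.morphospecies not in MORPHOSPECIES:
            raise DataValidationError(
                f"{self.specimen_id}: unknown morphospecies {self.morphospecies!r}"
            )
        if (
            self.genotypic_cluster is not None
            and self.genotypic_cluster not in GENOTYPIC_CLUSTERS
        ):
            raise DataValidationError(
                f"{self.specimen_id}: unknown genotypic cluster "
                f"{self.genotypic_cluster!r}"
            )
        if self.genotypic_cluster is not None and self.morphospecies is not None:
            expected = CLUSTER_TO_SPECIES[self.genotypic_cluster]
            if self.morphospecies != expected:
                raise DataValidationError(
                    f"{self.specimen_id}: cluster {self.genotypic_cluster} implies "
                    f"morphospecies {expected}, got {self.morphospecies}"
                )
        if self.side_used not in SIDES:
            raise DataValidationError(
                f"{self.specimen_id}: side_used must be one of {SIDES}"
            )


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------


def read_tps(path) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a TPS file.

    Supports ``LM=``, ``IMAGE=``, ``ID=`` and ``SCALE=`` records. When a
    SCALE record is present the raw coordinates are multiplied by it to
    yield mm. An empty file yields an empty list. All records must share
    the same landmark count ``k``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()

    configs: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ParseError(f"line {i + 1}: expected LM= record, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: malformed LM= record {line!r}") from exc
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= n_lines:
                raise ParseError(f"line {i + 1}: unexpected end of file in record")
            parts = lines[i].split()
            if len(parts) != 2:
                raise ParseError(
                    f"line {i + 1}: malformed coordinate line {lines[i].rstrip()!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise ParseError(
                    f"line {i + 1}: malformed coordinate line {lines[i].rstrip()!r}"
                ) from exc
            i += 1
        specimen_id = None
        image = None
        scale = None
        side = "right"
        while i < n_lines:
            tail = lines[i].strip()
            if not tail or tail.upper().startswith("LM="):
                break
            key, _, value = tail.partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "ID":
                specimen_id = value
            elif key == "IMAGE":
                image = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise ParseError(f"line {i + 1}: malformed SCALE= record") from exc
            elif key == "SIDE":  # package extension, written by write_tps
                side = value.lower()
            i += 1
        if specimen_id is None:
            specimen_id = image if image is not None else f"record_{len(configs) + 1}"
        if scale is not None:
            coords = coords * scale
        configs.append(LandmarkConfiguration(specimen_id, coords, side=side))

    ks = {c.k for c in configs}
    if len(ks) > 1:
        offender = next(c for c in configs if c.k != configs[0].k)
        raise DataValidationError(
            f"inconsistent landmark count: specimen {offender.specimen_id} has "
            f"k={offender.k}, expected k={configs[0].k}"
        )
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], path) -> None:
    """Write configurations to TPS. Coordinates are written in mm (SCALE=1)."""
    with open(path, "w", encoding="utf-8") as fh:
        for idx, cfg in enumerate(configs, start=1):
            fh.write(f"LM={cfg.k}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.12g} {y:.12g}\n")
            fh.write(f"ID={cfg.specimen_id}\n")
            fh.write(f"SIDE={cfg.side}\n")
            fh.write("SCALE=1.0\n")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_landmarks(path, format: str = "tps") -> list[LandmarkConfiguration]:
    """Read landmark configurations from ``path`` in ``format`` ('tps'|'csv').

    The CSV dialect has one row per specimen with columns
    ``specimen_id, side, x1, y1, …, xk, yk``.
    """
    if format == "tps":
        return read_tps(path)
    if format != "csv":
        raise ValueError(f"unknown landmark format {format!r}")

    df = pd.read_csv(path)
    if df.empty and len(df.columns) == 0:
        return []
    if "specimen_id" not in df.columns:
        raise ParseError("landmark CSV must have a specimen_id column")
    xcols = sorted(
        (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    ycols = [f"y{c[1:]}" for c in xcols]
    missing = [c for c in ycols if c not in df.columns]
    if missing or not xcols:
        raise ParseError(f"landmark CSV missing coordinate columns: {missing or 'x*'}")
    configs = []
    for _, row in df.iterrows():
        coords = np.column_stack(
            [row[xcols].to_numpy(dtype=float), row[ycols].to_numpy(dtype=float)]
        )
        if not np.all(np.isfinite(coords)):
            raise DataValidationError(
                f"{row['specimen_id']}: missing or non-finite landmark; records "
                "with absent points are rejected"
            )
        configs.append(
            LandmarkConfiguration(
                str(row["specimen_id"]), coords, side=row.get("side", "right")
            )
        )
    return configs


def write_landmarks_csv(configs: Sequence[LandmarkConfiguration], path) -> None:
    if not configs:
        pd.DataFrame().to_csv(path, index=False)
        return
    k = configs[0].k
    cols: dict[str, list] = {"specimen_id": [], "side": []}
    for j in range(1, k + 1):
        cols[f"x{j}"] = []
        cols[f"y{j}"] = []
    for cfg in configs:
        cols["specimen_id"].append(cfg.specimen_id)
        cols["side"].append(cfg.side)
        for j in range(k):
            cols[f"x{j + 1}"].append(cfg.coords[j, 0])
            cols[f"y{j + 1}"].append(cfg.coords[j, 1])
    pd.DataFrame(cols).to_csv(path, index=False)


def read_areas(path) -> list[BandAreaVector]:
    """Read band-area vectors from CSV (columns ``specimen_id, a1..am``)."""
    df = pd.read_csv(path)
    if df.empty and len(df.columns) == 0:
        return []
    acols = sorted(
        (c for c in df.columns if c.startswith("a") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if "specimen_id" not in df.columns or not acols:
        raise ParseError("area CSV must have specimen_id and a1..am columns")
    return [
        BandAreaVector(str(row["specimen_id"]), row[acols].to_numpy(dtype=float))
        for _, row in df.iterrows()
    ]


def write_areas_csv(vectors: Sequence[BandAreaVector], path) -> None:
    if not vectors:
        pd.DataFrame().to_csv(path, index=False)
        return
    m = vectors[0].m
    data = {"specimen_id": [v.specimen_id for v in vectors]}
    for j in range(m):
        data[f"a{j + 1}"] = [v.areas[j] for v in vectors]
    pd.DataFrame(data).to_csv(path, index=False)


def read_metadata(path) -> list[SpecimenMeta]:
    """Read and validate specimen metadata from CSV.

    Required columns: ``specimen_id, sex``; optional:
    ``morphospecies, genotypic_cluster, side_used``. Duplicate ids and
    cluster/species mismatches raise :class:`DataValidationError`.
    """
    df = pd.read_csv(path)
    required = {"specimen_id", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"metadata CSV missing required columns: {sorted(missing)}")
    ids = df["specimen_id"].astype(str)
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise DataValidationError(f"duplicate specimen_id values: {dupes}")

    def _opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        if pd.isna(v) or v == "" or str(v).lower() == "unknown":
            return None
        return str(v)

    records = []
    for _, row in df.iterrows():
        records.append(
            SpecimenMeta(
                specimen_id=str(row["specimen_id"]),
                sex=str(row["sex"]),
                morphospecies=_opt(row, "morphospecies"),
                genotypic_cluster=_opt(row, "genotypic_cluster"),
                side_used=_opt(row, "side_used") or "right",
            )
        )
    return records


def write_metadata_csv(records: Sequence[SpecimenMeta], path) -> None:
    pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "sex": [r.sex for r in records],
            "morphospecies": [r.morphospecies or "" for r in records],
            "genotypic_cluster": [r.genotypic_cluster or "" for r in records],
            "side_used": [r.side_used for r in records],
        }
    ).to_csv(path, index=False)


def metadata_frame(records: Sequence[SpecimenMeta]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by specimen_id."""
    return pd.DataFrame(
        {
            "sex": [r.sex for r in records],
            "morphospecies": [r.morphospecies for r in records],
            "genotypic_cluster": [r.genotypic_cluster for r in records],
            "side_used": [r.side_used for r in records],
        },
        index=pd.Index([r.specimen_id for r in records], name="specimen_id"),
    )


# ---------------------------------------------------------------------------
# Reference library
# ---------------------------------------------------------------------------


@dataclass
class ReferenceLibrary:
    """A frozen diagnostic library.

    Holds the feature matrix the model was trained on, its specimen
    metadata, the fitted DAPC model, and — for landmark libraries — the
    consensus configuration queries are aligned to.

    Attributes
    ----------
    feature_kind : {'landmarks', 'areas'}
    grouping : {'morphospecies', 'genotypic_cluster'}
    sex : {'male', 'female'}
        Libraries are sex-stratified; queries must declare a matching sex.
    consensus : ndarray (k, 2) or None
        GPA consensus (landmark libraries only).
    """

    feature_kind: str
    grouping: str
    sex: str
    features: np.ndarray
    specimen_ids: list[str]
    labels: list[str]
    model: "object"  # DapcModel; typed loosely to avoid a circular import
    consensus: np.ndarray | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise DataValidationError("library features must be a 2-D matrix")
        n = self.features.shape[0]
        if n == 0:
            raise DataValidationError("refusing to build an empty reference library")
        if not (len(self.specimen_ids) == len(self.labels) == n):
            raise DataValidationError(
                "features, specimen_ids and labels must have one row per specimen"
            )
        if self.feature_kind not in ("landmarks", "areas"):
            raise DataValidationError(f"unknown feature kind {self.feature_kind!r}")
        if self.sex not in SEXES:
            raise DataValidationError(f"unknown sex stratum {self.sex!r}")
        model_groups = set(getattr(self.model, "groups"))
        if not model_groups <= set(self.labels):
            raise DataValidationError(
                "model group labels are not a subset of library labels"
            )


def save_library(lib: ReferenceLibrary, path) -> None:
    """Serialize a reference library to JSON (full float precision)."""
    from .dapc import DapcModel  # local import: dapc depends on data_model

    if not isinstance(lib.model, DapcModel):
        raise DataValidationError("library model must be a fitted DapcModel")
    payload = {
        "schema_version": LIBRARY_SCHEMA_VERSION,
        "feature_kind": lib.feature_kind,
        "grouping": lib.grouping,
        "sex": lib.sex,
        "features": lib.features.tolist(),
        "specimen_ids": list(lib.specimen_ids),
        "labels": list(lib.labels),
        "model": lib.model.to_dict(),
        "consensus": None if lib.consensus is None else np.asarray(lib.consensus).tolist(),
        "notes": lib.notes,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_library(path) -> ReferenceLibrary:
    """Load a reference library saved by :func:`save_library`."""
    from .dapc import DapcModel

    with open(path, "r", encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"not a valid library file: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ParseError("not a reference-library file (no schema_version)")
    if payload["schema_version"] != LIBRARY_SCHEMA_VERSION:
        raise ParseError(
            f"library schema version {payload['schema_version']} not supported "
            f"(expected {LIBRARY_SCHEMA_VERSION})"
        )
    try:
        return ReferenceLibrary(
            feature_kind=payload["feature_kind"],
            grouping=payload["grouping"],
            sex=payload["sex"],
            features=np.asarray(payload["features"], dtype=float),
            specimen_ids=[str(s) for s in payload["specimen_ids"]],
            labels=[str(s) for s in payload["labels"]],
            model=DapcModel.from_dict(payload["model"]),
            consensus=(
                None
                if payload.get("consensus") is None
                else np.asarray(payload["consensus"], dtype=float)
            ),
            notes=payload.get("notes", ""),
        )
    except KeyError as exc:
        raise ParseError(f"library file missing field {exc}") from exc
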