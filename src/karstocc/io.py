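"""Study data model and delimited-text I/O.

The study design is a three-level nesting: *sites* (caves, springs, wells,
each carrying occurrence covariates — land-use composition or a precomputed
disturbance index, and dominant lithology), *sampling units* within sites
(carrying detection covariates — water volume, water-column velocity,
substrate), and repeat *surveys* of each unit (occasion x method, with a
binary detection record per taxon).

Canonical on-disk representation is UTF-8 CSV with a header row and "."
decimal separator:

* ``sites.csv`` — site_id, feature_kind, lithology, p_open_dev, p_low_dev,
  p_med_dev, p_high_dev, p_pasture, p_crops, p_undisturbed and optionally
  disturbance_index, elevation_range_m, ndvi_mean.  Exactly one of the
  land-use composition and the precomputed index must be supplied per site.
* ``units.csv`` — unit_id, site_id, volume_m3, velocity, substrate.
* ``surveys.csv`` — unit_id, occasion, method, y_cavefish, y_cave_crayfish.
* ``qpcr.csv`` (optional) — plate_id, unit_id, subsample_id, replicate_id,
  taxon, amplified, role.

Validation reports 1-based data-row numbers (the header is row 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataValidationError,
    ReferentialError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Fixed taxon order; matches the row order of the study's summary tables
#: (cave crayfish rows printed before cavefish rows).
TAXA: tuple[str, str] = ("cave_crayfish", "cavefish")

FEATURE_KINDS = ("cave", "spring", "well")
LITHOLOGIES = ("limestone", "dolostone")  # dolostone is the reference level
VELOCITIES = ("flowing", "not_flowing")  # not_flowing is the reference level
SUBSTRATES = ("coarse", "fine")  # coarse is the reference level
METHODS = ("eDNA", "visual")  # eDNA is the reference level
QPCR_ROLES = ("sample", "negative_control", "positive_control", "field_negative")

#: Land-use classes of the disturbance index, and their sites.csv columns.
LAND_USE_CLASSES = (
    "open_space_dev",
    "low_intensity_dev",
    "medium_intensity_dev",
    "high_intensity_dev",
    "pasture_hay",
    "cultivated_crops",
    "undisturbed",
)
_LANDUSE_COLUMNS = {
    "p_open_dev": "open_space_dev",
    "p_low_dev": "low_intensity_dev",
    "p_med_dev": "medium_intensity_dev",
    "p_high_dev": "high_intensity_dev",
    "p_pasture": "pasture_hay",
    "p_crops": "cultivated_crops",
    "p_undisturbed": "undisturbed",
}


@dataclass
class Site:
    """One karst feature with its occurrence covariates.

    Exactly one of ``landuse`` (a proportions mapping over
    :data:`LAND_USE_CLASSES`) and ``disturbance_index`` must be supplied.
    ``elevation_range_m`` and ``ndvi_mean`` feed only the covariate
    screening step, never the occupancy model.
    """

    site_id: str
    feature_kind: str
    lithology: str
    landuse: dict[str, float] | None = None
    disturbance_index: float | None = None
    elevation_range_m: float | None = None
    ndvi_mean: float | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise DataValidationError(
                f"site {self.site_id!r}: unknown feature_kind {self.feature_kind!r}"
            )
        if self.lithology not in LITHOLOGIES:
            raise DataValidationError(
                f"site {self.site_id!r}: unknown lithology {self.lithology!r}"
            )
        if (self.landuse is None) == (self.disturbance_index is None):
            raise DataValidationError(
                f"site {self.site_id!r}: exactly one of land-use composition and "
                "disturbance_index must be supplied"
            )
        if self.disturbance_index is not None and self.disturbance_index < 1.0:
            raise DataValidationError(
                f"site {self.site_id!r}: disturbance_index {self.disturbance_index} < 1.0"
            )
        if self.ndvi_mean is not None and not -1.0 <= self.ndvi_mean <= 1.0:
            raise DataValidationError(
                f"site {self.site_id!r}: ndvi_mean {self.ndvi_mean} outside [-1, 1]"
            )
        if self.elevation_range_m is not None and self.elevation_range_m < 0:
            raise DataValidationError(
                f"site {self.site_id!r}: negative elevation_range_m"
            )


@dataclass
class SamplingUnit:
    """A discrete habitat patch within a site, with detection covariates."""

    unit_id: str
    site_id: str
    volume_m3: float
    velocity: str
    substrate: str

    def __post_init__(self) -> None:
        if not self.volume_m3 > 0:
            raise DataValidationError(
                f"unit {self.unit_id!r}: volume_m3 must be strictly positive "
                "(it is log-transformed)"
            )
        if self.velocity not in VELOCITIES:
            raise DataValidationError(
                f"unit {self.unit_id!r}: unknown velocity {self.velocity!r}"
            )
        if self.substrate not in SUBSTRATES:
            raise DataValidationError(
                f"unit {self.unit_id!r}: unknown substrate {self.substrate!r}"
            )


@dataclass
class SurveyRecord:
    """One survey of one unit: (occasion, method) with per-taxon detections."""

    unit_id: str
    occasion: int
    method: str
    detections: dict[str, int]

    def __post_init__(self) -> None:
        if self.occasion < 1:
            raise DataValidationError(
                f"survey of {self.unit_id!r}: occasion must be >= 1"
            )
        if self.method not in METHODS:
            raise DataValidationError(
                f"survey of {self.unit_id!r}: unknown method {self.method!r}"
            )
        extra = set(self.detections) - set(TAXA)
        if extra:
            raise DataValidationError(
                f"survey of {self.unit_id!r}: unknown taxa {sorted(extra)}"
            )
        for taxon in TAXA:
            y = self.detections.get(taxon)
            if y not in (0, 1):
                raise DataValidationError(
                    f"survey of {self.unit_id!r}: detection for {taxon!r} "
                    f"must be 0 or 1, got {y!r}"
                )


@dataclass
class QpcrWell:
    unit_id: str
    subsample_id: str
    replicate_id: str
    taxon: str
    amplified: bool
    role: str

    def __post_init__(self) -> None:
        if self.role not in QPCR_ROLES:
            raise DataValidationError(f"unknown qPCR well role {self.role!r}")


@dataclass
class QpcrPlate:
    plate_id: str
    wells: list[QpcrWell] = field(default_factory=list)

    @property
    def sample_wells(self) -> list[QpcrWell]:
        return [w for w in self.wells if w.role == "sample"]

    @property
    def negative_controls(self) -> list[QpcrWell]:
        return [w for w in self.wells if w.role == "negative_control"]


@dataclass
class StudyDesign:
    """Validated nested study: sites -> sampling units -> surveys.

    Index conventions: taxon i runs over :data:`TAXA` (length 2), unit j
    over ``units`` in list order (dense), and survey k over the surveys of
    each unit in list order.
    """

    sites: list[Site]
    units: list[SamplingUnit]
    surveys: list[SurveyRecord]
    taxa: tuple[str, str] = TAXA

    def __post_init__(self) -> None:
        self.validate()

    # -- derived indices ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_surveys(self) -> int:
        return len(self.surveys)

    def site_by_id(self) -> dict[str, Site]:
        return {s.site_id: s for s in self.sites}

    def unit_by_id(self) -> dict[str, SamplingUnit]:
        return {u.unit_id: u for u in self.units}

    def surveys_of_unit(self) -> dict[str, list[SurveyRecord]]:
        out: dict[str, list[SurveyRecord]] = {u.unit_id: [] for u in self.units}
        for rec in self.surveys:
            out[rec.unit_id].append(rec)
        return out

    def validate(self) -> None:
        if tuple(self.taxa) != TAXA:
            raise DataValidationError(f"taxa must be {TAXA}, got {tuple(self.taxa)}")
        site_ids = [s.site_id for s in self.sites]
        if len(set(site_ids)) != len(site_ids):
            raise ReferentialError("duplicate site_id in sites")
        unit_ids = [u.unit_id for u in self.units]
        if len(set(unit_ids)) != len(unit_ids):
            raise ReferentialError("duplicate unit_id in units")
        known_sites = set(site_ids)
        for u in self.units:
            if u.site_id not in known_sites:
                raise ReferentialError(
                    f"unit {u.unit_id!r} references unknown site {u.site_id!r}"
                )
        known_units = set(unit_ids)
        seen: set[tuple[str, int, str]] = set()
        for rec in self.surveys:
            if rec.unit_id not in known_units:
                raise ReferentialError(
                    f"survey references unknown unit {rec.unit_id!r}"
                )
            key = (rec.unit_id, rec.occasion, rec.method)
            if key in seen:
                raise ReferentialError(f"duplicate survey key {key}")
            seen.add(key)
        surveyed = {rec.unit_id for rec in self.surveys}
        missing = known_units - surveyed
        if missing:
            raise DataValidationError(
                f"units with no surveys: {sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def _read_csv(path: str | Path, table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} file not found: {path}")
    return pd.read_csv(path)


def _as_float(value, table: str, column: str, row: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise DataValidationError(
            f"{table}.{column}: non-numeric value {value!r}", rows=[row]
        ) from None
    if math.isnan(out):
        raise DataValidationError(f"{table}.{column}: missing value", rows=[row])
    return out


def _check_level(value: str, levels: Sequence[str], table: str, column: str,
                 row: int) -> str:
    value = str(value).strip()
    if value not in levels:
        raise DataValidationError(
            f"{table}.{column}: unknown level {value!r} (expected one of {list(levels)})",
            rows=[row],
        )
    return value


def read_sites(path: str | Path) -> list[Site]:
    df = _read_csv(path, "sites")
    _require_columns(df, ["site_id", "feature_kind", "lithology"], "sites")
    have_landuse_cols = all(c in df.columns for c in _LANDUSE_COLUMNS)
    sites: list[Site] = []
    for pos, rec in enumerate(df.to_dict("records")):
        row = pos + 1
        landuse = None
        if have_landuse_cols and not all(
            pd.isna(rec[c]) for c in _LANDUSE_COLUMNS
        ):
            landuse = {
                cls: _as_float(rec[col], "sites", col, row)
                for col, cls in _LANDUSE_COLUMNS.items()
            }
        dist = rec.get("disturbance_index")
        dist = None if dist is None or pd.isna(dist) else float(dist)
        elev = rec.get("elevation_range_m")
        elev = None if elev is None or pd.isna(elev) else float(elev)
        ndvi = rec.get("ndvi_mean")
        ndvi = None if ndvi is None or pd.isna(ndvi) else float(ndvi)
        try:
            sites.append(
                Site(
                    site_id=str(rec["site_id"]),
                    feature_kind=_check_level(
                        rec["feature_kind"], FEATURE_KINDS, "sites", "feature_kind", row
                    ),
                    lithology=_check_level(
                        rec["lithology"], LITHOLOGIES, "sites", "lithology", row
                    ),
                    landuse=landuse,
                    disturbance_index=dist,
                    elevation_range_m=elev,
                    ndvi_mean=ndvi,
                )
            )
        except DataValidationError as err:
            if not err.rows:
                raise type(err)(str(err), rows=[row]) from None
            raise
    if any(s.elevation_range_m is None for s in sites):
        logger.info("sites: elevation_range_m missing for some sites (screening only)")
    if any(s.ndvi_mean is None for s in sites):
        logger.info("sites: ndvi_mean missing for some sites (screening only)")
    return sites


def read_units(path: str | Path) -> list[SamplingUnit]:
    df = _read_csv(path, "units")
    _require_columns(
        df, ["unit_id", "site_id", "volume_m3", "velocity", "substrate"], "units"
    )
    units: list[SamplingUnit] = []
    for pos, rec in enumerate(df.to_dict("records")):
        row = pos + 1
        vol = _as_float(rec["volume_m3"], "units", "volume_m3", row)
        if not vol > 0:
            raise DataValidationError(
                "units.volume_m3: must be strictly positive (log-transform "
                f"precondition), got {vol}",
                rows=[row],
            )
        units.append(
            SamplingUnit(
                unit_id=str(rec["unit_id"]),
                site_id=str(rec["site_id"]),
                volume_m3=vol,
                velocity=_check_level(rec["velocity"], VELOCITIES, "units", "velocity", row),
                substrate=_check_level(rec["substrate"], SUBSTRATES, "units", "substrate", row),
            )
        )
    return units


def read_surveys(path: str | Path) -> list[SurveyRecord]:
    df = _read_csv(path, "surveys")
    y_cols = [f"y_{taxon}" for taxon in TAXA]
    _require_columns(df, ["unit_id", "occasion", "method", *y_cols], "surveys")
    surveys: list[SurveyRecord] = []
    for pos, rec in enumerate(df.to_dict("records")):
        row = pos + 1
        detections = {}
        for taxon in TAXA:
            y = _as_float(rec[f"y_{taxon}"], "surveys", f"y_{taxon}", row)
            if y not in (0.0, 1.0):
                raise DataValidationError(
                    f"surveys.y_{taxon}: detections must be 0/1, got {y}", rows=[row]
                )
            detections[taxon] = int(y)
        surveys.append(
            SurveyRecord(
                unit_id=str(rec["unit_id"]),
                occasion=int(_as_float(rec["occasion"], "surveys", "occasion", row)),
                method=_check_level(rec["method"], METHODS, "surveys", "method", row),
                detections=detections,
            )
        )
    return surveys


def read_study(
    sites_path: str | Path,
    units_path: str | Path,
    surveys_path: str | Path,
) -> StudyDesign:
    """Read and cross-validate the three study tables.

    Returns a validated :class:`StudyDesign`; logs row counts per table.
    Raises :class:`SchemaError` for missing columns,
    :class:`DataValidationError` (with 1-based row numbers) for bad values,
    and :class:`ReferentialError` for broken references or duplicates.
    """
    sites = read_sites(sites_path)
    units = read_units(units_path)
    surveys = read_surveys(surveys_path)
    study = StudyDesign(sites=sites, units=units, surveys=surveys)
    logger.info(
        "read_study: %d sites, %d units, %d surveys",
        study.n_sites, study.n_units, study.n_surveys,
    )
    return study


def read_qpcr(path: str | Path) -> list[QpcrPlate]:
    """Read a qPCR well table and group wells into plates."""
    df = _read_csv(path, "qpcr")
    _require_columns(
        df,
        ["plate_id", "unit_id", "subsample_id", "replicate_id", "taxon",
         "amplified", "role"],
        "qpcr",
    )
    plates: dict[str, QpcrPlate] = {}
    truthy = {"1", "true", "yes"}
    falsy = {"0", "false", "no"}
    for pos, rec in enumerate(df.to_dict("records")):
        row = pos + 1
        role = _check_level(rec["role"], QPCR_ROLES, "qpcr", "role", row)
        unit_id = rec["unit_id"]
        if role == "sample" and (unit_id is None or pd.isna(unit_id)):
            raise SchemaError(f"qpcr: sample well missing unit_id at row {row}")
        amp_raw = str(rec["amplified"]).strip().lower()
        if amp_raw in truthy:
            amplified = True
        elif amp_raw in falsy:
            amplified = False
        else:
            raise DataValidationError(
                f"qpcr.amplified: expected boolean, got {rec['amplified']!r}", rows=[row]
            )
        plate = plates.setdefault(str(rec["plate_id"]), QpcrPlate(str(rec["plate_id"])))
        plate.wells.append(
            QpcrWell(
                unit_id="" if pd.isna(unit_id) else str(unit_id),
                subsample_id="" if pd.isna(rec["subsample_id"]) else str(rec["subsample_id"]),
                replicate_id="" if pd.isna(rec["replicate_id"]) else str(rec["replicate_id"]),
                taxon=_check_level(rec["taxon"], TAXA, "qpcr", "taxon", row)
                if not pd.isna(rec["taxon"]) else TAXA[0],
                amplified=amplified,
                role=role,
            )
        )
    return list(plates.values())


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def study_to_frames(study: StudyDesign) -> dict[str, pd.DataFrame]:
    """Render a StudyDesign back into its three canonical tables."""
    site_rows = []
    for s in study.sites:
        row: dict[str, object] = {
            "site_id": s.site_id,
            "feature_kind": s.feature_kind,
            "lithology": s.lithology,
        }
        for col, cls in _LANDUSE_COLUMNS.items():
            row[col] = s.landuse.get(cls, 0.0) if s.landuse is not None else np.nan
        row["disturbance_index"] = (
            np.nan if s.disturbance_index is None else s.disturbance_index
        )
        if s.elevation_range_m is not None:
            row["elevation_range_m"] = s.elevation_range_m
        if s.ndvi_mean is not None:
            row["ndvi_mean"] = s.ndvi_mean
        site_rows.append(row)
    unit_rows = [
        {
            "unit_id": u.unit_id,
            "site_id": u.site_id,
            "volume_m3": u.volume_m3,
            "velocity": u.velocity,
            "substrate": u.substrate,
        }
        for u in study.units
    ]
    survey_rows = [
        {
            "unit_id": r.unit_id,
            "occasion": r.occasion,
            "method": r.method,
            **{f"y_{taxon}": r.detections[taxon] for taxon in TAXA},
        }
        for r in study.surveys
    ]
    return {
        "sites": pd.DataFrame(site_rows),
        "units": pd.DataFrame(unit_rows),
        "surveys": pd.DataFrame(survey_rows),
    }


def write_study(study: StudyDesign, directory: str | Path) -> dict[str, Path]:
    """Write sites.csv / units.csv / surveys.csv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in study_to_frames(study).items():
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


SUMMARY_COLUMNS = ("parameter", "mean", "sd", "hdi_low", "hdi_high")


def write_posterior_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write a posterior summary table (one row per parameter).

    Required columns: parameter, mean, sd, hdi_low, hdi_high; extra columns
    (e.g. rhat) are preserved.  Floats round-trip losslessly at double
    precision (pandas writes shortest-repr decimal strings).
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise SchemaError(f"posterior summary: missing column(s) {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(path, index=False)


def read_posterior_summary(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "posterior_summary")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"posterior summary: missing column(s) {missing}")
    return df
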