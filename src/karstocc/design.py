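"""Covariate transforms and design structures for the occupancy model.

Detection linear predictor per (taxon i, unit j, survey k), with dummy
coding relative to the reference levels eDNA / not-flowing / coarse:

    logit p_ijk = a1_i + a2 X1 + a3_i X2 + a4 X1 X2 + a5_i X3 + a6_i X4
                  + a7_i X2 X3 + a8_i X2 X4

where X1 = velocity (flowing=1), X2 = method (visual=1), X3 = substrate
(fine=1), X4 = standardized log water volume.  The velocity main effect
(a2) and the method-by-velocity interaction (a4) are common to both taxa;
every other term is taxon-specific (means parameterization).

Occurrence linear predictor per (taxon i, unit j):

    logit psi_ij = g_i + b1_i X1 + b2_i X2

with X1 = standardized log disturbance index and X2 = lithology
(limestone=1, dolostone reference).  Units within a site share one row.

Continuous covariates (volume, disturbance) are natural-log transformed
for right skew and then standardized to mean 0, sd 1 (n-1 denominator)
over the sampling units; the realized (mean, sd) pairs are stored in a
:class:`TransformSpec` for exact inverse mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disturbance import DEFAULT_COEFFICIENTS, unit_disturbance
from .exceptions import ScreeningError, TransformError
from .io import TAXA, StudyDesign

#: Detection design-matrix columns, in coefficient order a1..a8.
DET_TERMS = (
    "intercept",
    "velocity",
    "method",
    "method_x_velocity",
    "substrate",
    "volume",
    "substrate_x_method",
    "volume_x_method",
)
#: Detection terms pooled across taxa (single coefficient).
SHARED_DET_TERMS = frozenset({"velocity", "method_x_velocity"})
#: Occurrence design-matrix columns.
OCC_TERMS = ("intercept", "disturbance", "lithology")

PEARSON_THRESHOLD = 0.65


@dataclass(frozen=True)
class TransformSpec:
    """Record of the covariate transforms applied at design-build time."""

    log_transformed: frozenset[str] = frozenset({"volume", "disturbance"})
    standardization: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def transform(self, name: str, values) -> np.ndarray:
        """Raw covariate -> model scale (log where specified, then z-score)."""
        x = np.asarray(values, dtype=float)
        if name in self.log_transformed:
            x = np.log(x)
        mean, sd = self.standardization[name]
        return (x - mean) / sd

    def inverse(self, name: str, values) -> np.ndarray:
        """Model scale -> raw covariate (exact inverse of :meth:`transform`)."""
        z = np.asarray(values, dtype=float)
        mean, sd = self.standardization[name]
        x = z * sd + mean
        if name in self.log_transformed:
            x = np.exp(x)
        return x


@dataclass
class DetectionDesign:
    """Per-survey detection design.

    ``matrix`` has one row per survey and columns :data:`DET_TERMS`;
    ``unit_index`` maps each survey row to its dense unit index j;
    ``y`` is the (taxon, survey) detection array.
    """

    matrix: np.ndarray  # (n_surveys, 8)
    unit_index: np.ndarray  # (n_surveys,) int
    y: np.ndarray  # (n_taxa, n_surveys) int8
    n_units: int
    survey_keys: list[tuple[str, int, str]]

    @property
    def n_surveys(self) -> int:
        return self.matrix.shape[0]

    @property
    def any_detection(self) -> np.ndarray:
        """(n_taxa, n_units) bool: unit has >= 1 detection for the taxon."""
        out = np.zeros((self.y.shape[0], self.n_units), dtype=bool)
        for i in range(self.y.shape[0]):
            np.logical_or.at(out[i], self.unit_index, self.y[i].astype(bool))
        return out


@dataclass
class OccurrenceDesign:
    """Per-unit occurrence design; rows repeat across units within a site."""

    matrix: np.ndarray  # (n_units, 3)
    unit_ids: list[str]
    site_ids: list[str]

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]


def _standardize(values: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if not sd > 0:
        raise TransformError(f"covariate {name!r} has zero variance; cannot standardize")
    return (values - mean) / sd, mean, sd


def transform_covariates(
    study: StudyDesign,
    *,
    log_transformed: Sequence[str] = ("volume", "disturbance"),
    coefficients: Mapping[str, float] = DEFAULT_COEFFICIENTS,
    renormalize: bool = False,
) -> tuple[DetectionDesign, OccurrenceDesign, TransformSpec]:
    """Build the detection and occurrence design structures.

    Standardization statistics are computed over the J sampling units
    (site-level covariates repeated per unit), matching the unit-level
    index of the model.  Raises :class:`TransformError` when a continuous
    covariate or lithology has no variation; warns when velocity,
    substrate, or method is constant.
    """
    log_set = frozenset(log_transformed)
    unit_ids = [u.unit_id for u in study.units]
    unit_pos = {uid: j for j, uid in enumerate(unit_ids)}
    site_of = {u.unit_id: u.site_id for u in study.units}
    sites = study.site_by_id()

    # -- unit-level covariates --------------------------------------------
    volume = np.array([u.volume_m3 for u in study.units], dtype=float)
    if np.any(volume <= 0):
        raise TransformError("volume_m3 must be strictly positive")
    vol_work = np.log(volume) if "volume" in log_set else volume
    vol_std, vol_mean, vol_sd = _standardize(vol_work, "volume")

    dist_by_unit = unit_disturbance(study, coefficients, renormalize=renormalize)
    disturbance = np.array([dist_by_unit[uid] for uid in unit_ids], dtype=float)
    if np.any(disturbance < 1.0):
        raise TransformError("disturbance index must be >= 1.0")
    dist_work = np.log(disturbance) if "disturbance" in log_set else disturbance
    dist_std, dist_mean, dist_sd = _standardize(dist_work, "disturbance")

    velocity = np.array([u.velocity == "flowing" for u in study.units], dtype=float)
    substrate = np.array([u.substrate == "fine" for u in study.units], dtype=float)
    lithology = np.array(
        [sites[site_of[uid]].lithology == "limestone" for uid in unit_ids], dtype=float
    )
    if lithology.min() == lithology.max():
        raise TransformError("lithology is constant across sites; dummy has no contrast")
    for name, col in (("velocity", velocity), ("substrate", substrate)):
        if col.min() == col.max():
            warnings.warn(f"detection covariate {name!r} is constant", stacklevel=2)

    spec = TransformSpec(
        log_transformed=log_set,
        standardization={
            "volume": (vol_mean, vol_sd),
            "disturbance": (dist_mean, dist_sd),
        },
    )

    # -- occurrence design -------------------------------------------------
    occ_matrix = np.column_stack([np.ones(len(unit_ids)), dist_std, lithology])
    occ_design = OccurrenceDesign(
        matrix=occ_matrix,
        unit_ids=unit_ids,
        site_ids=[site_of[uid] for uid in unit_ids],
    )

    # -- detection design ----------------------------------------------------
    n_surveys = study.n_surveys
    j_idx = np.array([unit_pos[rec.unit_id] for rec in study.surveys], dtype=np.intp)
    x1 = velocity[j_idx]
    x2 = np.array([rec.method == "visual" for rec in study.surveys], dtype=float)
    if n_surveys and x2.min() == x2.max():
        warnings.warn("only one survey method present", stacklevel=2)
    x3 = substrate[j_idx]
    x4 = vol_std[j_idx]
    det_matrix = np.column_stack(
        [np.ones(n_surveys), x1, x2, x1 * x2, x3, x4, x2 * x3, x2 * x4]
    )
    y = np.array(
        [[rec.detections[taxon] for rec in study.surveys] for taxon in TAXA],
        dtype=np.int8,
    )
    det_design = DetectionDesign(
        matrix=det_matrix,
        unit_index=j_idx,
        y=y,
        n_units=len(unit_ids),
        survey_keys=[(r.unit_id, r.occasion, r.method) for r in study.surveys],
    )
    return det_design, occ_design, spec


def build_detection_terms(design_row: Sequence[float], alpha: Sequence[float]) -> float:
    """Detection linear predictor a1 + a2 X1 + ... + a8 X2 X4 for one row.

    ``design_row`` is the full 8-vector (leading 1 included) ordered as
    :data:`DET_TERMS`; ``alpha`` the matching coefficient 8-vector.
    """
    row = np.asarray(design_row, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if row.shape != (len(DET_TERMS),) or a.shape != (len(DET_TERMS),):
        raise ValueError(f"expected length-{len(DET_TERMS)} row and coefficients")
    return float(row @ a)


@dataclass
class ScreeningReport:
    """Pairwise correlation screen among candidate occurrence covariates."""

    pearson: dict[tuple[str, str], float]
    point_biserial: dict[str, float]
    flagged_pairs: list[tuple[str, str]]
    excluded: list[str]
    threshold: float
    n: int


def screen_covariates(
    site_table: pd.DataFrame,
    *,
    continuous: Sequence[str] = ("disturbance_index", "elevation_range_m", "ndvi_mean"),
    binary: str = "lithology",
    threshold: float = PEARSON_THRESHOLD,
) -> ScreeningReport:
    """Correlation screen used to prune redundant occurrence covariates.

    Computes pairwise Pearson correlations among the continuous candidates
    and the point-biserial correlation between each continuous candidate
    and the binary covariate.  Any continuous pair with |r| > ``threshold``
    is flagged; the non-disturbance member of a flagged pair is listed for
    exclusion.  Requires >= 3 complete rows.
    """
    present = [c for c in continuous if c in site_table.columns]
    cols = present + ([binary] if binary in site_table.columns else [])
    table = site_table[cols].dropna()
    if len(table) < 3:
        raise ScreeningError(
            f"need >= 3 complete rows for screening, have {len(table)}"
        )
    pearson: dict[tuple[str, str], float] = {}
    flagged: list[tuple[str, str]] = []
    for a_pos, a in enumerate(present):
        for b in present[a_pos + 1:]:
            r = float(stats.pearsonr(table[a], table[b]).statistic)
            pearson[(a, b)] = r
            if abs(r) > threshold:
                flagged.append((a, b))
    point_biserial: dict[str, float] = {}
    if binary in table.columns:
        levels = table[binary]
        if levels.dtype == object:
            codes = (levels == "limestone").astype(float)
        else:
            codes = levels.astype(float)
        if codes.min() != codes.max():
            for a in present:
                point_biserial[a] = float(
                    stats.pointbiserialr(codes, table[a]).statistic
                )
    excluded: list[str] = []
    for a, b in flagged:
        drop = b if a == "disturbance_index" else a if b == "disturbance_index" else b
        if drop not in excluded:
            excluded.append(drop)
    return ScreeningReport(
        pearson=pearson,
        point_biserial=point_biserial,
        flagged_pairs=flagged,
        excluded=excluded,
        threshold=threshold,
        n=len(table),
    )
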