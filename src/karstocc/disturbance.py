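"""Human disturbance index from land-use composition.

Each site's 500-m buffer is summarised upstream (GIS) as proportions of
seven land-use classes.  The index is the proportion-weighted sum of fixed
per-class disturbance coefficients, so it is a convex combination of the
coefficients and always lies in [1.00, 8.67] under the defaults: 1.00 is
a fully undisturbed buffer, 8.67 fully high-intensity development.
"""

from __future__ import annotations

import math
from types import MappingProxyType
from typing import Mapping

from .exceptions import CompositionError, DataValidationError, SchemaError
from .io import LAND_USE_CLASSES, StudyDesign

#: Disturbance weight per land-use class.  "undisturbed" absorbs every
#: class not otherwise listed (water, barren, forest, ...); callers must
#: pre-aggregate those into it.
DEFAULT_COEFFICIENTS: Mapping[str, float] = MappingProxyType(
    {
        "open_space_dev": 1.83,
        "low_intensity_dev": 7.31,
        "medium_intensity_dev": 7.31,
        "high_intensity_dev": 8.67,
        "pasture_hay": 2.99,
        "cultivated_crops": 4.54,
        "undisturbed": 1.00,
    }
)

_SUM_TOLERANCE = 1e-6


def _validate_coefficients(coefficients: Mapping[str, float]) -> None:
    unknown = set(coefficients) - set(LAND_USE_CLASSES)
    if unknown:
        raise SchemaError(f"unknown land-use class(es) in coefficients: {sorted(unknown)}")
    missing = set(LAND_USE_CLASSES) - set(coefficients)
    if missing:
        raise SchemaError(f"missing coefficient(s) for: {sorted(missing)}")
    for cls, coef in coefficients.items():
        if not coef >= 1.0:
            raise DataValidationError(
                f"coefficient for {cls!r} must be >= 1.00, got {coef}"
            )


def compute_disturbance_index(
    composition: Mapping[str, float],
    coefficients: Mapping[str, float] = DEFAULT_COEFFICIENTS,
    *,
    renormalize: bool = False,
) -> float:
    """Weighted sum of land-use proportions by disturbance coefficients.

    Parameters
    ----------
    composition
        Mapping from land-use class to its proportion of the site buffer.
        Proportions must lie in [0, 1] and sum to 1 within 1e-6 unless
        ``renormalize`` is set, in which case they are rescaled to sum to 1
        (sums far from 1 usually indicate an upstream GIS error, hence the
        explicit opt-in).
    coefficients
        Per-class weights; defaults to :data:`DEFAULT_COEFFICIENTS`.

    Returns
    -------
    float
        The index, a convex combination of the coefficients; in
        [1.00, 8.67] under the defaults.
    """
    unknown = set(composition) - set(LAND_USE_CLASSES)
    if unknown:
        raise SchemaError(f"unknown land-use class(es): {sorted(unknown)}")
    _validate_coefficients(coefficients)
    props = {cls: float(composition.get(cls, 0.0)) for cls in LAND_USE_CLASSES}
    for cls, p in props.items():
        if not 0.0 <= p <= 1.0 or math.isnan(p):
            raise CompositionError(f"proportion for {cls!r} outside [0, 1]: {p}")
    total = sum(props.values())
    if abs(total - 1.0) > _SUM_TOLERANCE:
        if not renormalize:
            raise CompositionError(
                f"proportions sum to {total:.8f}, not 1 (within {_SUM_TOLERANCE}); "
                "pass renormalize=True to rescale explicitly"
            )
        if total <= 0:
            raise CompositionError("cannot renormalize an all-zero composition")
        props = {cls: p / total for cls, p in props.items()}
    return float(sum(props[cls] * coefficients[cls] for cls in LAND_USE_CLASSES))


def score_sites(
    study: StudyDesign,
    coefficients: Mapping[str, float] = DEFAULT_COEFFICIENTS,
    *,
    renormalize: bool = False,
) -> dict[str, float]:
    """One disturbance index per site.

    Sites carrying a precomputed ``disturbance_index`` pass through
    unchanged; sites carrying a land-use composition are scored with
    :func:`compute_disturbance_index`.  Sampling units nested within a site
    inherit the site's value (see :func:`unit_disturbance`).
    """
    scores: dict[str, float] = {}
    for site in study.sites:
        if site.disturbance_index is not None:
            scores[site.site_id] = float(site.disturbance_index)
        elif site.landuse is not None:
            scores[site.site_id] = compute_disturbance_index(
                site.landuse, coefficients, renormalize=renormalize
            )
        else:  # pragma: no cover - Site.__post_init__ forbids this
            raise DataValidationError(
                f"site {site.site_id!r} has neither land-use composition nor "
                "precomputed disturbance index"
            )
    return scores


def unit_disturbance(
    study: StudyDesign,
    coefficients: Mapping[str, float] = DEFAULT_COEFFICIENTS,
    *,
    renormalize: bool = False,
) -> dict[str, float]:
    """Disturbance index per sampling unit, inherited from its site."""
    site_scores = score_sites(study, coefficients, renormalize=renormalize)
    return {u.unit_id: site_scores[u.site_id] for u in study.units}
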