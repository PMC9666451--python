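"""Aggregation of qPCR pseudoreplicates into survey-level eDNA detections.

Each filtered water sample yields two extraction subsamples, each run in
qPCR triplicate, giving six pseudoreplicates per sampling unit per taxon.
A unit is scored positive for a taxon if *any* clean-plate pseudoreplicate
amplified.  Plates on which any negative plate control amplified are
discarded wholesale before aggregation; their samples become missing (a
discarded run is evidence of nothing, not evidence of absence).  Field
negative controls (filtered distilled water) are reported but do not by
themselves invalidate co-collected samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import SchemaError
from .io import QpcrPlate

logger = logging.getLogger(__name__)


@dataclass
class AggregationReport:
    """Outcome of pseudoreplicate aggregation.

    ``detections`` maps (unit_id, taxon) to 0/1.  A unit/taxon observed
    only on discarded plates has no entry at all — missing, not 0.
    """

    detections: dict[tuple[str, str], int] = field(default_factory=dict)
    discarded_plates: list[str] = field(default_factory=list)
    n_pseudoreplicates: dict[tuple[str, str], int] = field(default_factory=dict)


def aggregate_pseudoreplicates(plates: list[QpcrPlate]) -> AggregationReport:
    """Collapse qPCR wells to binary (unit, taxon) detections.

    Rules, applied in order:

    1. any amplified negative plate control discards the whole plate;
    2. a plate with no sample wells is skipped with a warning;
    3. detection = 1 iff >= 1 surviving sample pseudoreplicate amplified,
       else 0; units seen only on discarded plates stay missing.
    """
    report = AggregationReport()
    for plate in plates:
        if any(w.amplified for w in plate.negative_controls):
            report.discarded_plates.append(plate.plate_id)
            logger.warning(
                "plate %s discarded: negative control amplified", plate.plate_id
            )
            continue
        samples = plate.sample_wells
        if not samples:
            logger.warning("plate %s has no sample wells; skipped", plate.plate_id)
            continue
        for well in samples:
            if not well.unit_id:
                raise SchemaError(
                    f"plate {plate.plate_id}: sample well missing unit_id"
                )
            key = (well.unit_id, well.taxon)
            report.n_pseudoreplicates[key] = report.n_pseudoreplicates.get(key, 0) + 1
            prev = report.detections.get(key, 0)
            report.detections[key] = max(prev, int(well.amplified))
    return report


def check_field_controls(plates: list[QpcrPlate]) -> list[str]:
    """Identifiers of amplified field negative controls.

    An empty list indicates the absence of field-level false positives.
    If no field-control wells exist at all, returns [] with a logged notice.
    """
    field_wells = [w for p in plates for w in p.wells if w.role == "field_negative"]
    if not field_wells:
        logger.info("no field negative-control wells present")
        return []
    failures = []
    for plate in plates:
        for well in plate.wells:
            if well.role == "field_negative" and well.amplified:
                failures.append(
                    f"{plate.plate_id}:{well.subsample_id or well.unit_id}:"
                    f"{well.replicate_id}"
                )
    return failures
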