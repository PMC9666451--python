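import numpy as np
import pytest

from karstocc.design import DetectionDesign, OccurrenceDesign
from karstocc.io import SamplingUnit, Site, StudyDesign, SurveyRecord, TAXA


def build_small_study(detections=None) -> StudyDesign:
    """Two sites / four units / 16 surveys with contrast in every covariate."""
    sites = [
        Site(site_id="S1", feature_kind="cave", lithology="limestone",
             landuse={"undisturbed": 1.0}),
        Site(site_id="S2", feature_kind="spring", lithology="dolostone",
             landuse={"pasture_hay": 0.5, "undisturbed": 0.5}),
    ]
    units = [
        SamplingUnit("U1", "S1", 1.0, "flowing", "coarse"),
        SamplingUnit("U2", "S1", float(np.e), "not_flowing", "fine"),
        SamplingUnit("U3", "S2", float(np.e) ** 2, "flowing", "fine"),
        SamplingUnit("U4", "S2", 10.0, "not_flowing", "coarse"),
    ]
    default_y = {
        ("U1", 1, "visual"): {"cave_crayfish": 1, "cavefish": 0},
        ("U3", 2, "eDNA"): {"cave_crayfish": 0, "cavefish": 1},
    }
    detections = default_y if detections is None else detections
    surveys = []
    for unit in units:
        for occasion in (1, 2):
            for method in ("eDNA", "visual"):
                y = detections.get(
                    (unit.unit_id, occasion, method),
                    {taxon: 0 for taxon in TAXA},
                )
                surveys.append(SurveyRecord(unit.unit_id, occasion, method, dict(y)))
    return StudyDesign(sites=sites, units=units, surveys=surveys)


@pytest.fixture
def small_study() -> StudyDesign:
    return build_small_study()


def intercept_only_designs(y: np.ndarray, n_units: int):
    """Designs whose only active column is the intercept.

    ``y`` is (n_taxa, n_units * k) with surveys blocked by unit.
    """
    n_surveys = y.shape[1]
    k = n_surveys // n_units
    det = DetectionDesign(
        matrix=np.column_stack([np.ones(n_surveys), np.zeros((n_surveys, 7))]),
        unit_index=np.repeat(np.arange(n_units), k),
        y=y.astype(np.int8),
        n_units=n_units,
        survey_keys=[(f"U{j}", s + 1, "eDNA")
                     for j in range(n_units) for s in range(k)],
    )
    occ = OccurrenceDesign(
        matrix=np.column_stack([np.ones(n_units), np.zeros((n_units, 2))]),
        unit_ids=[f"U{j}" for j in range(n_units)],
        site_ids=[f"S{j}" for j in range(n_units)],
    )
    return det, occ
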