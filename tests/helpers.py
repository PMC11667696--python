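"""Shared factories and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np

from stilsort import Cohort, PatientRecord, ROIAnnotation, WSIRecord
from stilsort.config import DEFAULT_RARITY_MAP

RACES = ["White", "Black or African American", "Other", None]
ETHNICITIES = ["Hispanic or Latino", "Not Hispanic or Latino", None]
SEXES = ["F", "M", None]
STAGES = ["I", "II", "III", "IV", None]
PITFALL_LABELS = list(DEFAULT_RARITY_MAP)


def make_patient(pid="P1", site="S", age=65, sex="F", race="White",
                 ethnicity="Not Hispanic or Latino", bc_stage=None, **kw):
    return PatientRecord(patient_id=pid, site_id=site, age=age, sex=sex,
                         race=race, ethnicity=ethnicity, bc_stage=bc_stage, **kw)


def make_wsi(wid="W1", pid="P1"):
    return WSIRecord(wsi_id=wid, patient_id=pid)


def make_roi(rid, wid, density=None, pitfalls=(), evaluable=None):
    if evaluable is None:
        evaluable = density is not None
    return ROIAnnotation(roi_id=rid, wsi_id=wid, evaluable=evaluable,
                         stils_density_pct=density, pitfalls=tuple(pitfalls))


def single_wsi_cohort(densities, patient_kwargs=None, pitfalls_per_roi=None):
    """One patient / one WSI cohort with the given ROI densities (None =
    not evaluable)."""
    patient = make_patient(**(patient_kwargs or {}))
    wsi = make_wsi(pid=patient.patient_id)
    pitfalls_per_roi = pitfalls_per_roi or [()] * len(densities)
    rois = [
        make_roi(f"R{i}", wsi.wsi_id, density=d, pitfalls=p)
        for i, (d, p) in enumerate(zip(densities, pitfalls_per_roi))
    ]
    cohort = Cohort(patients=[patient], wsis=[wsi], rois=rois)
    cohort.validate()
    return cohort


def random_small_cohort(rng: np.random.Generator, max_wsis: int = 8) -> Cohort:
    """Random tie-prone cohort of at most ``max_wsis`` WSIs for oracle
    comparison; densities drawn from a coarse grid so score ties occur."""
    n_wsis = int(rng.integers(1, max_wsis + 1))
    n_patients = int(rng.integers(1, n_wsis + 1))
    patients = [
        PatientRecord(
            patient_id=f"P{i}",
            site_id="S",
            age=int(rng.integers(20, 96)),
            sex=SEXES[rng.integers(len(SEXES))],
            race=RACES[rng.integers(len(RACES))],
            ethnicity=ETHNICITIES[rng.integers(len(ETHNICITIES))],
            bc_stage=STAGES[rng.integers(len(STAGES))],
        )
        for i in range(n_patients)
    ]
    wsis, rois = [], []
    grid = [0.0, 5.0, 20.0, 50.0, 80.0]
    for w in range(n_wsis):
        pid = f"P{int(rng.integers(n_patients))}"
        wid = f"W{w}"
        wsis.append(WSIRecord(wsi_id=wid, patient_id=pid))
        for k in range(int(rng.integers(1, 6))):
            evaluable = rng.random() < 0.8
            density = float(grid[rng.integers(len(grid))]) if evaluable else None
            pitfalls = tuple(
                label for label in PITFALL_LABELS if rng.random() < 0.05
            )
            rois.append(
                ROIAnnotation(
                    roi_id=f"{wid}-R{k}", wsi_id=wid, evaluable=evaluable,
                    stils_density_pct=density, pitfalls=pitfalls,
                )
            )
    cohort = Cohort(patients=patients, wsis=wsis, rois=rois)
    cohort.validate()
    return cohort


def brute_force_order(scored):
    """Selection sort using only pairwise lexicographic comparisons.

    Independent of the implementation's sort: repeatedly extracts the entry
    beating every remaining one under component-by-component comparison with
    ascending wsi_id as the final tie-break.
    """

    def beats(a, b):
        for ca, cb in zip(a[1], b[1]):
            if ca > cb:
                return True
            if ca < cb:
                return False
        return a[0] < b[0]

    remaining = list(scored)
    out = []
    while remaining:
        best = remaining[0]
        for item in remaining[1:]:
            if beats(item, best):
                best = item
        out.append(best)
        remaining.remove(best)
    return out
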