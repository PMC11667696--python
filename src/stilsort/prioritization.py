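"""Hierarchical rank-sort case prioritization and batch assignment.

Each whole-slide image (WSI) receives a four-component score tuple:

1. normalized density count score — bin fractions of its ROIs' sTILs
   densities weighted 2/1/0 for high/medium/low;
2. race & ethnicity score — 2 points for non-White race, 2 for Hispanic or
   Latino ethnicity;
3. stage, age, sex score — up to 2 points each for aggregated stage, age
   band, and non-female sex;
4. pitfall score — occurrences of assessment pitfalls weighted by rarity.

Cases are sorted in descending lexicographic order of that tuple (a later
component only breaks ties in all earlier ones), deduplicated to one WSI per
patient keeping the best-ranked slide, and the top ``batch_size x n_batches``
cases are dealt round-robin into batches: the case at 1-based rank ``r``
joins batch ``((r - 1) mod n_batches) + 1``.

Missing demographic or disease values always contribute 0 points, so absent
metadata never lifts a case above a documented one.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .cohort import Cohort, PatientRecord, ROIAnnotation, WSIRecord
from .config import (
    BIN_LABELS,
    DEFAULT_AGE_BANDS,
    DEFAULT_DENSITY_WEIGHTS,
    DEFAULT_RARITY_MAP,
    DEFAULT_STAGE_POINTS,
    DensityBinning,
    ScoringConfig,
)

__all__ = [
    "ScoreTuple",
    "BatchPlan",
    "BatchingError",
    "assign_density_bin",
    "normalized_density_count_score",
    "race_ethnicity_score",
    "bcs_age_sex_score",
    "pitfall_score",
    "derive_rarity_map",
    "score_wsi",
    "rank_cases",
    "deduplicate_by_patient",
    "create_batches",
    "prioritize",
]

logger = logging.getLogger(__name__)


class ScoreTuple(NamedTuple):
    """The four score components; tuple order is the sort hierarchy."""

    density_score: float
    race_ethnicity_score: int
    bcs_age_sex_score: int
    pitfall_score: int


class BatchingError(ValueError):
    """Raised when the retained case list cannot fill the requested batches."""


@dataclass
class BatchPlan:
    """Ranked, deduplicated case order and its round-robin batch assignment.

    ``ranked_wsis`` holds the post-deduplication order (one WSI per patient)
    as ``(wsi_id, ScoreTuple, rank)`` with 1-based ranks — the ranks batching
    operates on. ``excluded_duplicates`` lists lower-ranked same-patient WSIs
    dropped before batching.
    """

    ranked_wsis: list[tuple[str, ScoreTuple, int]]
    excluded_duplicates: list[str]
    batches: dict[int, list[str]]
    batch_size: int
    n_batches: int

    def selected_wsi_ids(self) -> list[str]:
        """Selected cases in rank order (the top batch_size x n_batches)."""
        return [w for w, _, _ in self.ranked_wsis[: self.batch_size * self.n_batches]]

    def batch_of(self) -> dict[str, int]:
        return {w: b for b, members in self.batches.items() for w in members}


def assign_density_bin(density_pct: float, binning: DensityBinning | None = None) -> str:
    """Discretize a density percentage into low / medium / high."""
    binning = binning if binning is not None else DensityBinning()
    return binning.assign(density_pct)


def normalized_density_count_score(
    rois_of_wsi: Sequence[ROIAnnotation],
    binning: DensityBinning | None = None,
    weights: Mapping[str, float] | None = None,
    denominator: str = "all",
) -> float:
    """Bin-fraction score of one WSI's ROIs: sum of weight(bin) x fraction.

    With the default weights (high 2, medium 1, low 0) the score lies in
    [0, 2] and is maximal when every counted ROI is high-density. Under the
    ``"all"`` denominator every annotated ROI counts (non-evaluable regions
    fall in no bin and contribute 0 to the numerator); ``"evaluable"``
    divides by evaluable ROIs only.
    """
    if not rois_of_wsi:
        raise ValueError("a WSI must have at least one ROI to be scored")
    binning = binning if binning is not None else DensityBinning()
    weights = dict(DEFAULT_DENSITY_WEIGHTS) if weights is None else weights
    evaluable = [r for r in rois_of_wsi if r.evaluable]
    if denominator == "all":
        denom = len(rois_of_wsi)
    elif denominator == "evaluable":
        denom = len(evaluable)
    else:
        raise ValueError(f"bad denominator {denominator!r}")
    if denom == 0:
        logger.warning(
            "WSI %s has no evaluable ROIs; density score set to 0",
            rois_of_wsi[0].wsi_id,
        )
        return 0.0
    counts = Counter(binning.assign(r.stils_density_pct) for r in evaluable)
    return float(sum(weights[b] * c for b, c in counts.items()) / denom)


def race_ethnicity_score(patient: PatientRecord) -> int:
    """2 points for documented non-White race + 2 for Hispanic or Latino.

    Missing race or ethnicity contributes 0 — absence of documentation is
    never treated as membership in the enriched group.
    """
    score = 0
    if patient.race is not None and patient.race != "White":
        score += 2
    if patient.ethnicity == "Hispanic or Latino":
        score += 2
    return score


def bcs_age_sex_score(
    patient: PatientRecord,
    stage_points: Mapping[str, int] | None = None,
    age_bands: Sequence[tuple[int, int | None, int]] | None = None,
    sex_nonfemale_points: int = 2,
) -> int:
    """Stage (2: III/IV, 1: I/II) + age band + non-female sex points."""
    stage_points = DEFAULT_STAGE_POINTS if stage_points is None else stage_points
    age_bands = DEFAULT_AGE_BANDS if age_bands is None else age_bands
    score = 0
    if patient.bc_stage is not None:
        score += stage_points.get(patient.bc_stage, 0)
    if patient.age is not None:
        age = int(patient.age)
        for lo, hi, pts in age_bands:
            if age >= lo and (hi is None or age <= hi):
                score += pts
                break
    if patient.sex is not None and patient.sex != "F":
        score += sex_nonfemale_points
    return score


def pitfall_score(
    rois_of_wsi: Iterable[ROIAnnotation],
    rarity: Mapping[str, int] | None = None,
    policy: str = "strict",
) -> int:
    """Rarity-weighted count of pitfall occurrences across a WSI's ROIs.

    A pitfall appearing on three ROIs counts three times. Labels absent from
    the rarity map raise under the ``"strict"`` policy and score 0 with a
    warning under ``"lenient"``.
    """
    rarity = DEFAULT_RARITY_MAP if rarity is None else rarity
    if policy not in ("strict", "lenient"):
        raise ValueError(f"bad policy {policy!r}")
    total = 0
    for roi in rois_of_wsi:
        for label in roi.pitfalls:
            if label not in rarity:
                if policy == "strict":
                    raise KeyError(f"pitfall label not in rarity map: {label!r}")
                logger.warning("unlisted pitfall %r scored 0 (lenient policy)", label)
                continue
            total += rarity[label]
    return total


def derive_rarity_map(
    cohort: Cohort,
    rare_max_cases: int = 2,
    semirare_max_cases: int = 10,
) -> dict[str, int]:
    """Tier pitfalls by the number of cases (WSIs) they appear in.

    2 points when a label occurs in at most ``rare_max_cases`` WSIs, 1 up to
    ``semirare_max_cases``, else 0.
    """
    case_sets: dict[str, set[str]] = defaultdict(set)
    for roi in cohort.rois:
        for label in roi.pitfalls:
            case_sets[label].add(roi.wsi_id)
    out = {}
    for label, wsis in case_sets.items():
        n = len(wsis)
        out[label] = 2 if n <= rare_max_cases else (1 if n <= semirare_max_cases else 0)
    return out


def score_wsi(
    wsi: WSIRecord,
    cohort: Cohort,
    config: ScoringConfig | None = None,
    _rois: Sequence[ROIAnnotation] | None = None,
    _patient: PatientRecord | None = None,
    _rarity: Mapping[str, int] | None = None,
) -> ScoreTuple:
    """Compute the four-component score tuple for one WSI.

    The leading-underscore parameters accept precomputed indexes so bulk
    ranking avoids rebuilding them per slide.
    """
    config = config if config is not None else ScoringConfig()
    rois = _rois if _rois is not None else cohort.rois_by_wsi().get(wsi.wsi_id, [])
    patient = (
        _patient if _patient is not None else cohort.patients_by_id()[wsi.patient_id]
    )
    rarity = _rarity
    if rarity is None:
        rarity = (
            derive_rarity_map(cohort, config.rare_max_cases, config.semirare_max_cases)
            if config.derive_rarity_from_cohort
            else config.rarity_map
        )
    return ScoreTuple(
        density_score=normalized_density_count_score(
            rois, config.binning, config.density_weights, config.density_denominator
        ),
        race_ethnicity_score=race_ethnicity_score(patient),
        bcs_age_sex_score=bcs_age_sex_score(
            patient, config.stage_points, config.age_bands, config.sex_nonfemale_points
        ),
        pitfall_score=pitfall_score(rois, rarity, config.unlisted_pitfall_policy),
    )


def rank_cases(
    cohort: Cohort, config: ScoringConfig | None = None
) -> list[tuple[str, ScoreTuple]]:
    """Score every WSI and sort descending lexicographically on the tuple.

    Residual ties after all four components are broken by ascending
    ``wsi_id``, making the order a deterministic function of cohort content
    alone (independent of input row order).
    """
    config = config if config is not None else ScoringConfig()
    roi_index = cohort.rois_by_wsi()
    patient_index = cohort.patients_by_id()
    rarity = (
        derive_rarity_map(cohort, config.rare_max_cases, config.semirare_max_cases)
        if config.derive_rarity_from_cohort
        else config.rarity_map
    )
    scored = []
    for wsi in cohort.wsis:
        rois = roi_index.get(wsi.wsi_id, [])
        if not rois:
            raise ValueError(f"WSI {wsi.wsi_id} has no ROIs and cannot be ranked")
        st = score_wsi(
            wsi, cohort, config,
            _rois=rois, _patient=patient_index[wsi.patient_id], _rarity=rarity,
        )
        scored.append((wsi.wsi_id, st))
    return sorted(scored, key=lambda item: (tuple(-c for c in item[1]), item[0]))


def deduplicate_by_patient(
    ranked: Sequence[tuple[str, ScoreTuple]], cohort: Cohort
) -> tuple[list[tuple[str, ScoreTuple]], list[str]]:
    """Keep each patient's best-ranked WSI; exclude the lower-ranked rest.

    Relative order of retained entries is preserved. Returns
    ``(retained, excluded_wsi_ids)``.
    """
    owner = cohort.patient_of_wsi()
    seen: set[str] = set()
    retained: list[tuple[str, ScoreTuple]] = []
    excluded: list[str] = []
    for wsi_id, st in ranked:
        pid = owner[wsi_id]
        if pid in seen:
            excluded.append(wsi_id)
        else:
            seen.add(pid)
            retained.append((wsi_id, st))
    return retained, excluded


def create_batches(
    retained: Sequence[tuple[str, ScoreTuple]],
    batch_size: int = 8,
    n_batches: int = 5,
) -> BatchPlan:
    """Deal the top ``batch_size x n_batches`` cases round-robin into batches.

    The case at 1-based rank ``r`` joins batch ``((r - 1) mod n_batches) + 1``
    (assignment pattern 1, 2, ..., n, 1, 2, ...), so every batch ends with
    exactly ``batch_size`` members drawn evenly from the ranking.
    """
    need = batch_size * n_batches
    if len(retained) < need:
        raise BatchingError(
            f"need {need} cases for {n_batches} batches of {batch_size}, "
            f"have {len(retained)} (shortfall {need - len(retained)})"
        )
    batches: dict[int, list[str]] = {b: [] for b in range(1, n_batches + 1)}
    for r, (wsi_id, _) in enumerate(retained[:need], start=1):
        batches[(r - 1) % n_batches + 1].append(wsi_id)
    return BatchPlan(
        ranked_wsis=[(w, s, r) for r, (w, s) in enumerate(retained, start=1)],
        excluded_duplicates=[],
        batches=batches,
        batch_size=batch_size,
        n_batches=n_batches,
    )


def prioritize(cohort: Cohort, config: ScoringConfig | None = None) -> BatchPlan:
    """Full pipeline: score and rank, deduplicate per patient, batch."""
    config = config if config is not None else ScoringConfig()
    ranked = rank_cases(cohort, config)
    retained, excluded = deduplicate_by_patient(ranked, cohort)
    plan = create_batches(retained, config.batch_size, config.n_batches)
    plan.excluded_duplicates = excluded
    return plan
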