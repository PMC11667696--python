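"""Cohort data model and clinical-metadata harmonization.

The in-memory model mirrors the three tables an annotation study works with:

* patients — demographics and disease attributes (age, sex, race, ethnicity,
  TNM, aggregated breast-cancer stage, tumor size, plus an open ``extra`` map
  for further data-dictionary elements such as Ki-67 or Nottingham grade);
* whole-slide images (WSIs) — one or more digitized slides per patient with
  scanner metadata;
* regions of interest (ROIs) — per-region evaluability, stromal
  tumor-infiltrating lymphocyte (sTILs) density in percent, tumor-associated
  stroma percentage, and zero or more assessment-pitfall labels.

Missing values are represented by a single sentinel (``None`` in memory, an
empty field on disk); every "unknown"-coded raw token normalizes to it during
harmonization, so downstream summaries can treat unknown and missing as one
category.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .staging import StagingError, map_tnm_to_stage

__all__ = [
    "MISSING_TOKENS",
    "STAGES",
    "DEFAULT_DICTIONARY",
    "PatientRecord",
    "WSIRecord",
    "ROIAnnotation",
    "Cohort",
    "CohortValidationError",
    "harmonize_cohort",
    "missingness_table",
    "demographic_summary",
    "age_decade_bin",
]

STAGES = ("I", "II", "III", "IV")

#: raw tokens treated as the missing sentinel (case-insensitive)
MISSING_TOKENS = frozenset(
    {"", "na", "n/a", "nan", "none", "null", "unknown", "unk",
     "missing", "not reported", "not available", "declined"}
)

#: default data dictionary: field -> {type, allowed, aliases}. Alias keys are
#: matched case-insensitively; canonical values keep their listed casing.
DEFAULT_DICTIONARY: dict[str, dict[str, dict[str, Any]]] = {
    "patients": {
        "patient_id": {"type": "str", "required": True},
        "site_id": {"type": "str", "required": True},
        "age": {"type": "int"},
        "sex": {
            "type": "category",
            "allowed": ["F", "M"],
            "aliases": {"female": "F", "male": "M", "f": "F", "m": "M",
                        "woman": "F", "man": "M"},
        },
        "race": {
            "type": "category",
            "allowed": [
                "White",
                "Black or African American",
                "Asian",
                "American Indian or Alaska Native",
                "Native Hawaiian or Other Pacific Islander",
                "Other",
            ],
            "aliases": {
                "w": "White",
                "caucasian": "White",
                "aa": "Black or African American",
                "black": "Black or African American",
                "african american": "Black or African American",
                "pacific islander": "Native Hawaiian or Other Pacific Islander",
                "native american": "American Indian or Alaska Native",
            },
        },
        "ethnicity": {
            "type": "category",
            "allowed": ["Hispanic or Latino", "Not Hispanic or Latino"],
            "aliases": {
                "hispanic": "Hispanic or Latino",
                "latino": "Hispanic or Latino",
                "non-hispanic": "Not Hispanic or Latino",
                "not hispanic": "Not Hispanic or Latino",
                "non hispanic": "Not Hispanic or Latino",
            },
        },
        "tnm_t": {"type": "tnm_t"},
        "tnm_n": {"type": "tnm_n"},
        "tnm_m": {"type": "tnm_m"},
        "bc_stage": {
            "type": "category",
            "allowed": ["I", "II", "III", "IV"],
            "aliases": {
                "1": "I", "2": "II", "3": "III", "4": "IV",
                "ia": "I", "ib": "I", "iia": "II", "iib": "II",
                "iiia": "III", "iiib": "III", "iiic": "III",
                "stage i": "I", "stage ii": "II", "stage iii": "III",
                "stage iv": "IV",
            },
        },
        "tumor_size_cm": {"type": "float", "min": 0.0},
    },
    "wsis": {
        "wsi_id": {"type": "str", "required": True},
        "patient_id": {"type": "str", "required": True},
        "scanner_make_model": {"type": "str"},
        "image_resolution_um_per_px": {"type": "float", "min": 1e-9},
        "objective_magnification": {"type": "float", "min": 1e-9},
        "numerical_aperture": {"type": "float", "min": 1e-9},
    },
    "rois": {
        "roi_id": {"type": "str", "required": True},
        "wsi_id": {"type": "str", "required": True},
        "evaluable": {"type": "bool", "required": True},
        "stils_density_pct": {"type": "float", "min": 0.0, "max": 100.0},
        "tumor_region_type": {"type": "str"},
        "stroma_pct": {"type": "float", "min": 0.0, "max": 100.0},
        "pitfalls": {"type": "pitfalls"},
    },
}


class CohortValidationError(ValueError):
    """Aggregate of every integrity problem found in a cohort."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n  " + "\n  ".join(self.problems)
        )


@dataclass
class PatientRecord:
    """One patient's harmonized demographics and disease attributes."""

    patient_id: str
    site_id: str
    age: int | None = None
    sex: str | None = None
    race: str | None = None
    ethnicity: str | None = None
    tnm: tuple[str | None, str | None, str | None] | None = None
    bc_stage: str | None = None
    tumor_size_cm: float | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise ValueError(f"patient {self.patient_id}: negative age {self.age}")
        if self.bc_stage is not None and self.bc_stage not in STAGES:
            raise ValueError(
                f"patient {self.patient_id}: bc_stage {self.bc_stage!r} not in {STAGES}"
            )
        if self.tumor_size_cm is not None and self.tumor_size_cm < 0:
            raise ValueError(f"patient {self.patient_id}: negative tumor size")


@dataclass
class WSIRecord:
    """One whole-slide image with optional scanner metadata."""

    wsi_id: str
    patient_id: str
    scanner_make_model: str | None = None
    image_resolution_um_per_px: float | None = None
    objective_magnification: float | None = None
    numerical_aperture: float | None = None

    def __post_init__(self) -> None:
        for name in ("image_resolution_um_per_px", "objective_magnification",
                     "numerical_aperture"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"WSI {self.wsi_id}: {name} must be positive, got {v}")


@dataclass
class ROIAnnotation:
    """One region of interest: evaluability, sTILs density, pitfalls.

    A density is carried if and only if the region is evaluable — the
    evaluable/not-evaluable call is the first step of the sTILs assessment
    and non-evaluable tissue has no density by definition.
    """

    roi_id: str
    wsi_id: str
    evaluable: bool
    stils_density_pct: float | None = None
    tumor_region_type: str | None = None
    stroma_pct: float | None = None
    pitfalls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.evaluable and self.stils_density_pct is None:
            raise ValueError(f"ROI {self.roi_id}: evaluable but has no sTILs density")
        if not self.evaluable and self.stils_density_pct is not None:
            raise ValueError(f"ROI {self.roi_id}: not evaluable but carries a density")
        for name in ("stils_density_pct", "stroma_pct"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"ROI {self.roi_id}: {name}={v} outside [0, 100]")


@dataclass
class Cohort:
    """Referentially linked collections of patients, WSIs, and ROIs."""

    patients: list[PatientRecord] = field(default_factory=list)
    wsis: list[WSIRecord] = field(default_factory=list)
    rois: list[ROIAnnotation] = field(default_factory=list)

    def validate(self) -> None:
        problems: list[str] = []
        pids = [p.patient_id for p in self.patients]
        wids = [w.wsi_id for w in self.wsis]
        rids = [r.roi_id for r in self.rois]
        for label, ids in (("patient", pids), ("WSI", wids), ("ROI", rids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            if dups:
                problems.append(f"duplicate {label} identifiers: {sorted(dups)}")
        pid_set, wid_set = set(pids), set(wids)
        bad_w = sorted({w.wsi_id for w in self.wsis if w.patient_id not in pid_set})
        if bad_w:
            problems.append(f"WSIs referencing unknown patients: {bad_w}")
        bad_r = sorted({r.roi_id for r in self.rois if r.wsi_id not in wid_set})
        if bad_r:
            problems.append(f"ROIs referencing unknown WSIs: {bad_r}")
        if problems:
            raise CohortValidationError(problems)

    # -- indexes ---------------------------------------------------------

    def patients_by_id(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def wsis_by_id(self) -> dict[str, WSIRecord]:
        return {w.wsi_id: w for w in self.wsis}

    def rois_by_wsi(self) -> dict[str, list[ROIAnnotation]]:
        index: dict[str, list[ROIAnnotation]] = defaultdict(list)
        for r in self.rois:
            index[r.wsi_id].append(r)
        return dict(index)

    def patient_of_wsi(self) -> dict[str, str]:
        return {w.wsi_id: w.patient_id for w in self.wsis}

    def site_ids(self) -> list[str]:
        return sorted({p.site_id for p in self.patients})


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def clean_token(raw: Any) -> str | None:
    """Strip a raw cell; map every unknown/missing-coded token to None."""
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    s = str(raw).strip()
    if s.lower() in MISSING_TOKENS:
        return None
    return s


_BOOL_TOKENS = {
    "true": True, "false": False, "1": True, "0": False, "yes": True,
    "no": False, "evaluable": True, "not evaluable": False, "t": True, "f": False,
}


def _harmonize_value(raw: Any, spec: Mapping[str, Any], where: str,
                     log: list[str]) -> Any:
    """Map one raw cell to its dictionary term / coerced type / missing."""
    s = clean_token(raw)
    if s is None:
        if raw is not None and str(raw).strip() != "" and not (
            isinstance(raw, float) and math.isnan(raw)
        ):
            log.append(f"{where}: {str(raw).strip()!r} -> <missing>")
        return None
    kind = spec["type"]
    if kind == "str":
        return s
    if kind == "category":
        for canon in spec["allowed"]:
            if s.lower() == canon.lower():
                if s != canon:
                    log.append(f"{where}: {s!r} -> {canon!r}")
                return canon
        alias = spec.get("aliases", {}).get(s.lower())
        if alias is not None:
            log.append(f"{where}: {s!r} -> {alias!r}")
            return alias
        log.append(f"{where}: unmapped value {s!r} -> <missing>")
        return None
    if kind == "int":
        try:
            v = int(math.floor(float(s)))
        except ValueError:
            log.append(f"{where}: uncoercible {s!r} -> <missing>")
            return None
        if float(s) != v:
            log.append(f"{where}: {s!r} -> {v}")
        return v
    if kind == "float":
        try:
            v = float(s)
        except ValueError:
            log.append(f"{where}: uncoercible {s!r} -> <missing>")
            return None
        lo, hi = spec.get("min"), spec.get("max")
        if (lo is not None and v < lo) or (hi is not None and v > hi):
            log.append(f"{where}: out-of-range {v} -> <missing>")
            return None
        return v
    if kind == "bool":
        b = _BOOL_TOKENS.get(s.lower())
        if b is None:
            log.append(f"{where}: uncoercible {s!r} -> <missing>")
            return None
        return b
    if kind in ("tnm_t", "tnm_n", "tnm_m"):
        from . import staging

        fn = {"tnm_t": staging.normalize_t, "tnm_n": staging.normalize_n,
              "tnm_m": staging.normalize_m}[kind]
        try:
            v = fn(s)
        except StagingError:
            log.append(f"{where}: unmapped value {s!r} -> <missing>")
            return None
        if v != s:
            log.append(f"{where}: {s!r} -> {v!r}")
        return v
    if kind == "pitfalls":
        labels = tuple(x.strip() for x in s.split(";") if x.strip())
        return labels
    raise ValueError(f"unknown dictionary type {kind!r} for {where}")


def _row_id(row: Mapping[str, Any], key: str, i: int) -> str:
    v = clean_token(row.get(key))
    return v if v is not None else f"<row {i}>"


def harmonize_cohort(
    raw_patient_table: pd.DataFrame,
    raw_wsi_table: pd.DataFrame,
    raw_roi_table: pd.DataFrame,
    dictionary: Mapping[str, Mapping[str, Mapping[str, Any]]] | None = None,
    log: list[str] | None = None,
) -> Cohort:
    """Harmonize raw tables to the controlled vocabularies and validate.

    Every raw value is either mapped to its dictionary term, coerced to the
    expected type, or set to the missing sentinel; each substitution is
    appended to ``log`` (one line per change). When the aggregated stage is
    missing but TNM categories are present, the stage is derived from the
    anatomic stage-group lookup.

    Raises :class:`CohortValidationError` on duplicate identifiers, dangling
    references, or record-level invariant violations.
    """
    dic = DEFAULT_DICTIONARY if dictionary is None else dictionary
    log = log if log is not None else []
    problems: list[str] = []

    patients: list[PatientRecord] = []
    known_p = set(dic["patients"])
    for i, row in enumerate(raw_patient_table.to_dict(orient="records")):
        rid = _row_id(row, "patient_id", i)
        vals: dict[str, Any] = {}
        for name, spec in dic["patients"].items():
            vals[name] = _harmonize_value(
                row.get(name), spec, f"patients.{name}[{rid}]", log
            )
            if spec.get("required") and vals[name] is None:
                problems.append(f"patients[{rid}]: required field {name!r} missing")
        tnm = (vals.pop("tnm_t", None), vals.pop("tnm_n", None), vals.pop("tnm_m", None))
        if all(c is None for c in tnm):
            tnm = None
        if vals.get("bc_stage") is None and tnm is not None:
            derived = map_tnm_to_stage(*tnm)
            if derived is not None:
                log.append(f"patients.bc_stage[{rid}]: derived {derived!r} from TNM {tnm}")
                vals["bc_stage"] = derived
        extra = {
            k: v for k, v in ((k, clean_token(row[k])) for k in row if k not in known_p)
            if v is not None
        }
        if any(p.startswith(f"patients[{rid}]") for p in problems):
            continue
        try:
            patients.append(PatientRecord(tnm=tnm, extra=extra, **vals))
        except ValueError as e:
            problems.append(str(e))

    wsis: list[WSIRecord] = []
    for i, row in enumerate(raw_wsi_table.to_dict(orient="records")):
        rid = _row_id(row, "wsi_id", i)
        vals = {
            name: _harmonize_value(row.get(name), spec, f"wsis.{name}[{rid}]", log)
            for name, spec in dic["wsis"].items()
        }
        if vals["wsi_id"] is None or vals["patient_id"] is None:
            problems.append(f"wsis[{rid}]: required identifier missing")
            continue
        try:
            wsis.append(WSIRecord(**vals))
        except ValueError as e:
            problems.append(str(e))

    rois: list[ROIAnnotation] = []
    for i, row in enumerate(raw_roi_table.to_dict(orient="records")):
        rid = _row_id(row, "roi_id", i)
        vals = {
            name: _harmonize_value(row.get(name), spec, f"rois.{name}[{rid}]", log)
            for name, spec in dic["rois"].items()
        }
        if vals["roi_id"] is None or vals["wsi_id"] is None or vals["evaluable"] is None:
            problems.append(f"rois[{rid}]: required field missing")
            continue
        if vals.get("pitfalls") is None:
            vals["pitfalls"] = ()
        try:
            rois.append(ROIAnnotation(**vals))
        except ValueError as e:
            problems.append(str(e))

    if problems:
        raise CohortValidationError(problems)
    cohort = Cohort(patients=patients, wsis=wsis, rois=rois)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def _site_subsets(cohort: Cohort) -> list[tuple[str, list[PatientRecord]]]:
    subsets = [("all", cohort.patients)]
    for site in cohort.site_ids():
        subsets.append((site, [p for p in cohort.patients if p.site_id == site]))
    return subsets


def missingness_table(
    cohort: Cohort,
    fields: Iterable[str] = ("age", "sex", "race", "ethnicity", "bc_stage"),
) -> pd.DataFrame:
    """Per-field missingness, overall and per site, at the patient level.

    Returns a tidy frame with columns ``field, site, n_missing, n_patients,
    pct_missing`` (percentage of that site's patients, one decimal). Unknown
    -coded values already count as missing courtesy of harmonization.
    """
    if not cohort.patients:
        raise ValueError("empty cohort")
    fields = list(fields)
    for f in fields:
        if not hasattr(cohort.patients[0], f):
            raise ValueError(f"unknown patient field {f!r}")
    rows = []
    for site, subset in _site_subsets(cohort):
        for f in fields:
            n_missing = sum(1 for p in subset if getattr(p, f) is None)
            rows.append(
                {
                    "field": f,
                    "site": site,
                    "n_missing": n_missing,
                    "n_patients": len(subset),
                    "pct_missing": round(100.0 * n_missing / len(subset), 1),
                }
            )
    return pd.DataFrame(rows)


def demographic_summary(
    cohort: Cohort,
    variables: Iterable[str] = ("sex", "race", "ethnicity"),
) -> pd.DataFrame:
    """Demographic distribution table, overall and per site.

    Age is summarized as mean (SD, sample, ``ddof=1``; SD absent for n=1)
    over non-missing ages; each categorical variable as count and percentage
    on the full patient denominator, with missing shown as its own level.
    Means/SDs are rounded to two decimals and percentages to one, matching
    conventional cohort tables.

    Columns: ``variable, level, site, count, pct, mean, sd``.
    """
    if not cohort.patients:
        raise ValueError("empty cohort")
    rows = []
    for site, subset in _site_subsets(cohort):
        n = len(subset)
        ages = [p.age for p in subset if p.age is not None]
        rows.append(
            {
                "variable": "age",
                "level": "mean_sd",
                "site": site,
                "count": len(ages),
                "pct": None,
                "mean": round(float(np.mean(ages)), 2) if ages else None,
                "sd": round(float(np.std(ages, ddof=1)), 2) if len(ages) > 1 else None,
            }
        )
        for var in variables:
            values = [getattr(p, var) for p in subset]
            levels = sorted({v for v in values if v is not None})
            if any(v is None for v in values):
                levels.append("missing")
            for level in levels:
                count = sum(
                    1 for v in values
                    if (v is None and level == "missing") or v == level
                )
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "site": site,
                        "count": count,
                        "pct": round(100.0 * count / n, 1),
                        "mean": None,
                        "sd": None,
                    }
                )
    return pd.DataFrame(rows)


def age_decade_bin(age: int) -> str:
    """Closed decade bin label for an age in whole years: 1-10, 11-20, ..."""
    if age < 1:
        return "0"
    lo = ((age - 1) // 10) * 10 + 1
    return f"{lo}-{lo + 9}"
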