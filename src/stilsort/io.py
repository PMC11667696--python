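"""Round-trip readers/writers for on-disk artifacts and the run manifest.

A cohort lives in a directory as three UTF-8 comma-separated tables with a
header row: ``patients.csv``, ``wsis.csv``, ``rois.csv``. A missing value is
an empty field — never a literal token like ``NA``, which could collide with
a category label. Numeric fields are bare decimals (no embedded units or
percent signs); the pitfall multiset is a semicolon-joined list in one
field. ``write_cohort`` followed by ``read_cohort`` is the identity on
harmonized cohorts.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

from .cohort import Cohort, PatientRecord, ROIAnnotation, WSIRecord
from .prioritization import BatchPlan

__all__ = [
    "CohortFormatError",
    "PATIENT_COLUMNS",
    "WSI_COLUMNS",
    "ROI_COLUMNS",
    "cohort_to_frames",
    "write_cohort",
    "read_cohort",
    "read_raw_tables",
    "write_batch_plan",
    "RunManifest",
    "write_manifest",
]

PATIENT_COLUMNS = [
    "patient_id", "site_id", "age", "sex", "race", "ethnicity",
    "tnm_t", "tnm_n", "tnm_m", "bc_stage", "tumor_size_cm",
]
WSI_COLUMNS = [
    "wsi_id", "patient_id", "scanner_make_model",
    "image_resolution_um_per_px", "objective_magnification", "numerical_aperture",
]
ROI_COLUMNS = [
    "roi_id", "wsi_id", "evaluable", "stils_density_pct",
    "tumor_region_type", "stroma_pct", "pitfalls",
]

_FLOAT_RE = re.compile(r"^-?\d+(\.\d+)?([eE][+-]?\d+)?$")
_INT_RE = re.compile(r"^-?\d+$")


class CohortFormatError(ValueError):
    """Malformed on-disk cohort table; message carries file, line, column."""


def _fmt(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _patient_row(p: PatientRecord) -> dict[str, str]:
    t, n, m = p.tnm if p.tnm is not None else (None, None, None)
    row = {
        "patient_id": p.patient_id, "site_id": p.site_id, "age": _fmt(p.age),
        "sex": _fmt(p.sex), "race": _fmt(p.race), "ethnicity": _fmt(p.ethnicity),
        "tnm_t": _fmt(t), "tnm_n": _fmt(n), "tnm_m": _fmt(m),
        "bc_stage": _fmt(p.bc_stage), "tumor_size_cm": _fmt(p.tumor_size_cm),
    }
    row.update({k: _fmt(v) for k, v in p.extra.items()})
    return row


def cohort_to_frames(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Render a cohort as the three string-valued tables ("" = missing)."""
    extra_cols = sorted({k for p in cohort.patients for k in p.extra})
    p_cols = PATIENT_COLUMNS + extra_cols
    p_rows = [{c: r.get(c, "") for c in p_cols} for r in map(_patient_row, cohort.patients)]
    w_rows = [
        {c: _fmt(getattr(w, c)) for c in WSI_COLUMNS} for w in cohort.wsis
    ]
    r_rows = [
        {
            "roi_id": r.roi_id, "wsi_id": r.wsi_id, "evaluable": _fmt(r.evaluable),
            "stils_density_pct": _fmt(r.stils_density_pct),
            "tumor_region_type": _fmt(r.tumor_region_type),
            "stroma_pct": _fmt(r.stroma_pct),
            "pitfalls": ";".join(r.pitfalls),
        }
        for r in cohort.rois
    ]
    return {
        "patients": pd.DataFrame(p_rows, columns=p_cols, dtype=str),
        "wsis": pd.DataFrame(w_rows, columns=WSI_COLUMNS, dtype=str),
        "rois": pd.DataFrame(r_rows, columns=ROI_COLUMNS, dtype=str),
    }


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write patients.csv / wsis.csv / rois.csv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = cohort_to_frames(cohort)
    for name, frame in frames.items():
        path = directory / f"{name}.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(frame.columns.tolist())
            for row in frame.itertuples(index=False):
                writer.writerow(list(row))


def _parse_cell(raw: str, kind: str, path: Path, line: int, column: str) -> Any:
    if raw == "":
        return None
    where = f"{path}:{line}:{column}"
    if kind == "str":
        return raw
    if kind == "int":
        if not _INT_RE.match(raw):
            raise CohortFormatError(f"{where}: expected a bare integer, got {raw!r}")
        return int(raw)
    if kind == "float":
        if not _FLOAT_RE.match(raw):
            raise CohortFormatError(f"{where}: expected a bare decimal, got {raw!r}")
        return float(raw)
    if kind == "bool":
        if raw not in ("true", "false"):
            raise CohortFormatError(f"{where}: expected true/false, got {raw!r}")
        return raw == "true"
    if kind == "pitfalls":
        return tuple(x for x in raw.split(";") if x)
    raise ValueError(f"unknown cell kind {kind!r}")


_PATIENT_KINDS = {
    "patient_id": "str", "site_id": "str", "age": "int", "sex": "str",
    "race": "str", "ethnicity": "str", "tnm_t": "str", "tnm_n": "str",
    "tnm_m": "str", "bc_stage": "str", "tumor_size_cm": "float",
}
_WSI_KINDS = {
    "wsi_id": "str", "patient_id": "str", "scanner_make_model": "str",
    "image_resolution_um_per_px": "float", "objective_magnification": "float",
    "numerical_aperture": "float",
}
_ROI_KINDS = {
    "roi_id": "str", "wsi_id": "str", "evaluable": "bool",
    "stils_density_pct": "float", "tumor_region_type": "str",
    "stroma_pct": "float", "pitfalls": "pitfalls",
}


def _read_table(path: Path, required: Iterable[str]) -> tuple[list[str], list[dict[str, str]]]:
    if not path.exists():
        raise CohortFormatError(f"missing table: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise CohortFormatError(f"{path}: missing required header {col!r}")
        rows = []
        for row in reader:
            if None in row:
                raise CohortFormatError(
                    f"{path}:{reader.line_num}: row has more cells than the header"
                )
            rows.append(row)
    return header, rows


def read_cohort(directory: str | Path) -> Cohort:
    """Read the three-table layout strictly and return a validated cohort.

    Fields must already hold harmonized values: bare decimals (a value such
    as ``"25.0%"`` is rejected), ``true``/``false`` booleans, empty string
    for missing. Errors name the file, line, and column.
    """
    directory = Path(directory)

    p_path = directory / "patients.csv"
    header, rows = _read_table(p_path, _PATIENT_KINDS)
    patients = []
    for i, row in enumerate(rows):
        line = i + 2  # header is line 1
        vals = {
            k: _parse_cell(row[k].strip(), kind, p_path, line, k)
            for k, kind in _PATIENT_KINDS.items()
        }
        tnm = (vals.pop("tnm_t"), vals.pop("tnm_n"), vals.pop("tnm_m"))
        extra = {
            k: row[k].strip() for k in header
            if k not in _PATIENT_KINDS and row[k].strip() != ""
        }
        try:
            patients.append(
                PatientRecord(
                    tnm=None if all(c is None for c in tnm) else tnm,
                    extra=extra, **vals,
                )
            )
        except ValueError as e:
            raise CohortFormatError(f"{p_path}:{line}: {e}") from e

    w_path = directory / "wsis.csv"
    _, rows = _read_table(w_path, _WSI_KINDS)
    wsis = []
    for i, row in enumerate(rows):
        line = i + 2
        vals = {
            k: _parse_cell(row[k].strip(), kind, w_path, line, k)
            for k, kind in _WSI_KINDS.items()
        }
        try:
            wsis.append(WSIRecord(**vals))
        except ValueError as e:
            raise CohortFormatError(f"{w_path}:{line}: {e}") from e

    r_path = directory / "rois.csv"
    _, rows = _read_table(r_path, _ROI_KINDS)
    rois = []
    for i, row in enumerate(rows):
        line = i + 2
        vals = {
            k: _parse_cell(row[k].strip(), kind, r_path, line, k)
            for k, kind in _ROI_KINDS.items()
        }
        if vals["evaluable"] is None:
            raise CohortFormatError(f"{r_path}:{line}:evaluable: value required")
        if vals["pitfalls"] is None:
            vals["pitfalls"] = ()
        try:
            rois.append(ROIAnnotation(**vals))
        except ValueError as e:
            raise CohortFormatError(f"{r_path}:{line}: {e}") from e

    cohort = Cohort(patients=patients, wsis=wsis, rois=rois)
    cohort.validate()
    return cohort


def read_raw_tables(
    patients_path: str | Path, wsis_path: str | Path, rois_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read arbitrary raw delimited tables for harmonization (all cells as
    strings, no NA inference)."""
    kw = dict(dtype=str, keep_default_na=False)
    return (
        pd.read_csv(patients_path, **kw),
        pd.read_csv(wsis_path, **kw),
        pd.read_csv(rois_path, **kw),
    )


def write_batch_plan(
    plan: BatchPlan, cohort: Cohort, directory: str | Path,
    config_echo: Mapping[str, Any] | None = None,
) -> None:
    """Export a batch plan as ``batch_plan.csv`` plus a JSON sidecar.

    CSV columns: rank, wsi_id, patient_id, the four score components, and
    batch (empty beyond the selected cases). The sidecar echoes the resolved
    configuration and the per-patient duplicate exclusions.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    owner = cohort.patient_of_wsi()
    batch_of = plan.batch_of()
    with open(directory / "batch_plan.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["rank", "wsi_id", "patient_id", "density_score", "race_ethnicity_score",
             "bcs_age_sex_score", "pitfall_score", "batch"]
        )
        for wsi_id, st, rank in plan.ranked_wsis:
            writer.writerow(
                [rank, wsi_id, owner[wsi_id], repr(st.density_score),
                 st.race_ethnicity_score, st.bcs_age_sex_score, st.pitfall_score,
                 batch_of.get(wsi_id, "")]
            )
    sidecar = {
        "batch_size": plan.batch_size,
        "n_batches": plan.n_batches,
        "excluded_duplicates": list(plan.excluded_duplicates),
        "batches": {str(b): members for b, members in sorted(plan.batches.items())},
        "config": dict(config_echo) if config_echo is not None else None,
    }
    (directory / "batch_plan.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


@dataclass
class RunManifest:
    """Provenance of one CLI run: command, resolved config, input digests,
    tool version, seed, timestamp."""

    command: str
    version: str
    seed: int | None
    config: dict[str, Any] | None
    inputs: dict[str, str]
    timestamp: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    directory: str | Path,
    command: str,
    config: Mapping[str, Any] | None = None,
    inputs: Iterable[str | Path] = (),
    seed: int | None = None,
) -> RunManifest:
    """Write ``manifest.json`` in ``directory`` and return the manifest."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        version=__version__,
        seed=seed,
        config=dict(config) if config is not None else None,
        inputs={str(p): _sha256(Path(p)) for p in inputs},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.to_json(directory / "manifest.json")
    return manifest
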