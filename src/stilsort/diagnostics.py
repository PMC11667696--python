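"""Diversity diagnostics: bin entropy, density skewness, subgroup retention.

These quantify what the rank-sort selection does to the cohort: whether the
selected cases spread more evenly across sTILs density bins (entropy up),
whether the density distribution is less dominated by the low tail (skewness
down), and which demographic subgroups survive selection.

The unit of the before/after metrics is the evaluable ROI: "before" covers
every evaluable ROI in the cohort, "after" the evaluable ROIs of the batched
WSIs. Entropy defaults to the natural logarithm over the three evaluable
density bins; both the base and (via ``bin_counts``) the category set are
caller-controlled.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, age_decade_bin
from .config import BIN_LABELS, DensityBinning
from .prioritization import BatchPlan

__all__ = [
    "DiversityReport",
    "shannon_entropy",
    "sample_skewness",
    "diversity_report",
    "stage_distribution",
]


def shannon_entropy(
    counts: Mapping[str, int] | Sequence[int], base: float | None = None
) -> float:
    """Shannon entropy H = -sum p_i log(p_i) of a categorical count vector.

    ``base=None`` means natural log. Zero-count categories contribute
    nothing; H is maximal (log k) for a uniform distribution over the k
    categories with positive counts, and 0 when one category holds all mass.
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    if any(v < 0 for v in values):
        raise ValueError("counts must be non-negative")
    if sum(values) == 0:
        raise ValueError("at least one count must be positive")
    return float(stats.entropy(values, base=base))


def sample_skewness(values: Sequence[float], adjusted: bool = False) -> float:
    """Fisher-Pearson coefficient of skewness g1 = m3 / m2^(3/2).

    ``adjusted=True`` applies the bias correction G1 = g1 *
    sqrt(n(n-1))/(n-2). Requires at least three values and non-zero
    variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires at least 3 values")
    if np.all(x == x[0]):
        raise ValueError("skewness undefined for zero-variance sample")
    return float(stats.skew(x, bias=not adjusted))


@dataclass
class DiversityReport:
    """Before/after selection metrics over evaluable ROIs and patients."""

    entropy_before: float
    entropy_after: float
    skewness_before: float
    skewness_after: float
    bin_counts_before: dict[str, int]
    bin_counts_after: dict[str, int]
    #: (variable, level) -> (count in cohort, count among selected patients)
    subgroup_retention: dict[tuple[str, str], tuple[int, int]]
    per_batch_bin_counts: dict[int, dict[str, int]]
    unit: str = "evaluable ROIs"

    def to_dict(self) -> dict:
        retention: dict[str, dict[str, list[int]]] = {}
        for (var, level), (n_cohort, n_sel) in self.subgroup_retention.items():
            retention.setdefault(var, {})[level] = [n_cohort, n_sel]
        return {
            "unit": self.unit,
            "entropy_before": self.entropy_before,
            "entropy_after": self.entropy_after,
            "skewness_before": self.skewness_before,
            "skewness_after": self.skewness_after,
            "bin_counts_before": dict(self.bin_counts_before),
            "bin_counts_after": dict(self.bin_counts_after),
            "subgroup_retention": retention,
            "per_batch_bin_counts": {
                str(b): dict(c) for b, c in sorted(self.per_batch_bin_counts.items())
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


_RETENTION_VARIABLES = ("sex", "race", "ethnicity", "bc_stage")


def _bin_counts(rois, binning: DensityBinning) -> dict[str, int]:
    counts = Counter(binning.assign(r.stils_density_pct) for r in rois)
    return {b: counts.get(b, 0) for b in BIN_LABELS}


def diversity_report(
    cohort: Cohort,
    batch_plan: BatchPlan,
    binning: DensityBinning | None = None,
    base: float | None = None,
    adjusted_skew: bool = False,
) -> DiversityReport:
    """Compare cohort-wide vs selected-case diversity for a batch plan.

    Entropy is computed over density-bin counts of evaluable ROIs; skewness
    over the raw density values. The retention table counts patients per
    demographic level in the full cohort vs among patients owning a batched
    WSI (missing values form their own level but are excluded from none).
    """
    binning = binning if binning is not None else DensityBinning()
    selected = {w for members in batch_plan.batches.values() for w in members}

    before_rois = [r for r in cohort.rois if r.evaluable]
    after_rois = [r for r in before_rois if r.wsi_id in selected]
    bins_before = _bin_counts(before_rois, binning)
    bins_after = _bin_counts(after_rois, binning)

    report = DiversityReport(
        entropy_before=shannon_entropy(bins_before, base=base),
        entropy_after=shannon_entropy(bins_after, base=base),
        skewness_before=sample_skewness(
            [r.stils_density_pct for r in before_rois], adjusted=adjusted_skew
        ),
        skewness_after=sample_skewness(
            [r.stils_density_pct for r in after_rois], adjusted=adjusted_skew
        ),
        bin_counts_before=bins_before,
        bin_counts_after=bins_after,
        subgroup_retention={},
        per_batch_bin_counts={},
    )

    owner = cohort.patient_of_wsi()
    selected_pids = {owner[w] for w in selected}

    def level_of(p, var):
        if var == "age_decade":
            return age_decade_bin(p.age) if p.age is not None else None
        return getattr(p, var)

    for var in _RETENTION_VARIABLES + ("age_decade",):
        cohort_counts: Counter = Counter()
        selected_counts: Counter = Counter()
        for p in cohort.patients:
            level = level_of(p, var)
            key = "missing" if level is None else str(level)
            cohort_counts[key] += 1
            if p.patient_id in selected_pids:
                selected_counts[key] += 1
        for level, n in sorted(cohort_counts.items()):
            report.subgroup_retention[(var, level)] = (n, selected_counts.get(level, 0))

    roi_index = cohort.rois_by_wsi()
    for b, members in sorted(batch_plan.batches.items()):
        rois = [r for w in members for r in roi_index.get(w, []) if r.evaluable]
        report.per_batch_bin_counts[b] = _bin_counts(rois, binning)

    return report


def stage_distribution(cohort: Cohort) -> pd.DataFrame:
    """Breast-cancer stage distribution, overall and per site.

    Tidy frame with columns ``stage, site, count, pct``; stages I-IV plus a
    ``missing`` row, percentages on the site's patient denominator (one
    decimal).
    """
    if not cohort.patients:
        raise ValueError("empty cohort")
    rows = []
    scopes = [("all", cohort.patients)] + [
        (s, [p for p in cohort.patients if p.site_id == s]) for s in cohort.site_ids()
    ]
    for site, subset in scopes:
        n = len(subset)
        for stage in ("I", "II", "III", "IV", "missing"):
            count = sum(
                1 for p in subset
                if (p.bc_stage is None and stage == "missing") or p.bc_stage == stage
            )
            rows.append(
                {
                    "stage": stage,
                    "site": site,
                    "count": count,
                    "pct": round(100.0 * count / n, 1),
                }
            )
    return pd.DataFrame(rows)
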