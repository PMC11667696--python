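"""Scoring configuration: bin thresholds, point tables, batch geometry.

Defaults encode the study's published scheme: density bins low (<=10%),
medium (10-40%], high (>40%) weighted 0/1/2; two points for non-White race
and two for Hispanic or Latino ethnicity; stage III/IV worth 2 and I/II worth
1; age bands rewarding the rarer decades; two points for non-female sex; and
a three-tier pitfall rarity map. Missing values always contribute 0 points.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

__all__ = [
    "BIN_LABELS",
    "DensityBinning",
    "DEFAULT_DENSITY_WEIGHTS",
    "DEFAULT_STAGE_POINTS",
    "DEFAULT_AGE_BANDS",
    "DEFAULT_RARITY_MAP",
    "ScoringConfig",
]

BIN_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class DensityBinning:
    """Thresholds discretizing sTILs density: low <= low_max < medium
    <= medium_max < high."""

    low_max_pct: float = 10.0
    medium_max_pct: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 < self.low_max_pct < self.medium_max_pct < 100.0:
            raise ValueError(
                f"require 0 < low_max ({self.low_max_pct}) < medium_max "
                f"({self.medium_max_pct}) < 100"
            )

    def assign(self, density_pct: float) -> str:
        if not 0.0 <= density_pct <= 100.0:
            raise ValueError(f"density {density_pct} outside [0, 100]")
        if density_pct <= self.low_max_pct:
            return "low"
        if density_pct <= self.medium_max_pct:
            return "medium"
        return "high"


DEFAULT_DENSITY_WEIGHTS: dict[str, float] = {"low": 0.0, "medium": 1.0, "high": 2.0}

DEFAULT_STAGE_POINTS: dict[str, int] = {"I": 1, "II": 1, "III": 2, "IV": 2}

#: inclusive (lo, hi, points) age bands in whole years; hi=None means open.
#: Ages above 90 score 2: the published bands stop at 81-90 and the scheme
#: rewards rarity, so the extreme tail keeps the top weight.
DEFAULT_AGE_BANDS: tuple[tuple[int, int | None, int], ...] = (
    (0, 40, 2),
    (41, 50, 2),
    (51, 60, 1),
    (61, 70, 0),
    (71, 80, 1),
    (81, 90, 2),
    (91, None, 2),
)

#: pitfall label -> points; 2 = rare (<=2 cases), 1 = semi-rare (3-10),
#: 0 = common (>10) in the source cohort.
DEFAULT_RARITY_MAP: dict[str, int] = {
    "Carcinoma In Situ": 2,
    "Ischemia": 2,
    "Sparse Distribution": 2,
    "Fibers": 2,
    "Over Staining": 2,
    "Under Staining": 2,
    "Benign Glands": 1,
    "Necrosis/Fibrin": 1,
    "Eosinophilia": 1,
    "Perinuclear Clearing": 1,
    "Crush Artifact": 1,
    "Adipocytes": 0,
    "Nerves/Vessels": 0,
    "Pyknotic Nuclei": 0,
    "Fibroblasts": 0,
}


@dataclass
class ScoringConfig:
    """Every knob of the rank-sort: point tables, conventions, batch shape."""

    binning: DensityBinning = field(default_factory=DensityBinning)
    density_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_WEIGHTS)
    )
    #: "all" counts every annotated ROI in the denominator (non-evaluable
    #: regions fall in no bin and dilute the score); "evaluable" restricts
    #: the denominator to evaluable ROIs.
    density_denominator: str = "all"
    stage_points: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_POINTS)
    )
    age_bands: tuple[tuple[int, int | None, int], ...] = DEFAULT_AGE_BANDS
    sex_nonfemale_points: int = 2
    rarity_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RARITY_MAP)
    )
    #: re-derive the rarity map from the cohort's own case counts instead of
    #: using the fixed map above
    derive_rarity_from_cohort: bool = False
    rare_max_cases: int = 2
    semirare_max_cases: int = 10
    #: "strict" errors on pitfall labels absent from the rarity map;
    #: "lenient" scores them 0 with a logged warning
    unlisted_pitfall_policy: str = "strict"
    batch_size: int = 8
    n_batches: int = 5
    #: residual tie-break after all four scores (only "wsi_id" supported)
    tie_break: str = "wsi_id"

    def __post_init__(self) -> None:
        if self.density_denominator not in ("all", "evaluable"):
            raise ValueError(f"bad density_denominator {self.density_denominator!r}")
        if self.unlisted_pitfall_policy not in ("strict", "lenient"):
            raise ValueError(f"bad unlisted_pitfall_policy {self.unlisted_pitfall_policy!r}")
        if self.tie_break != "wsi_id":
            raise ValueError(f"unsupported tie_break {self.tie_break!r}")
        if self.batch_size <= 0 or self.n_batches <= 0:
            raise ValueError("batch_size and n_batches must be positive")
        if not 0 < self.rare_max_cases <= self.semirare_max_cases:
            raise ValueError("require 0 < rare_max_cases <= semirare_max_cases")
        self.age_bands = tuple(tuple(b) for b in self.age_bands)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["binning"] = asdict(self.binning)
        d["age_bands"] = [list(b) for b in self.age_bands]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScoringConfig":
        d = dict(d)
        if "binning" in d and isinstance(d["binning"], dict):
            d["binning"] = DensityBinning(**d["binning"])
        if "age_bands" in d:
            d["age_bands"] = tuple(tuple(b) for b in d["age_bands"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoringConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
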