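"""Seeded synthetic cohorts with the statistical structure of a two-site
sTILs annotation study.

The generator emulates the features the prioritization method reacts to:
two sites with distinct race/ethnicity/age profiles, a subset of patients
contributing multiple sequential-section WSIs, about ten ROIs per WSI, a
low-skewed sTILs density mixture (most regions below 10%), tiered
rare/semi-rare/common pitfall frequencies, and heavy stage missingness. It
does not simulate image content or inter-reader annotation noise — densities
are taken as given, the way a first-pass expert estimate would be.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config, so identical seed + config reproduce the cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import truncnorm

from .cohort import Cohort, PatientRecord, ROIAnnotation, WSIRecord
from .config import DensityBinning

__all__ = [
    "SiteProfile",
    "SyntheticConfig",
    "generate_cohort",
    "study_preset",
    "table_matched_cohort",
]

#: per-ROI occurrence probabilities tiered so that, at the scale of tens of
#: WSIs with ~10 ROIs each, labels fall into the rare (<=2 cases),
#: semi-rare (3-10) and common (>10) classes.
DEFAULT_PITFALL_RATES: dict[str, float] = {
    "Carcinoma In Situ": 0.003,
    "Ischemia": 0.003,
    "Sparse Distribution": 0.003,
    "Fibers": 0.003,
    "Over Staining": 0.003,
    "Under Staining": 0.003,
    "Benign Glands": 0.012,
    "Necrosis/Fibrin": 0.012,
    "Eosinophilia": 0.012,
    "Perinuclear Clearing": 0.012,
    "Crush Artifact": 0.012,
    "Adipocytes": 0.08,
    "Nerves/Vessels": 0.08,
    "Pyknotic Nuclei": 0.08,
    "Fibroblasts": 0.08,
}

_REGION_TYPES = ("tumor bed", "invasive margin", "stroma-rich")


def _check_probs(name: str, probs: Mapping[str, float]) -> None:
    if any(not 0.0 <= p <= 1.0 for p in probs.values()):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(probs.values()) - 1.0) > 1e-6:
        raise ValueError(f"{name}: probabilities must sum to 1, got {sum(probs.values())}")


@dataclass
class SiteProfile:
    """Per-site demographics: cohort size, age model, race/ethnicity mix."""

    n_patients: int
    age_mean: float
    age_sd: float
    age_min: int = 18
    age_max: int = 100
    race_probs: dict[str, float] = field(
        default_factory=lambda: {"White": 0.6, "Black or African American": 0.35,
                                 "Other": 0.05}
    )
    ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: {"Not Hispanic or Latino": 0.92,
                                 "Hispanic or Latino": 0.08}
    )

    def validate(self, name: str) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"site {name}: n_patients must be positive")
        if self.age_sd <= 0 or not self.age_min < self.age_max:
            raise ValueError(f"site {name}: invalid age model")
        _check_probs(f"site {name} race_probs", self.race_probs)
        _check_probs(f"site {name} ethnicity_probs", self.ethnicity_probs)


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic cohort; every rate has a study-like
    default."""

    seed: int = 0
    sites: dict[str, SiteProfile] = field(
        default_factory=lambda: {
            "A": SiteProfile(n_patients=50, age_mean=64.0, age_sd=14.0),
            "B": SiteProfile(n_patients=55, age_mean=62.0, age_sd=14.0),
        }
    )
    #: probability a patient contributes a second (sequential-section) WSI
    multi_wsi_fraction: float = 0.17
    sex_probs: dict[str, float] = field(default_factory=lambda: {"F": 1.0})
    #: stage distribution conditional on the stage being documented
    stage_probs: dict[str, float] = field(
        default_factory=lambda: {"I": 0.481, "II": 0.365, "III": 0.096, "IV": 0.058}
    )
    stage_missing_prob: float = 0.51
    race_missing_prob: float = 0.01
    ethnicity_missing_prob: float = 0.04
    tumor_size_missing_prob: float = 0.3
    rois_per_wsi: int = 10
    evaluable_prob: float = 0.79
    #: marginal density-bin mixture; within a bin densities are uniform
    density_mixture: dict[str, float] = field(
        default_factory=lambda: {"low": 0.68, "medium": 0.22, "high": 0.10}
    )
    binning: DensityBinning = field(default_factory=DensityBinning)
    pitfall_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PITFALL_RATES)
    )

    def validate(self) -> None:
        if not self.sites:
            raise ValueError("at least one site is required")
        for name, profile in self.sites.items():
            profile.validate(name)
        _check_probs("sex_probs", self.sex_probs)
        _check_probs("stage_probs", self.stage_probs)
        _check_probs("density_mixture", self.density_mixture)
        if set(self.density_mixture) != {"low", "medium", "high"}:
            raise ValueError("density_mixture must cover exactly low/medium/high")
        for name in ("multi_wsi_fraction", "stage_missing_prob", "race_missing_prob",
                     "ethnicity_missing_prob", "tumor_size_missing_prob",
                     "evaluable_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.rois_per_wsi <= 0:
            raise ValueError("rois_per_wsi must be positive")
        if any(not 0.0 <= p <= 1.0 for p in self.pitfall_rates.values()):
            raise ValueError("pitfall_rates must lie in [0, 1]")


def _choice(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    labels = list(probs)
    return labels[rng.choice(len(labels), p=np.array(list(probs.values())) / sum(probs.values()))]


def _bin_range(bin_label: str, binning: DensityBinning) -> tuple[float, float]:
    if bin_label == "low":
        return 0.0, binning.low_max_pct
    if bin_label == "medium":
        return binning.low_max_pct, binning.medium_max_pct
    return binning.medium_max_pct, 100.0


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> Cohort:
    """Draw a referentially intact cohort from the configured distributions.

    ``seed`` overrides ``config.seed`` when given. Evaluable ROIs get a
    density by first sampling a bin from ``density_mixture`` and then a
    uniform draw within that bin's range; non-evaluable ROIs carry none.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    patients: list[PatientRecord] = []
    wsis: list[WSIRecord] = []
    rois: list[ROIAnnotation] = []

    for site_name in config.sites:
        profile = config.sites[site_name]
        a = (profile.age_min - profile.age_mean) / profile.age_sd
        b = (profile.age_max - profile.age_mean) / profile.age_sd
        ages = truncnorm.rvs(
            a, b, loc=profile.age_mean, scale=profile.age_sd,
            size=profile.n_patients, random_state=rng,
        )
        for i in range(profile.n_patients):
            pid = f"{site_name}-P{i:04d}"
            race = (
                None if rng.random() < config.race_missing_prob
                else _choice(rng, profile.race_probs)
            )
            ethnicity = (
                None if rng.random() < config.ethnicity_missing_prob
                else _choice(rng, profile.ethnicity_probs)
            )
            stage = (
                None if rng.random() < config.stage_missing_prob
                else _choice(rng, config.stage_probs)
            )
            tumor_size = (
                None if rng.random() < config.tumor_size_missing_prob
                else round(float(rng.lognormal(mean=math.log(2.0), sigma=0.6)), 1)
            )
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    site_id=site_name,
                    age=int(math.floor(ages[i])),
                    sex=_choice(rng, config.sex_probs),
                    race=race,
                    ethnicity=ethnicity,
                    bc_stage=stage,
                    tumor_size_cm=tumor_size,
                )
            )
            n_wsis = 2 if rng.random() < config.multi_wsi_fraction else 1
            for j in range(n_wsis):
                wsi_id = f"{pid}-W{j}"
                wsis.append(
                    WSIRecord(
                        wsi_id=wsi_id,
                        patient_id=pid,
                        scanner_make_model="Aperio AT2 DX",
                        image_resolution_um_per_px=0.25,
                        objective_magnification=40.0,
                        numerical_aperture=0.95,
                    )
                )
                for k in range(config.rois_per_wsi):
                    roi_id = f"{wsi_id}-R{k:02d}"
                    evaluable = bool(rng.random() < config.evaluable_prob)
                    density = None
                    if evaluable:
                        bin_label = _choice(rng, config.density_mixture)
                        lo, hi = _bin_range(bin_label, config.binning)
                        density = float(rng.uniform(lo, hi))
                    pitfalls = tuple(
                        label for label, rate in config.pitfall_rates.items()
                        if rng.random() < rate
                    )
                    rois.append(
                        ROIAnnotation(
                            roi_id=roi_id,
                            wsi_id=wsi_id,
                            evaluable=evaluable,
                            stils_density_pct=density,
                            tumor_region_type=str(
                                _REGION_TYPES[rng.choice(len(_REGION_TYPES))]
                            ),
                            stroma_pct=float(np.round(rng.uniform(10.0, 90.0), 1)),
                            pitfalls=pitfalls,
                        )
                    )

    cohort = Cohort(patients=patients, wsis=wsis, rois=rois)
    cohort.validate()
    return cohort


def study_preset() -> SyntheticConfig:
    """Two-site configuration mimicking the published study structure.

    Site SB: 49 patients, 87.8% White, mean age 64.98 (SD 14.95); site EUH:
    56 patients, 35.7% White / 62.5% Black or African American, mean age
    62.09 (SD 13.80). Stage missingness ~0.51 overall, 10 ROIs per WSI,
    79% of ROIs evaluable, density mixture 0.68/0.22/0.10 low/medium/high.
    """
    return SyntheticConfig(
        seed=0,
        sites={
            "SB": SiteProfile(
                n_patients=49,
                age_mean=64.98,
                age_sd=14.95,
                race_probs={"White": 0.878, "Black or African American": 0.102,
                            "Other": 0.020},
                ethnicity_probs={"Not Hispanic or Latino": 0.918,
                                 "Hispanic or Latino": 0.082},
            ),
            "EUH": SiteProfile(
                n_patients=56,
                age_mean=62.09,
                age_sd=13.80,
                race_probs={"White": 0.357, "Black or African American": 0.625,
                            "Other": 0.018},
                ethnicity_probs={"Not Hispanic or Latino": 0.981,
                                 "Hispanic or Latino": 0.019},
            ),
        },
    )


def table_matched_cohort(
    stage_counts: Mapping[str, tuple[int, int, int, int, int]] | None = None,
) -> Cohort:
    """Deterministic synthetic cohort reproducing published-style marginal
    counts, for exercising the summary tables.

    This is a synthetic stand-in constructed from printed marginal totals,
    not real patient data. Defaults: 105 patients across two sites; site SB
    ages 48x65 + 1x64 (mean 64.98), race 43 White / 5 Black or African
    American / 1 Other, ethnicity 45 / 4 Hispanic or Latino; site EUH ages
    55x62 + 1x67 (mean 62.09), race 20 White / 35 Black or African American
    / 1 missing, ethnicity 51 / 1 Hispanic or Latino / 4 missing; stage rows
    (I, II, III, IV, missing) per site default SB (4, 3, 1, 0, 41) and EUH
    (21, 16, 4, 2, 13), i.e. 54/105 stages missing and 25 stage-I patients.

    ``stage_counts`` overrides the per-site stage rows (each must sum to the
    site's patient count).
    """
    sites: dict[str, dict] = {
        "SB": {
            "ages": [65] * 48 + [64],
            "race": ["White"] * 43 + ["Black or African American"] * 5 + ["Other"],
            "ethnicity": ["Not Hispanic or Latino"] * 45 + ["Hispanic or Latino"] * 4,
        },
        "EUH": {
            "ages": [62] * 55 + [67],
            "race": ["White"] * 20 + ["Black or African American"] * 35 + [None],
            "ethnicity": ["Not Hispanic or Latino"] * 51 + ["Hispanic or Latino"]
            + [None] * 4,
        },
    }
    default_stages = {"SB": (4, 3, 1, 0, 41), "EUH": (21, 16, 4, 2, 13)}
    stage_counts = dict(default_stages if stage_counts is None else stage_counts)

    patients: list[PatientRecord] = []
    for site, cols in sites.items():
        n = len(cols["ages"])
        counts = stage_counts[site]
        if sum(counts) != n:
            raise ValueError(f"stage counts for {site} must sum to {n}")
        stages: list[str | None] = []
        for label, c in zip(("I", "II", "III", "IV", None), counts):
            stages.extend([label] * c)
        for i in range(n):
            patients.append(
                PatientRecord(
                    patient_id=f"{site}-P{i:04d}",
                    site_id=site,
                    age=cols["ages"][i],
                    sex="F",
                    race=cols["race"][i],
                    ethnicity=cols["ethnicity"][i],
                    bc_stage=stages[i],
                )
            )
    cohort = Cohort(patients=patients, wsis=[], rois=[])
    cohort.validate()
    return cohort
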