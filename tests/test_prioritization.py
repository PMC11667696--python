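"""Score components, hierarchical rank-sort, deduplication, batching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stilsort import (
    BatchingError,
    Cohort,
    ScoringConfig,
    assign_density_bin,
    bcs_age_sex_score,
    create_batches,
    deduplicate_by_patient,
    derive_rarity_map,
    normalized_density_count_score,
    pitfall_score,
    prioritize,
    race_ethnicity_score,
    rank_cases,
    score_wsi,
)
from stilsort.prioritization import ScoreTuple

from helpers import (
    brute_force_order,
    make_patient,
    make_roi,
    make_wsi,
    random_small_cohort,
    single_wsi_cohort,
)


class TestDensityBin:
    @pytest.mark.parametrize(
        ("density", "expected"),
        [(0.0, "low"), (10.0, "low"), (10.0001, "medium"), (40.0, "medium"),
         (40.5, "high"), (100.0, "high")],
    )
    def test_boundaries(self, density, expected):
        assert assign_density_bin(density) == expected

    @pytest.mark.parametrize("density", [-0.1, 100.1])
    def test_out_of_range_rejected(self, density):
        with pytest.raises(ValueError):
            assign_density_bin(density)


class TestDensityScore:
    def test_all_high_is_maximal(self):
        rois = [make_roi(f"R{i}", "W", density=80.0) for i in range(10)]
        assert normalized_density_count_score(rois) == 2.0

    def test_all_low_is_zero(self):
        rois = [make_roi(f"R{i}", "W", density=5.0) for i in range(10)]
        assert normalized_density_count_score(rois) == 0.0

    def test_half_high_half_low(self):
        rois = [make_roi(f"R{i}", "W", density=80.0) for i in range(5)]
        rois += [make_roi(f"S{i}", "W", density=5.0) for i in range(5)]
        assert normalized_density_count_score(rois) == pytest.approx(1.0)

    def test_non_evaluable_rois_dilute_the_default_denominator(self):
        rois = [make_roi("R0", "W", density=80.0), make_roi("R1", "W", density=None)]
        assert normalized_density_count_score(rois, denominator="all") == 1.0
        assert normalized_density_count_score(rois, denominator="evaluable") == 2.0

    def test_zero_evaluable_scores_zero_with_warning(self, caplog):
        rois = [make_roi("R0", "W", density=None)]
        with caplog.at_level("WARNING"):
            assert normalized_density_count_score(rois, denominator="evaluable") == 0.0
        assert "no evaluable" in caplog.text

    def test_zero_rois_rejected(self):
        with pytest.raises(ValueError):
            normalized_density_count_score([])


class TestDemographicScores:
    @pytest.mark.parametrize(
        ("race", "ethnicity", "expected"),
        [
            ("Black or African American", "Hispanic or Latino", 4),
            ("White", "Not Hispanic or Latino", 0),
            ("Other", "Not Hispanic or Latino", 2),
            ("White", "Hispanic or Latino", 2),
            (None, None, 0),
        ],
    )
    def test_race_ethnicity(self, race, ethnicity, expected):
        p = make_patient(race=race, ethnicity=ethnicity)
        assert race_ethnicity_score(p) == expected

    @pytest.mark.parametrize(
        ("stage", "age", "sex", "expected"),
        [
            ("III", 35, "M", 6),
            (None, 65, "F", 0),
            ("I", 55, "F", 2),
            ("IV", 85, "F", 4),
            ("II", 75, "F", 2),
            (None, 95, "F", 2),   # beyond the last printed band: rarest, top points
            (None, None, None, 0),
        ],
    )
    def test_stage_age_sex(self, stage, age, sex, expected):
        p = make_patient(bc_stage=stage, age=age, sex=sex)
        assert bcs_age_sex_score(p) == expected


class TestPitfallScore:
    def test_rarity_weighted_occurrences(self):
        rois = [
            make_roi("R0", "W", density=5.0, pitfalls=("Carcinoma In Situ", "Adipocytes")),
            make_roi("R1", "W", density=5.0, pitfalls=("Adipocytes",)),
            make_roi("R2", "W", density=5.0, pitfalls=("Adipocytes",)),
        ]
        assert pitfall_score(rois) == 2  # 2x1 rare + 0x3 common

    def test_repeated_semi_rare_counts_per_occurrence(self):
        rois = [make_roi(f"R{i}", "W", density=5.0, pitfalls=("Benign Glands",))
                for i in range(2)]
        assert pitfall_score(rois) == 2

    def test_no_pitfalls_scores_zero(self):
        assert pitfall_score([make_roi("R0", "W", density=5.0)]) == 0

    def test_unlisted_label_strict_vs_lenient(self, caplog):
        rois = [make_roi("R0", "W", density=5.0, pitfalls=("Mystery Artifact",))]
        with pytest.raises(KeyError, match="Mystery Artifact"):
            pitfall_score(rois, policy="strict")
        with caplog.at_level("WARNING"):
            assert pitfall_score(rois, policy="lenient") == 0
        assert "Mystery Artifact" in caplog.text

    @pytest.mark.parametrize(("n_wsis", "points"), [(1, 2), (2, 2), (3, 1),
                                                    (10, 1), (11, 0)])
    def test_derived_rarity_tiers_by_case_count(self, n_wsis, points):
        patients = [make_patient(pid=f"P{i}") for i in range(n_wsis)]
        wsis = [make_wsi(f"W{i}", f"P{i}") for i in range(n_wsis)]
        rois = [make_roi(f"R{i}", f"W{i}", density=5.0, pitfalls=("Weird Thing",))
                for i in range(n_wsis)]
        cohort = Cohort(patients=patients, wsis=wsis, rois=rois)
        assert derive_rarity_map(cohort)["Weird Thing"] == points


class TestScoreWsi:
    def test_componentwise_worked_example(self):
        cohort = single_wsi_cohort(
            densities=[80.0] * 10,
            patient_kwargs=dict(race="Black or African American",
                                ethnicity="Hispanic or Latino",
                                bc_stage="IV", age=35, sex="M"),
            pitfalls_per_roi=[("Ischemia",)] + [()] * 9,
        )
        st_ = score_wsi(cohort.wsis[0], cohort)
        assert st_ == ScoreTuple(2.0, 4, 6, 2)

    def test_all_zero_case(self):
        cohort = single_wsi_cohort(densities=[5.0] * 10)
        assert score_wsi(cohort.wsis[0], cohort) == ScoreTuple(0.0, 0, 0, 0)

    def test_mixed_density_otherwise_zero_patient(self):
        cohort = single_wsi_cohort(densities=[80.0] * 5 + [5.0] * 5)
        assert score_wsi(cohort.wsis[0], cohort) == ScoreTuple(1.0, 0, 0, 0)


class TestRanking:
    def test_single_wsi_is_rank_one(self):
        cohort = single_wsi_cohort(densities=[5.0])
        ranked = rank_cases(cohort)
        assert [w for w, _ in ranked] == [cohort.wsis[0].wsi_id]

    def test_pitfall_breaks_tie_on_first_three_components(self):
        patients = [make_patient(pid=f"P{i}") for i in range(2)]
        wsis = [make_wsi(f"W{i}", f"P{i}") for i in range(2)]
        rois = [make_roi("R0", "W0", density=5.0, pitfalls=("Benign Glands",) ),
                make_roi("R1", "W1", density=5.0,
                         pitfalls=("Benign Glands", "Carcinoma In Situ"))]
        cohort = Cohort(patients=patients, wsis=wsis, rois=rois)
        ranked = rank_cases(cohort)
        assert [w for w, _ in ranked] == ["W1", "W0"]

    def test_matches_brute_force_oracle_on_small_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            cohort = random_small_cohort(rng)
            ranked = rank_cases(cohort)
            assert ranked == brute_force_order(ranked)

    def test_ranking_is_independent_of_input_row_order(self):
        rng = np.random.default_rng(7)
        cohort = random_small_cohort(rng)
        reversed_cohort = Cohort(
            patients=cohort.patients[::-1], wsis=cohort.wsis[::-1],
            rois=cohort.rois[::-1],
        )
        assert rank_cases(cohort) == rank_cases(reversed_cohort)

    def test_enrichment_race_dominates_when_all_else_equal(self):
        patients, wsis, rois = [], [], []
        for i in range(6):
            race = "White" if i % 2 == 0 else "Black or African American"
            patients.append(make_patient(pid=f"P{i}", race=race))
            wsis.append(make_wsi(f"W{i}", f"P{i}"))
            rois += [make_roi(f"W{i}-R{k}", f"W{i}", density=30.0) for k in range(3)]
        cohort = Cohort(patients=patients, wsis=wsis, rois=rois)
        ranked = [w for w, _ in rank_cases(cohort)]
        non_white = {"W1", "W3", "W5"}
        assert set(ranked[:3]) == non_white


class TestDeduplication:
    def _two_wsi_cohort(self):
        patient = make_patient(pid="P1")
        wsis = [make_wsi("W-good", "P1"), make_wsi("W-bad", "P1")]
        rois = [make_roi("R0", "W-good", density=80.0),
                make_roi("R1", "W-bad", density=5.0)]
        cohort = Cohort(patients=[patient], wsis=wsis, rois=rois)
        return cohort

    def test_keeps_best_ranked_wsi_per_patient(self):
        cohort = self._two_wsi_cohort()
        ranked = rank_cases(cohort)
        retained, excluded = deduplicate_by_patient(ranked, cohort)
        assert [w for w, _ in retained] == ["W-good"]
        assert excluded == ["W-bad"]

    def test_identity_when_all_patients_unique(self):
        rng = np.random.default_rng(3)
        patients = [make_patient(pid=f"P{i}") for i in range(5)]
        wsis = [make_wsi(f"W{i}", f"P{i}") for i in range(5)]
        rois = [make_roi(f"R{i}", f"W{i}", density=float(rng.integers(0, 100)))
                for i in range(5)]
        cohort = Cohort(patients=patients, wsis=wsis, rois=rois)
        ranked = rank_cases(cohort)
        retained, excluded = deduplicate_by_patient(ranked, cohort)
        assert retained == ranked and excluded == []

    def test_three_wsis_keep_only_top(self):
        patient = make_patient(pid="P1")
        wsis = [make_wsi(f"W{i}", "P1") for i in range(3)]
        rois = [make_roi(f"R{i}", f"W{i}", density=d)
                for i, d in enumerate([80.0, 30.0, 5.0])]
        cohort = Cohort(patients=[patient], wsis=wsis, rois=rois)
        retained, excluded = deduplicate_by_patient(rank_cases(cohort), cohort)
        assert [w for w, _ in retained] == ["W0"]
        assert set(excluded) == {"W1", "W2"}

    def test_retained_score_is_lexicographic_max_of_patient(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            cohort = random_small_cohort(rng)
            ranked = rank_cases(cohort)
            retained, _ = deduplicate_by_patient(ranked, cohort)
            owner = cohort.patient_of_wsi()
            by_patient = {}
            for w, s in ranked:
                by_patient.setdefault(owner[w], []).append(s)
            assert len({owner[w] for w, _ in retained}) == len(retained)
            for w, s in retained:
                assert s == max(by_patient[owner[w]])


def _fake_retained(n):
    return [(f"W{r:03d}", ScoreTuple(2.0 - r * 0.01, 0, 0, 0)) for r in range(n)]


class TestBatching:
    def test_round_robin_assignment_of_forty_cases(self):
        plan = create_batches(_fake_retained(40), batch_size=8, n_batches=5)
        batch_of = plan.batch_of()
        for r, (wsi_id, _, rank) in enumerate(plan.ranked_wsis, start=1):
            assert rank == r
            assert batch_of[wsi_id] == (r - 1) % 5 + 1
        assert all(len(m) == 8 for m in plan.batches.values())

    def test_single_batch_keeps_rank_order(self):
        plan = create_batches(_fake_retained(8), batch_size=8, n_batches=1)
        assert plan.batches[1] == [w for w, _ in _fake_retained(8)]

    def test_two_batches_split_odd_even_ranks(self):
        plan = create_batches(_fake_retained(16), batch_size=8, n_batches=2)
        ids = [w for w, _ in _fake_retained(16)]
        assert plan.batches[1] == ids[0::2]
        assert plan.batches[2] == ids[1::2]

    def test_shortfall_raises_with_count(self):
        with pytest.raises(BatchingError, match="shortfall 1"):
            create_batches(_fake_retained(39), batch_size=8, n_batches=5)

    def test_batches_partition_top_cases(self):
        plan = create_batches(_fake_retained(50), batch_size=8, n_batches=5)
        members = [w for m in plan.batches.values() for w in m]
        assert len(members) == len(set(members)) == 40
        assert set(members) == set(plan.selected_wsi_ids())

    def test_full_pipeline_is_deterministic(self):
        rng = np.random.default_rng(9)
        cohort = random_small_cohort(rng, max_wsis=8)
        cfg = ScoringConfig(batch_size=1, n_batches=1)
        assert prioritize(cohort, cfg) == prioritize(cohort, cfg)


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

_patient_st = st.builds(
    make_patient,
    race=st.sampled_from(["White", "Black or African American", "Other", None]),
    ethnicity=st.sampled_from(["Hispanic or Latino", "Not Hispanic or Latino", None]),
    sex=st.sampled_from(["F", "M", None]),
    bc_stage=st.sampled_from(["I", "II", "III", "IV", None]),
    age=st.one_of(st.none(), st.integers(0, 110)),
)


@settings(max_examples=100, deadline=None)
@given(patient=_patient_st)
def test_score_bounds_and_missing_never_increases(patient):
    """Component ranges hold and blanking any field never raises a score."""
    re_score = race_ethnicity_score(patient)
    bas_score = bcs_age_sex_score(patient)
    assert re_score in (0, 2, 4)
    assert 0 <= bas_score <= 6
    for fields in (("race",), ("ethnicity",), ("sex",), ("bc_stage",), ("age",),
                   ("race", "ethnicity", "sex", "bc_stage", "age")):
        degraded = make_patient(
            race=patient.race, ethnicity=patient.ethnicity, sex=patient.sex,
            bc_stage=patient.bc_stage, age=patient.age,
        )
        for f in fields:
            setattr(degraded, f, None)
        assert race_ethnicity_score(degraded) <= re_score
        assert bcs_age_sex_score(degraded) <= bas_score


@settings(max_examples=100, deadline=None)
@given(
    bins=st.lists(st.sampled_from([5.0, 20.0, 80.0, None]), min_size=1, max_size=12),
    index=st.integers(0, 11),
)
def test_upgrading_a_low_roi_never_decreases_density_score(bins, index):
    rois = [make_roi(f"R{i}", "W", density=d) for i, d in enumerate(bins)]
    base = normalized_density_count_score(rois)
    i = index % len(bins)
    upgraded = list(bins)
    if upgraded[i] is not None and upgraded[i] <= 10.0:
        upgraded[i] = 80.0
    rois_up = [make_roi(f"R{i}", "W", density=d) for i, d in enumerate(upgraded)]
    assert normalized_density_count_score(rois_up) >= base


@settings(max_examples=100, deadline=None)
@given(
    labels=st.lists(st.sampled_from(
        ["Carcinoma In Situ", "Benign Glands", "Adipocytes"]), max_size=8),
    added=st.sampled_from(["Carcinoma In Situ", "Ischemia"]),
)
def test_adding_a_rare_pitfall_never_decreases_pitfall_score(labels, added):
    rois = [make_roi("R0", "W", density=5.0, pitfalls=tuple(labels))]
    base = pitfall_score(rois)
    rois_more = [make_roi("R0", "W", density=5.0, pitfalls=tuple(labels) + (added,))]
    assert pitfall_score(rois_more) >= base
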