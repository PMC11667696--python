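# Methods

## Problem and approach

`stilsort` builds reader-study batches from a cohort of whole-slide images
(WSIs) of H&E-stained breast-core biopsies, each carrying region-of-interest
(ROI) annotations of stromal tumor-infiltrating lymphocyte (sTILs) density.
Clinical cohorts assembled retrospectively are dominated by low sTILs
densities and by the majority demographic of the contributing sites; a
validation dataset sampled naively from such a cohort gives little insight
into model performance on the underrepresented subgroups. The package
implements a hierarchical rank-sort: every WSI receives a tuple of four
scores, cases are sorted in descending lexicographic order of that tuple,
deduplicated to one WSI per patient, and dealt round-robin into fixed-size
batches. A later score component matters only when all earlier components
tie, so the hierarchy encodes an explicit priority ordering over enrichment
criteria rather than a weighted compromise.

## The score tuple

For one WSI with ROI set R and patient p:

1. **Normalized density count score** (range [0, 2]). Each evaluable ROI's
   density x is binned: low (x ≤ 10%), medium (10% < x ≤ 40%), high
   (x > 40%). The score is Σ_b w_b · n_b / N with weights w = (0, 1, 2) for
   (low, medium, high). By default N counts *all* annotated ROIs of the WSI,
   so non-evaluable regions — which fall in no bin — dilute the score; a
   config switch (`density_denominator="evaluable"`) restricts N to
   evaluable ROIs. The all-ROIs reading is the literal one for a
   "fraction of ROIs in the WSI" and is the shipped default; the ambiguity
   is surfaced as an option rather than resolved silently. A WSI with no
   evaluable ROIs scores 0 with a logged warning.
2. **Race and ethnicity score** {0, 2, 4}: 2 points for documented race ≠
   White, 2 for ethnicity = Hispanic or Latino.
3. **Stage, age, sex score** [0, 6]: stage III/IV 2 points, I/II 1 point;
   age ≤ 40, 41–50 or 81–90 → 2 points, 51–60 or 71–80 → 1, 61–70 → 0; sex
   ≠ F → 2 points. Ages above 90 fall outside the published bands; they
   score 2 because the scheme rewards rarity and the extreme tail is the
   rarest band. This is configurable via `age_bands`. Non-integer ages are
   floored to whole years.
4. **Pitfall score** (unbounded ≥ 0): each pitfall occurrence — counted per
   ROI appearance, so a pitfall on three ROIs counts three times — earns its
   rarity points: 2 for rare labels (≤ 2 cases in the source cohort), 1 for
   semi-rare (3–10), 0 for common (> 10). The shipped map fixes the fifteen
   labels' tiers; `derive_rarity_map` re-derives tiers for a new cohort,
   counting a "case" as a WSI containing the label at least once. Labels
   absent from the map raise by default (`strict`); a `lenient` policy
   scores them 0 with a warning, because silent zeros would hide vocabulary
   drift.

Missing values contribute 0 points in every component: an undocumented race
or sex is never treated as membership in the enriched group, so complete
metadata can only help a case, never hurt a documented one relative to an
absent one.

Residual ties after all four components are broken by ascending `wsi_id`.
The published procedure is silent here; a content-based key makes the
ranking a pure function of cohort content, independent of input row order.

## Deduplication and batching

Some patients contribute several sequential-section WSIs. After ranking,
only each patient's best-ranked WSI is retained (order otherwise
preserved). The top `batch_size × n_batches` retained cases (default 8 × 5
= 40) are assigned by 1-based rank r to batch ((r − 1) mod n_batches) + 1 —
the round-robin pattern 1, 2, 3, 4, 5, 1, 2, … — so each batch receives an
even spread of ranks rather than a contiguous block. Fewer retained cases
than the requested geometry is an error stating the shortfall.

## Metadata harmonization

Raw site exports are mapped to controlled vocabularies via a data
dictionary (field → type, allowed values, alias map). Every raw value is
either alias-mapped, type-coerced, or set to the single missing sentinel
(`None` in memory, empty field on disk); tokens such as `Unknown`, `NA`,
`N/A` and the empty string all normalize to it, so "unknown" and "missing"
are one category in every downstream table. Each substitution is logged one
line at a time. Harmonization is idempotent: applied to its own output it
makes no further changes.

When the aggregated stage is absent but TNM categories are present, the
stage is derived from a shipped transcription of the AJCC 8th-edition
anatomic stage groups (`staging.py`), replaceable via the `groups` argument.
`M1` implies stage IV on its own; otherwise a missing T, N or M yields
missing. In-situ-only disease (`Tis`) and `T0 N0` have no anatomic group
within I–IV and also map to missing; `TX`/`NX`/`MX` normalize to missing.

ROIs violating the density/evaluability invariant (a density on a
non-evaluable ROI, or an evaluable ROI without one) are rejected at
harmonization rather than silently repaired, so scoring never sees them.

## Diversity diagnostics

`diversity_report` compares the full cohort against the batched selection.
The unit is the evaluable ROI: "before" covers every evaluable ROI,
"after" those belonging to selected WSIs. Two scalar summaries are used:

* **Shannon entropy** of the density-bin counts, H = −Σ p_i ln p_i, natural
  log by default over the three evaluable bins (both base and category set
  are caller-controlled). Entropy rises as bins equalize; maximum ln 3 ≈
  1.0986 for a uniform three-bin distribution.
* **Sample skewness**, the Fisher–Pearson coefficient g1 = m3 / m2^{3/2}
  over raw density values (bias-corrected G1 by flag). Low-dominated
  cohorts have strongly positive skew; enrichment for medium/high densities
  lowers it.

The report also tabulates per-batch bin counts and subgroup retention
(cohort count vs selected count per level of sex, race, ethnicity, stage,
and closed decade age bins [1–10], [11–20], …).

The package reports entropy only under this documented convention; it does
not attempt to reproduce entropy values published under unstated
conventions that exceed the three-bin natural-log maximum.

## Synthetic cohorts

The generator (`synthetic.py`) draws cohorts with the structural features
the method reacts to, using one seeded `numpy.random.Generator` and no
global state: two sites with distinct truncated-normal age models (truncated
to [18, 100] years — an adult oncology cohort) and categorical
race/ethnicity mixes; a fraction of patients contributing a second WSI; ~10
ROIs per WSI of which ~79% are evaluable; densities drawn by sampling a bin
from the marginal mixture (default 0.68 / 0.22 / 0.10 low/medium/high) and
then uniformly within the bin's range — the simplest within-bin shape
consistent with a stated marginal; and per-ROI pitfall occurrence rates
tiered (0.003 / 0.012 / 0.08) so that rare/semi-rare/common case counts
emerge at the scale of tens of WSIs. Demographics and densities are drawn
independently; any real joint structure (e.g. stage × density correlation)
is not emulated, so passing tests demonstrate the mechanics of the
enrichment, not its effect size on real data.

`study_preset()` fixes the two-site geometry: site SB, 49 patients,
87.8% White, age mean 64.98 (SD 14.95); site EUH, 56 patients, 35.7%
White / 62.5% Black or African American, age mean 62.09 (SD 13.80); stage
distribution over documented stages ≈ (0.48, 0.37, 0.10, 0.06) for I–IV
with ~51% of stages missing; `multi_wsi_fraction` 0.17. These are the study
conditions every stochastic test and the acceptance script run under.

`table_matched_cohort()` is a deterministic synthetic reconstruction that
hits published-style *marginal* counts exactly (105 patients; 63 White;
site age sums giving means 64.98 / 62.09 and pooled 63.44; 54 missing
stages; 25 stage-I patients). It exists to exercise the summary tables
against known arithmetic; it contains no WSIs or ROIs.

## Numerical and formatting choices

* Percentages in summary tables are rounded to one decimal, means/SDs to
  two (sample SD, ddof = 1; absent for n = 1), matching conventional cohort
  tables.
* Entropy and skewness are computed via `scipy.stats.entropy` /
  `scipy.stats.skew`; the tests check them against direct evaluations of
  the defining formulas.
* On-disk floats use Python `repr`, which round-trips exactly; missing is
  always the empty field, never a literal token.
* Density bin boundaries are closed on the left bin (10.0 is low, 40.0 is
  medium), exactly as the binning is defined.
* The problem sizes used by the test suite and acceptance script — 105
  patients per replicate, 100 replicates for the enrichment property,
  1,000 small cohorts for the oracle comparison, 10,000 ROIs for generator
  fidelity — were chosen to make sampling error negligible relative to the
  asserted margins while keeping a full run in seconds.

## Known limitations

* The rarity map, point tables and bin thresholds are fixed inputs; the
  package does not learn weights or optimize batch composition (pure rank +
  modular assignment, no integer programming).
* The synthetic generator does not simulate image content, reader
  disagreement, or site-specific annotation protocols.
* Free-text pathology reports, assay-positivity logic (ER/PR/HER2), and
  slide-handling workflows are out of scope; inclusion as a
  triple-negative case is taken as given.
* The stage lookup covers invasive anatomic groups only; prognostic-group
  staging (which incorporates grade and biomarkers) is intentionally not
  implemented.
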