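# Methods

## The model

The Adhesion Risk Score is a consensus-weighted additive prognostic index:
twenty risk factors for post-surgical adhesion formation in gynaecological
surgery, each rated on an integer scale 0–4, summed into two sub-scores.
The weights express expert consensus, not fitted coefficients — there is no
likelihood, no uncertainty estimate and nothing to optimise; the package is
therefore a deterministic scoring engine rather than a statistical model
object. Its correctness claims are combinatorial: the achievable
preoperative range is exactly 0–36 and the perioperative range exactly
3–31, every intermediate integer is achievable (verified by exhaustive
enumeration), and the score is monotone in every factor because all weights
are non-negative and the sum is additive.

Assumptions inherited from the score's construction:

* factor effects are additive with no interactions;
* each categorical factor (cancer, radiation, surgery type/site, adhesion
  severity) contributes exactly one selected level, never a sum of
  applicable levels — the published worked maximum of 36 counts cancer only
  once (3 points), which would be impossible if subtypes summed;
* the three "sequelae of previous operations" factors (Hb-drop bleeding,
  postoperative complications, postoperative infection) presuppose at least
  one previous operation; a profile asserting a sequela with
  `previous_surgery_count == 0` is rejected as contradictory;
* adhesion quality and severity agree on the absence of adhesions
  (`quality == none` ⇔ `severity == none`).

## Interpretation choices in the weight tables

The published tables contain two typographical ambiguities that the package
resolves once, as follows:

* **Previous surgeries.** The factor's levels are rendered ambiguously in
  the source table; the worked minimum and maximum profiles pin down
  0 → 0 and >1 → 4, and the remaining level is read as 1 → 3.
* **Procedure duration.** The middle band is printed as "9 min to 2 hours";
  it is read as **90 min to 2 hours** (a dropped zero), giving bands
  <90 min → 2, 90–120 min → 3, >120 min → 4. The 120-minute boundary is
  assigned to the middle band because the top band is printed strictly
  "over 2 hours". Durations are accepted only as plain minutes; no
  "1h30"-style parsing is offered, precisely to avoid silent band
  misassignment around this boundary.
* **Adhesion quality** has no weight 1 (none 0, filmy 2, vascular 3,
  dense 4); this is transcribed as printed, not "corrected".

## Thresholds

Risk categories use the published inclusive integer thresholds:
preoperative 0–12 / 13–24 / 25–36 and perioperative 3–17 / 18–28 / 29–31.
The preoperative cutpoints coincide with exact tertiles of the range; the
perioperative cutpoints deviate from arithmetic tertiles because the
consensus panel adjusted them after field testing — the printed values are
treated as authoritative. Scores outside the achievable range raise an
error rather than being clamped: an out-of-range value can only signal a
scoring bug. A YAML config can override the intervals for sensitivity
exploration, but overrides must still partition the achievable range. The
combined ARS (sum of both sub-scores) is reported without a category, as no
combined threshold exists.

The second sub-score is published under two names; the package uses
*perioperative* canonically and accepts *intraoperative* as an alias.

## Missing data policy

In cohort files, a missing optional boolean defaults to false with a logged
warning, and absent enum factors default to their "absent"/"none" level.
Perioperative `duration_minutes` and `surgery_type_site` are mandatory
(every operation has both; the published minimum of 3 = 2 + 1 is only
reachable because they always contribute) and their absence invalidates the
row. Validation reports are structured (row, field, reason); lenient mode
skips invalid rows, strict mode fails the whole read.

## Synthetic cohorts

No patient-level dataset accompanies the score (the ~40-patient field test
behind the threshold adjustment is unpublished), so cohorts are simulated.
Each factor is drawn independently from a configurable marginal prevalence;
the defaults sketch a plausible elective gynaecological surgical population
— about half the patients with a previous abdominal/pelvic operation,
endometriosis in ~30 %, cancer in ~10 %, radiation rare, mostly
laparoscopic procedures under two hours. These defaults are illustrative
placeholders, not epidemiological estimates.

Cross-field rules are repaired deterministically in a fixed draw order so a
seed fully determines the cohort: the surgery count is drawn first and the
three sequelae are forced false wherever it is zero; adhesion quality is
drawn first and severity is then drawn from the positive-severity levels
(renormalised) where adhesions exist, or forced to `none` where they do
not. A consequence is that the *marginal* prevalence of the repaired
fields differs from the configured value; their configured prevalences are
honoured *conditionally* (sequelae among patients with a previous
operation, severity levels among patients with adhesions), and the
convergence tests check exactly that. Durations are drawn as whole minutes
uniformly within the selected band (30–89 / 90–120 / 121–240).

An optional correlation hook (`adhesion_coupling`, off by default) upgrades
adhesion quality one level with the given probability in patients with
moderate or severe endometriosis, emulating the clinical association
between endometriosis and pelvic adhesions. It is the only departure from
independence offered; real cohorts are of course jointly structured in ways
no independent-margins generator reproduces (e.g. long operations and
multi-quadrant complexity co-occur), so passing tests demonstrate the
engine's arithmetic and plumbing, not epidemiological realism.

## Enumeration oracle

`enumerate_profiles` generates every combination of declared factor levels
— 14,400 preoperative and 23,040 perioperative combinations — excluding and
counting the cross-field-invalid ones (4,200 and 8,064 respectively), with
one representative duration per band (60 / 100 / 180 min), which is
exhaustive for the score since only the band matters. Scoring the valid
10,200 + 14,976 profiles reproduces the extremes 0/36 and 3/31 and shows
every intermediate score is achievable; the test suite cross-checks the
full score distribution against a second, independently transcribed
brute-force implementation of the tables. Both enumerations score in well
under a second on one CPU.

## Test calibration and statistical caveats

Property tests (monotonicity under every single-factor raise, breakdown
conservation, I/O round-trip identity) run on seeded cohorts of 200–500
patients (1,000 profiles). The prevalence-convergence check draws 10,000
patients and requires every factor's empirical prevalence to lie within 3
binomial standard errors of its configured value. With ~45 level-wise
comparisons at a fixed 3-SE band, roughly one seed in eight will exceed the
band somewhere by chance alone; the check is therefore tied to the
generator's documented default spec and seed rather than an arbitrary one,
and the tolerance itself is left at 3 SE.

## Known limitations

* The score's predictive validity cannot be assessed here: no outcome data
  (adhesion occurrence) are published, and the package deliberately offers
  no outcome simulation or probability calibration of the categories.
* rASRM staging and Knightly grading are consumed as inputs (a stage, a
  category), never computed from lesion maps or operative findings.
* Synthetic prevalence defaults are not calibrated to any real population.
* Percentages in cohort summaries are displayed to one decimal with the
  rounding residue assigned to the largest category so columns sum to 100.
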