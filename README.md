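# adhesionrisk

Post-surgical adhesions — fibrous bands that form between intra-abdominal
tissues after surgical trauma — are among the most frequent complications of
gynaecological surgery, causing chronic pain, bowel obstruction and secondary
infertility. `adhesionrisk` implements the consensus **Adhesion Risk Score
(ARS)**, a simple weighted additive index that lets a gynaecological surgeon
stratify an individual patient's adhesion risk before and during an
operation, so that preventive measures (such as adhesion-reduction barrier
agents) can be targeted at the women most likely to benefit.

## The score

The ARS consists of two sub-scores, each the plain sum of ten integer factor
weights in {0, …, 4}:

* **Preoperative Adhesion Risk Score**, range **0–36** — patient history and
  pre-surgery findings: number of previous abdominal/pelvic surgeries
  (0 → 0, 1 → 3, >1 → 4), history of post-surgical adhesions (4), concomitant
  abdominal/gynaecological inflammation or infection (4), endometriosis
  severity by rASRM stage (minimal 1 … severe 4), cancer category (2–3),
  radiation therapy (local 4, distant 1), keloid scarring (3), and three
  sequelae of previous operations — unexpected Hb-drop bleeding (2),
  postoperative complications (4) and postoperative infection (4).
* **Perioperative (intraoperative) Adhesion Risk Score**, range **3–31** —
  findings and events during the current operation: quality (filmy 2 …
  dense 4) and Knightly extent (single 1 … bowel involvement 4) of existing
  adhesions, bleeding >500 ml (4), procedure duration (<90 min 2,
  90 min–2 h 3, >2 h 4), complex/multi-quadrant surgery (3), excessive
  coagulation (2), type and site of surgery (laparoscopy/fallopian tube 1 …
  open/ovary 4), foreign-body placement (3), electrical scalpel (2) and
  peritoneal closing (1). Duration and surgery type/site always contribute,
  hence the minimum of 3.

Each sub-score maps to a risk category with inclusive integer thresholds:

| risk   | preoperative | perioperative |
|--------|--------------|---------------|
| low    | 0–12         | 3–17          |
| medium | 13–24        | 18–28         |
| high   | 25–36        | 29–31         |

The sum of both sub-scores (the total ARS, 3–67) is reported as descriptive
information only; no combined threshold is defined.

## Worked example

```python
from adhesionrisk import PreoperativeProfile, score_preoperative

profile = PreoperativeProfile(
    previous_surgery_count=2,       # >1 prior operations -> 4 points
    endometriosis="moderate",       # rASRM stage III     -> 3 points
    prior_postoperative_infection=True,  # >=38 degC, >=2 days -> 4 points
)
result = score_preoperative(profile)
print(result.score, result.risk_category)
print(result.breakdown)
```

prints

```
11 low
{'previous_surgery_count': 4, 'history_postsurgical_adhesions': 0,
 'concomitant_inflammation_or_infection': 0, 'endometriosis': 3, 'cancer': 0,
 'radiation': 0, 'keloid_scarring': 0, 'prior_intraperitoneal_bleeding': 0,
 'prior_postoperative_complications': 0, 'prior_postoperative_infection': 4}
```

— a preoperative score of 11 (4 + 3 + 4), which falls in the low-risk band
0–12, with the per-factor contributions itemised.

The same engine runs from the shell over whole cohorts (CSV or JSON):

```
ars simulate cohort.csv -n 100 --seed 7   # synthetic 100-patient cohort
ars score cohort.csv scored.csv           # per-patient scores + breakdowns
ars report scored.csv                     # risk distribution summary
ars thresholds                            # print the risk bands
```

`ars score` writes one row per patient with both sub-scores, risk
categories, the total ARS and all twenty per-factor point columns;
`ars report` then tabulates the low/medium/high distribution and the top
contributing factors. Because no patient-level dataset is published with
the score, `ars simulate` generates seeded synthetic cohorts with
configurable per-factor prevalences (see `docs/methods.md`).

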