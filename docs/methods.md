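# Methods

## The score

The Coefficient of Energy Balance (CEB) condenses the two energy analytes of
an urgent cerebrospinal-fluid (CSF) examination into the average ATP yield
per glucose molecule implied by the lactate/glucose balance:

    CEB = 38 − 18 · lactate_CSF / glucose_CSF        (both in mmol/L)

Fully aerobic glycolysis yields 38 ATP per glucose; fully anaerobic
glycolysis yields 2 ATP and two lactate molecules, so each unit of the
lactate/glucose ratio forfeits 18 ATP. The score is bounded above by 38
(attained only at zero lactate) and unbounded below: the oxidative burst of
professional phagocytes (neutrophils in purulent inflammation; macrophages
eliminating intracellular bacteria, fungi, or tumour cells) consumes glucose
anaerobically at scale and drives CEB to strongly negative values.

Three bands drive interpretation: CEB ≥ 28.00 is the aerobic reference
range, 10.00 < CEB < 28.00 marks the moderately anaerobic state of serous
inflammation, and CEB ≤ 10.00 marks the oxidative burst. Both boundary
values belong to the outer bands (≤ and ≥), following the interpretation
scheme's inequality signs. All comparisons are made on unrounded values;
two-decimal formatting happens only at the display layer.

Numerical choices: CSF glucose at or below a floor of 0.01 mmol/L makes the
ratio measurement noise, so the score is refused with an explicit
"unquantifiable glucose" error carrying a qualitative extreme-anaerobic
flag — never an infinite value. The variance-stabilising transform for
display is log₁₀(40 − CEB); the base is configurable, base 10 chosen so a
decade of (40 − CEB) is one plot unit. The offset 40 keeps the argument
≥ 2 for every admissible score.

## Reference ranges and the control gate

The packaged YAML table holds the laboratory decision limits: Q_glu
0.55–0.65, CSF lactate 0.7–2.1 mmol/L, leukocytes 0–4/µL, CSF
beta-2-microglobulin 0.2–2.0 mg/L, intrathecal synthesis of IgG/IgA/IgM
exactly 0 %, and age-bracketed ranges for CSF total protein and the albumin
quotient (stored as dimensionless ratios; the table's ×10⁻³ scaling is
applied at load). Printed limits are inclusive. Infant brackets are
resolved in days; year-labelled brackets contain the ages whose floor year
falls inside the label, and ages above the oldest bracket reuse it. No
range exists for absolute CSF glucose, which is used only inside CEB and
Q_glu. Missing analytes flag NOT_EVALUABLE, which blocks the CONTROL label:
full normality can only be asserted for measured analytes.

## Syndrome classification

Pleocytosis is a leukocyte count above 4/µL, labelled by the predominant
differential class (GP/MP/LP). Any presence of malignant cells overrides the
composition: TP at pleocytic counts, TO otherwise. At normal counts the
composition is judged against the normal lymphocyte:monocyte balance of 7:3;
it is pathological — oligocytosis, GO/MO/LO — when the granulocyte fraction
exceeds 0.1, the monocyte fraction exceeds 0.5, or the lymphocyte fraction
exceeds 0.9 (all configurable; 7:3 is the only published anchor, so the
tolerances are this package's convention). Ties in predominance are broken
granulocyte > monocyte > lymphocyte — granulocytic findings carry the
highest urgency — and flagged AMBIGUOUS_PREDOMINANCE. Cytologically bland
records are CONTROL only when the whole flagged panel is in range and all
three intrathecal-synthesis inputs are present and zero; otherwise they are
labelled MO with a "barrier/immune abnormality only" annotation rather than
dropped, since chemically abnormal CSF cannot be a control. Erythrocytes
above 100/µL attach an ARTIFICIAL_BLOOD_ADMIXTURE flag without changing the
label. Intrathecal synthesis is an input percentage; the hyperbolic
discrimination functions that produce it are out of scope.

## Interpretation engine

An ordered rule table maps (band, syndrome) to one of seven suspicion
patterns (see `interpret.py` for the full table). Design points: GO in the
serous band maps to SEROUS_INFLAMMATION, not to a burst pattern — the
granulocyte-type oligocytosis picture belongs to initial non-purulent
stages and early ischaemia. GO in the burst band maps to NEUTROPHIL_BURST
with a low-cellularity caveat; this combination has no published mapping and
the choice is our convention, recorded in the emitted narrative. GP or LP
outside the burst band raise PREVENTIVE_NEUROPROTECTION_SUSPECT (cells
without burst energetics), except LP in the serous band, which is classic
serous inflammation and matches first. A burst band never yields NORMAL.
Every sentence of the narrative is traceable to a rule id, and every report
ends with the comprehensive-context reminder.

## Synthetic cohort generator

The generator emulates a reference cohort of 8183 lumbar punctures
(controls 235, GO 64, GP 766, LO 1200, LP 1610, MO 2699, MP 1457, TO 31,
TP 121; the tumorous groups are pooled as "TO + TP" in comparisons). For
each group only seven CEB quantiles are published (min, 2.5 %, 25 %, 50 %,
75 %, 97.5 %, max), so CEB is drawn by inverting a piecewise-linear quantile
function through the anchors. No parametric family is published, and none
fits distributions this skewed (GP: median 4.68, minimum −2996.50);
anchoring instead guarantees that the published summary statistics are
recoverable by construction. Below the 2.5th-percentile anchor the
interpolation runs in log₁₀(40 − CEB) so the heavy negative tail is reached
smoothly with total probability 0.025 and no point mass at the printed
minimum; the short upper segment (97.5 % to max) stays in raw CEB space.

Each CEB value is then realised as a full record: CSF glucose is drawn from
a group-conditional plausible range, lactate is set to
glucose · (38 − CEB)/18 — the exact score inversion, so regenerated records
recompute their CEB to 1e−9 — and serum glucose places Q_glu in a
group-conditional band. Cell counts, differential fractions, chemistry,
and immunology are drawn to satisfy each syndrome's definition: controls
pass every reference-range check (their glucose window is additionally
intersected with the lactate range 0.7–2.1 mmol/L so no control is flagged),
pleocytic groups draw log-uniform counts of 5–2000/µL with the correct
predominant class, tumorous records carry malignant cells, and 33.8 % of GP
records above the burst cutoff receive an erythrocyte admixture above
100/µL. These realisation ranges are invented plumbing — no per-group
glucose or cellularity tables are published — and are marked as such in the
packaged configuration. Randomness uses one root seed with named substreams
per group and variable, so adding a variable never perturbs existing draws,
and cohorts are byte-reproducible.

What the generator does not emulate: age dependence of CEB, repeat-puncture
structure, within-group correlation between CEB and cellularity, and
measurement error. Passing tests therefore demonstrate that the analysis
stack recovers the published distributional structure, not that it would
behave identically on raw clinical data.

## Cohort statistics

Descriptives use linear interpolation between order statistics (Hyndman–Fan
definition 7, the numpy default); the definition is configurable because
quantile recovery at small n depends on it. Normality screening is a
one-sample Kolmogorov–Smirnov test against a moment-fitted normal, used
only to justify the nonparametric route (n < 5 or a constant sample is not
evaluable). The omnibus test is tie-corrected Kruskal–Wallis with a
chi-square approximation (k − 1 df), retained even at small n; tests carry
an exact-permutation oracle for tiny instances. An all-identical pooled
sample returns H = 0, p = 1 explicitly. The post hoc procedure is Dunn's
z-test on the joint ranks with tie correction and Bonferroni adjustment
over all 28 pairs (Holm available); the published analysis names no method,
and Dunn/Bonferroni is the standard companion of Kruskal–Wallis. Adjusted
p-values are reported in the published three-tier scheme: "P < 0.001",
"P < 0.01", "No difference".

## Known limitations

* The synthetic cohort reproduces the published strong separations
  (all 14 "P < 0.001" pairs) and non-separations, but the narrow
  "P < 0.01" middle tier — adjusted p in [0.001, 0.01), a raw-p window of
  roughly one z-tenth at these group sizes — depends on the interior shape
  of each group's distribution between anchors, which seven quantiles do
  not determine. With piecewise-linear interiors, 18–20 of the 28 published
  tiers reproduce; the mismatches are almost exclusively published
  "P < 0.01" pairs observed as the stronger "P < 0.001".
* Band frequencies per group are approximate for the same reason (GP burst
  share ≈ 59 % vs the published 57.8 %; MP overshoots).
* Syndrome labels for mixed cytological pictures rest on this package's
  tie-break and tolerance conventions; the source laboratory's handling of
  such records is not published.
* Classification thresholds assume counts from a Fuchs–Rosenthal chamber
  expressed per µL; no chamber-conversion logic is included.

## Problem sizes used in the shipped tests and analyses

Large-sample quantile-recovery tests draw 100 000 values per group;
cohort-level tests and analysis scripts use the printed sizes (8183
records) or a deterministic 10 % subsample; the pairwise-tier study uses
20 seeds at full printed sizes.
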