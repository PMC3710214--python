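# Methods

## The decision problem

MPS I severity is a continuum, but the treatment decision is binary:
haematopoietic stem cell transplantation for Hurler (H), enzyme
replacement for Hurler-Scheie and Scheie (together "non-H"). The package
implements a categorical three-step classifier over data obtainable in
the first month of life, plus the statistics used to build and internally
validate it on a 30-patient cohort. There is deliberately no
probabilistic output: each step is a rule with an explicit evidence
requirement, and a patient no rule can decide is returned as
*indeterminate* rather than forced into a class.

## Step rules and their assumptions

**Genotype (step 1).** Call H iff both alleles are on the severe list.
The list is an input (the packaged default has 25 entries); membership is
exact set membership on a normalized form — prefix-cased namespace
(`p.`/`c.`), uppercased whitespace-free token. No HGVS grammar
validation or transcript mapping is attempted: tokens are opaque keys,
which is all exact-list matching needs. The rule is one-sided by design.
Mutations associated with attenuated disease are *not* used to call
non-H, because the phenotypic effect of attenuated alleles varies with
the allele in trans, modifier genes and environment; a genotype off the
list is simply uninformative and flows on. Consequence: the step can
never produce a false positive from a novel allele, and novel alleles
(expected to be common once newborn screening scales up) degrade
sensitivity only.

**Residual activity (step 2).** Fibroblast IDUA activity against a
rule-in / rule-out threshold pair (defaults 0.32 / 0.66 nmol·mg⁻¹·hr⁻¹).
Zone map: `activity <= lower` → H; `lower < activity <= upper` →
gray zone (fall through); `activity > upper` → non-H. The lower boundary
is **inclusive**: the development cohort contains a Hurler patient at
exactly 0.32, and the published operating characteristics (rule-in
sensitivity 5/9) hold only with inclusion. The upper boundary is
exclusive upward; no observed value sits at 0.66, so this choice is free
and keeps the gray zone half-open, `(lower, upper]`.

`derive_thresholds` re-derives boundaries from labeled data at observed
values: the lower cut-off is the largest observed activity `v` such that
every sample at or below `v` is H (the most permissive cut-off with 100%
observed rule-in specificity; a cross-class tie at `v` disqualifies it,
breaking ties toward the smaller H zone), and the upper cut-off is the
largest observed H activity (the tightest cut-off with 100% observed
rule-out sensitivity). On the packaged cohort this yields 0.32 / 0.58.
The packaged *default* upper cut-off is nonetheless pinned at the
published constant 0.66: no observed-value or midpoint convention
reproduces that constant from the 18 activities, and since no observation
lies in (0.58, 0.77), every performance number is identical under either
choice; we keep the published constant for comparability and report the
data-driven value alongside. When even the smallest observed activity is
non-H, no pure rule-in zone exists; the derivation returns a width-zero
zone flagged `separable=False` instead of guessing.

**Clinical findings (step 3).** Two tri-state findings: signs of upper
respiratory tract obstruction (excessive snoring, continuously runny
nose, obstructive apneas, feeding difficulty from nasal obstruction) and
inguinal hernia. Either present → H; both known absent → non-H; one
absent and one unknown → indeterminate, because absence of evidence on
one feature is not evidence of absence. Preterm patients (< 37+0 weeks)
pass through by default — prematurity itself causes inguinal hernias and
respiratory signs — switchable via `preterm_uses_clinical` for cohorts
where the confounding is judged acceptable. Unknown gestational age is
treated as term (term is the population prior) and is distinguishable
from recorded term by `GestationalAge.known`.

**Composition and missing data.** Steps run in the fixed order genotype →
activity → clinical; the first decisive step wins, so a severe genotype
can never be overridden by an activity or a finding. A missing activity
skips step 2 entirely — four of the 30 development patients lack
fibroblast cultures and are nonetheless correctly classified by their
findings, which is what forces this policy. Every remaining gap resolves
to indeterminate.

## Statistics

All kernels are exact, because the development cohort has n = 30 with
subgroups of 4-17:

- **ROC/AUC** by concordant-pair counting, oriented "low activity =
  positive (H)": AUC = (#{pos < neg} + ½·ties) / (n₊·n₋). Curve points
  enumerate observed cut-offs; the identity AUC = U/(n₊·n₋) against the
  Mann-Whitney statistic is kept under test.
- **Fisher's exact test**, two-sided, probability-based: with margins
  fixed, sum the hypergeometric probabilities of every table no more
  probable than the observed one (relative tolerance 1e-7 on the
  comparison, integer combinatorics throughout). This is the convention
  of the major statistical packages and reproduces the published screen
  p-values (0.0055, 0.0325).
- **Mann-Whitney U**, exact two-sided: U = #{x > y} + ½·ties;
  p = P(|U − nm/2| ≥ |U_obs − nm/2|) under the permutation null. With no
  ties and min(n, m) ≤ 12 the null distribution is enumerated in full via
  the standard count recurrence; otherwise a seeded permutation test with
  10⁵ draws (vectorized midrank computation) takes over. The permutation
  fallback is the one stochastic element in the package's statistics.

Published-style percentages round half-up to integers (82.35 → 82,
55.6 → 56, 88.9 → 89); raw fractions are always retained.

## Evaluation accounting

Positive class is H throughout. The complete algorithm is scored over
determinate verdicts only, with the indeterminate count reported
separately — an indeterminate is an honest "no call", and coercing it
either way would fabricate information. A one-sided *screening* step
evaluated in isolation is the exception: there, an undecided patient is
a negative call (the genotype step alone detects 14/17 Hurler patients —
sensitivity 82% — at specificity 100%), enabled via
`evaluate(..., indeterminate_as_negative=True)`. Empty denominators
yield `None`, never a fabricated 0 or 1. The feature screen excludes
preterm births, drops unknowns per feature, and computes p only when at
least `min_n` (default 10) patients have data and both table margins are
non-zero, mirroring how sparsely-observed findings (hepatomegaly,
kyphosis, …, each observed in ≤ 3 newborns) are reported as
"not computed".

## Synthetic cohorts

The generator emulates the cohort structure the algorithm assumes, with
defaults matched to the development cohort: phenotype mix (17, 6, 7)/30;
P(both alleles severe-listed | H) = 14/17 and never for non-H; activity
log-normal per phenotype — log-normal because activities are positive
and span an order of magnitude, parameters (log-mean, log-sd) of
(−1.02, 0.30) for H, (−0.10, 0.60) for H/S and (0.30, 0.18) for S,
placing each phenotype's mass over its observed range (H 0.23–0.58, H/S
straddling the gray zone, S 1.05–1.70) — finding prevalences from the
screen tables (H: 7/9 and 4/9; H/S: 1/6 and 0; S: 0 and 0); activity
missing with probability 12/30, findings 11/30 and 9/30, gestational age
3/30; preterm fraction 3/30. Activities are reported rounded to two
decimals, floored at 0.01, like assay output.

What the generator does **not** emulate: assay noise structure (the
~18.5% inter-assay CV of the underlying enzyme assay), allele-frequency
population genetics, correlation between findings beyond what the shared
phenotype induces, and recall bias in retrospective charts. Passing
recovery tests therefore show that the *procedures* (threshold
derivation, evaluation) behave correctly under the stated model, not
that the published operating characteristics generalize to new cohorts.

All draws flow through one `numpy` PCG64 generator seeded from the
config, so a fixed config is byte-reproducible; `recovery_experiment`
gives replicate `r` the seed `seed + r`.

## Numerical and interface choices

- Problem sizes in tests and the acceptance script are those of the
  packaged fixtures (30 patients, 18 activities); synthetic experiments
  use 120–1000 patients and ≤ 20 replicates, ample for the construction
  guarantees they check.
- The report schema ships as a JSON Schema document; validation is a
  small structural checker with identical constraints.
- Cohort files are UTF-8 delimited text, comma or tab auto-detected;
  `X` and the empty cell mean unknown/missing, matching clinical
  data-entry practice.
- The CLI is a thin layer over the library: config precedence is CLI
  flag > config file > packaged defaults, resolved values are echoed to
  stderr for provenance, data goes to stdout/files.

## Known limitations

- The severe-mutation list is region-dependent and will age as newborn
  screening surfaces novel alleles; it is a swappable input for exactly
  that reason.
- The development cohort supports no confidence intervals or external
  validation; the 100%/100% figure is an internal-validation statement
  over 29 classifiable patients, nothing more.
- Per-patient data exist for only the two packaged clinical findings;
  the other twelve screened characteristics are represented in the
  screen machinery but not in the fixture (their per-patient values were
  never published and are not fabricated).
- Gray-zone patients lacking both activity and findings are
  indeterminate by design; downstream workflows must route them to
  follow-up rather than expect a forced call.
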