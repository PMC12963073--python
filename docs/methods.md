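# Methods

## Scope and model of the report

`placenta-ssr` implements standardized structured reporting (SSR) for
placental pathology as a deterministic rule engine over discrete data
elements. A case record mirrors the tabs of a structured placental
report — demographics, macroscopy, microscopy — and every diagnostic
output (severity grades, phenotype code, prognostic group) is *computed*
from those elements, never entered by hand. The grading rules are the
Amsterdam-consensus patterns of placental injury with the
Freedman-Ernst severity and phenotype extensions: four graded patterns
(acute inflammation, chronic inflammation, fetal vascular malperfusion,
maternal vascular malperfusion) plus ungraded "other significant
pathology" lesions carrying suffix letters.

The diagnostic judgment of whether a lesion is present on the slide
remains with the pathologist; the engine standardizes everything
downstream of that judgment.

## Lesion catalog

The controlled vocabulary is a versioned CSV
(`src/placenta_ssr/data/lesion_catalog.csv`, 86 rows). Each lesion is
bound to exactly one of five compartments (membranes, umbilical cord,
chorionic plate, basal plate, villous/intervillous) and one of the five
injury patterns, so the catalog partitions into 25 (compartment,
pattern) cells. Scoring attributes live on the row, not in code:

* `mvm_points` (0/1/2) — the maternal-vascular-malperfusion point
  contribution;
* `other_letter` — one of the ten suffix letters h,i,j,k,s,n,o,p,q,r,
  each bound to exactly one lesion (k and s are the two stages of basal
  plate myometrial fibers and exclude each other);
* `exclusivity_group` — graded escalations of one finding (single vs
  multiple infarcts; retroplacental hematoma with vs without
  hemosiderin/infarct) that may not co-occur in a case.

Two deliberate modelling choices: *increased perivillous fibrin
deposition* is a single lesion that both carries suffix letter `n` and
scores 1 MVM point, so one data entry fires both effects; lesions that
the source vocabulary lists under more than one compartment (e.g.
meconium-laden macrophages) get compartment-specific ids, with the
suffix letter bound to the membranes entry so each letter maps to one
row. *Fibrinoid necrosis/acute atherosis* is catalogued at both of its
sites (membrane arterioles, basal plate) and both rows score 1 point.

## Grading rules

* **Acute inflammation** — the maternal and fetal Amsterdam stages
  (0–3) are captured discretely; the overall grade is high when
  `max(maternal, fetal) >= ai_high_stage_threshold`, low when any
  acute-inflammation lesion is recorded below that, none otherwise. The
  published scheme does not pin the "high stage" boundary to a number;
  the default threshold is stage 2, configurable, and both components
  are stored so alternative rules can be applied retrospectively.
* **Chronic inflammation** — graded by the number of *distinct*
  compartments containing at least one chronic-inflammation lesion:
  ≥ 2 high, 1 low, 0 none. Multiplicity within a compartment is
  irrelevant by construction.
* **Fetal vascular malperfusion** — high on more than one avascular-
  villi focus with foci of ≥ 45 villi, or ≥ 2 occlusive/nonocclusive
  thrombi (chorionic plate or stem villi); low for any other fetal
  vascular lesion; none otherwise. The 45-villi focus qualifier and
  both count cutoffs are config values. The high-grade criterion is
  evaluated from the discrete counts regardless of which lesion
  checkboxes accompany them; validation warns on a thrombus count
  without a matching lesion rather than blocking the case.
* **Maternal vascular malperfusion** — the point score is the sum of
  `mvm_points` over distinct recorded scoring lesions; score ≥ 4 is
  high, 2–3 low, 0–1 none. Low placental weight/placental hypoplasia
  (2 points) is derived, not ticked: it is present when the *trimmed*
  weight falls strictly below the 10th percentile for gestational age
  (or when recorded explicitly), and its points count only when at
  least one other MVM-scoring lesion is present — isolated hypoplasia
  is never scored. Untrimmed weights are never percentile-gated into
  the score, since the percentile references describe trimmed weights.

## Phenotype code and group assignment

The code writes the four grades in fixed order A/a, C/c, F/f, M/m
(letter present iff grade ≠ none, uppercase iff high), followed by the
suffix letters in canonical order. Group assignment is a first-match
decision tree over the grade levels, from combined high-grade patterns
(1a "triple threat" … 1d), through high acute + high fetal (2),
isolated high grades (3, 4, 5 with their subgroups), low-grade
combinations (6, 7), other-pathology-only (8), isolated acute
inflammation (9a/9b), to histologically normal (10). Suffix letters
never change the group when any core pattern is present; group 8
requires an empty core code plus ≥ 1 letter.

The group *definitions* are authoritative; the enumerated code lists
serve as a test fixture. Three printed list entries contradict their own
group definitions ("am" under 7a, which is defined as *without* acute
inflammation; "Acf"/"Acfm" under 4b/4d, which are defined by
*high-grade* chronic inflammation) and are corrected to "m", "ACf",
"ACfm" in the fixture, with the original spellings preserved in a
`printed_code` column. `enumerate_all_codes()` walks all 3⁴ = 81 grade
combinations and the tests assert that the corrected lists equal that
enumeration exactly — 81 distinct codes, each in exactly one group.

## Macroscopic calculations

* **Umbilical coiling index** = coil count / cord length (coils/cm),
  rounded half-even to 3 decimals; classified against a configurable
  normal range defaulting to [0.07, 0.30] coils/cm (the conventional
  published normal range; the source scheme prints none).
* **Percentile banding** (placental weight, cord diameter) compares the
  measurement to a per-completed-week reference table (p3/p10/p50/p90/
  p97 CSV). Lookup uses the nearest tabulated week with ties toward the
  lower week — published references are per completed week, so no
  interpolation is done; the rule is isolated in `ReferenceTable.row_for`
  and swappable. Band boundaries: `below_p10` is *strict* (`value <
  p10`), matching the "< 10th percentile" hypoplasia rule; upper bands
  are inclusive (`value >= p90`, `>= p97`) by symmetric convention.
* The bundled reference CSVs are **synthetic** (monotone round-number
  curves, weeks 20–42, labelled as such in the files). They exist so
  the pipeline and tests run end-to-end without endorsing any
  population norm; deployments supply their own tables via
  `--weight-ref` / `--cord-ref`.

## Validation model

Structural validity (types, ranges, required identity fields such as
accession and gestational age) is enforced at parse time by pydantic.
Completeness and cross-field consistency are checked by
`validate_case`, which returns issues instead of raising: core-item
absence (the core profile is a config list, defaulting to weight +
trimmed flag, completeness, shape, cord length/coils/diameter/insertion,
fetus count/status), twin cases without the septum/share/anastomoses
block (and singletons with it), findings that do not resolve in the
catalog or sit in the wrong compartment, exclusivity violations, and
acute-inflammation stages recorded without an acute lesion.
`level="full"` adds warnings for absent optional detail. Grading
refuses cases with outstanding errors.

## Synthetic case generator

`fixtures.make_case` builds cases from a profile (seed, target grade
quadruple, suffix letters, optional invalidity class, noisy flag, twin
flag) with *minimal* lesion recipes — the smallest lesion set achieving
each target grade — so the enumeration suite probes both the
sensitivity and the specificity of every rule. A noisy mode adds
grade-neutral findings. Gross measurements are drawn deterministically
(a string-seeded PRNG keyed by the full profile) from plausible
third-trimester ranges, with weight drawn around the synthetic
reference median so a generated case is never incidentally below the
10th percentile. The generator emulates report structure, not lesion
epidemiology: co-occurrence frequencies, gestational-age case mix and
real measurement error are all out of scope, so passing tests show the
rules are implemented exactly, not that the tool was validated on real
cohorts.

Problem sizes throughout are desk-scale by design: the exhaustive
81-case enumeration suite, grids of a few dozen points for every
threshold, and a few hundred randomized lesion sets for the gating and
monotonicity properties; the whole suite runs in about a second.

## Determinism

Identical case + config + catalog yield byte-identical result JSON and
synoptic text: results carry no timestamps, JSON keys are sorted, the
config is hashed into the output (`config_digest`), and the catalog
version is recorded. This is what makes pooled re-analysis of archived
results meaningful.

## Known limitations

* The engine encodes one published revision of the grading scheme;
  criteria evolution is handled by editing the catalog/config, but no
  migration tooling between catalog versions is provided.
* Whether massive perivillous fibrinoid deposition (letter `o`) should
  also carry an MVM point is unstated in the source scheme; only
  "increased" (letter `n`) scores, per the printed point list.
* Validated for third-trimester-style reports; nothing in the rules is
  gestational-age-aware beyond the percentile lookups, and the bundled
  reference range stops at 20 weeks.
* No terminology binding (SNOMED CT etc.), no database backend, no
  narrative-conclusion generation: the free-text comment field exists
  but is never auto-populated.
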