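# placenta-ssr

Standardized structured reporting (SSR) for placental pathology.

Placental histology underlies much of what we know about preeclampsia,
fetal growth restriction, preterm birth and stillbirth, yet most
placental reports are narrative free text: lesion terminology,
severity grading and diagnostic categories vary between pathologists,
which makes reports hard to pool for research and hard to act on
clinically. `placenta-ssr` is a rule engine that turns discrete,
controlled findings into a reproducible synoptic report: the pathologist
records *what is on the slide* from a controlled lesion catalog, and
the engine computes everything downstream — severity grades, the
phenotype code and the prognostic group — identically every time.

It is aimed at perinatal pathologists and researchers who need
machine-readable placental reports (cohort studies, trial pathology
cores, registry pipelines), and at anyone implementing or auditing
Amsterdam-consensus grading.

## The grading scheme

Findings are drawn from a versioned catalog of 86 lesions, each bound
to one of five compartments (membranes, umbilical cord, chorionic
plate, basal plate, villous/intervillous) and one of five injury
patterns. The four graded patterns each map to {none, low, high}:

* **Acute inflammation (A/a)** — high iff
  max(maternal stage, fetal stage) ≥ 2 on the 1–3 staging
  (threshold configurable); low for any acute lesion below that.
* **Chronic inflammation (C/c)** — counted over *distinct* involved
  compartments *k*: high iff k ≥ 2, low iff k = 1.
* **Fetal vascular malperfusion (F/f)** — high iff > 1 avascular-villi
  focus of ≥ 45 villi, or ≥ 2 occlusive/nonocclusive thrombi
  (chorionic plate or stem villi); low for any other fetal vascular
  lesion.
* **Maternal vascular malperfusion (M/m)** — a point score
  S = Σ points over recorded scoring lesions (1 or 2 points each):
  high iff S ≥ 4, low iff 2 ≤ S ≤ 3. Placental hypoplasia (trimmed
  weight < 10th percentile for gestation, 2 points) counts only
  alongside ≥ 1 other scoring lesion.

Ungraded "other significant pathology" lesions contribute suffix
letters (h…r). The phenotype code writes the grades in fixed order
(e.g. `aCFM` = low-grade acute + high-grade chronic/fetal/maternal),
and a decision tree assigns exactly one of 21 prognostic groups
(1a "triple threat" … 10 histologically normal); all 3⁴ = 81 grade
combinations enumerate to 81 distinct codes that partition into the
groups. Macroscopy is served by automated calculations: the umbilical
coiling index (coils/cm) and percentile banding of placental weight
and cord diameter against gestational-age reference tables.

See `docs/methods.md` for the full rule set, boundary semantics and
design choices.

## Worked example

Generate a synthetic case targeting low-grade acute inflammation plus
high-grade chronic inflammation, fetal and maternal vascular
malperfusion, with delayed villous maturation (letter p), then run it:

```python
import placenta_ssr as ps
from placenta_ssr.fixtures import FixtureProfile, make_case
from placenta_ssr.macro import synthetic_weight_reference

catalog = ps.load_catalog()
case = make_case(
    FixtureProfile(
        seed=1,
        target=(ps.Grade.LOW, ps.Grade.HIGH, ps.Grade.HIGH, ps.Grade.HIGH),
        letters=("p",),
    ),
    catalog,
)
ps.write_case(case, "demo.json")
result = ps.run_case(
    "demo.json", catalog, weight_reference=synthetic_weight_reference(), out_dir="."
)
print(open("demo.synoptic.txt").read())
```

prints (abridged):

```
MACROSCOPY
  Weight:               555.0 g (trimmed)
  Cord length:          50.0 cm
  Cord coil count:      17
  Coiling index:        0.34 coils/cm (hypercoiled)
  Weight percentile:    band p10_p90 (reference week 39; p50 575 g; deviation -20.0 g)

GRADING (computed)
  Acute inflammation:   low
  Chronic inflammation: high (2 compartment(s))
  Fetal vasc. malperf.: high
  Maternal vasc. malp.: high (score 4)
  Other pathology:      p

PHENOTYPE AND GROUP
  Phenotype code:       aCFMp
  Group:                1a [C,F,M all high (triple threat)]
```

Reading the numbers: 17 coils over 50 cm give a coiling index of
17/50 = 0.34 coils/cm, above the configured 0.30 upper normal bound,
hence hypercoiled; 555 g at 39 weeks sits between the 10th and 90th
percentile of the (synthetic, demo-only) weight reference, 20 g below
its median; chronic lesions in 2 compartments and an MVM score of 4
both cross their high-grade cutoffs; the code `aCFM` with all three of
C, F, M high lands in group 1a, and letter `p` rides along without
affecting the group. The machine-readable twin of this report is
written to `demo.result.json`.

The same pipeline is available from the shell:

```sh
ssr validate case.json            # completeness/consistency issues
ssr run case.json --weight-ref my_weights.csv --out results/
ssr batch cases/ --out results/   # per-case results + group-count CSV
ssr enumerate                     # the 81-row code/group table
ssr fixtures --seed 1 --count 81  # deterministic synthetic cases
```

The bundled percentile tables are synthetic placeholders; supply local
reference CSVs (`ga_weeks,p3,p10,p50,p90,p97`) for real use.

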