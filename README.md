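# odmfhir

Semantic interoperability tooling for clinical study data: convert CDISC ODM
studies onto FHIR resources with explicit loss accounting, or model studies
*natively* in FHIR with the proposed `ClinicalStudyPlan` and
`ClinicalStudyData` resources, and check a protocol's coverage of the WHO
trial-registration data set.

## Who this is for

Clinical-research informaticians who hold study exports in CDISC ODM 1.3 XML
(the electronic-data-capture interchange standard) and need them as FHIR
resources — either to feed FHIR-native infrastructure or to assess what a
conversion would lose.  ODM organises a study as two parallel hierarchies, a
metadata side (StudyEventDef → FormDef → ItemGroupDef → ItemDef, plus code
lists) and a clinical-data side (Subject → StudyEvent → Form → ItemGroup →
Item), joined by shared object identifiers (OIDs).  ODM is a sound syntactic
vehicle but carries almost no context: nothing marks *how* a measurement was
taken, and demographics, units and semantics live in conventions rather than
the model.

## What the package does

**Legacy mapping** (`odmfhir.mapping`).  A study is routed onto eight FHIR
resources (pinned to the STU3 snapshot of September 2016): CarePlan (study
definition; one activity per study event, scheduled or unscheduled),
Questionnaire (one per form, group tree mirroring the item groups), Patient
and ClinicalImpression (per subject), EpisodeOfCare and Encounter (per
study-event occurrence), and — per the routing configuration —
QuestionnaireResponse answers or Observations for the item data.  A group
with a configured parent code becomes a single multi-component Observation
(the blood-pressure pattern), with designated context items attached as
body site, position component, performer and effective time.  Every datum
or constraint the target cannot carry lands in an append-only **loss
ledger** (`dropped-attribute`, `dropped-constraint`, `retyped`,
`repurposed-resource`), because this mapping is inherently lossy: answer
nodes cannot carry ODM range checks or significant digits, and CarePlan /
ClinicalImpression / EpisodeOfCare / Encounter are all used outside their
intended purpose.

**Native resources** (`odmfhir.study`).  `ClinicalStudyPlan` holds protocol
and registration metadata (title, official title, registration date,
authoring body, mandatory status, sponsors, contacts, sample size,
three-part goals) plus planned activities; `ClinicalStudyData` holds one
patient's captured data as events and visits, where each visit's
`investigations` is a choice of **exactly one** of: a single
QuestionnaireResponse reference, ≥1 Observation references, or ≥1
ImagingManifest references.  Built this way, clinical data needs no
repurposed resources at all — the native path's ledger contains zero
`repurposed-resource` entries.

**WHO registration coverage** (`odmfhir.who`).  The WHO's twenty mandatory
trial-registration items, with their static mapping onto ClinicalStudyPlan
attributes.  Structural mode reports what the resource *can* express
(items 4, 11, 14 — funding sources, countries of recruitment, eligibility
criteria — have no attribute; item 15, study type, is only implicit);
instance mode additionally requires each mapped attribute to be populated.

**Synthetic studies** (`odmfhir.synth`).  A seeded generator of
referentially intact ODM studies (all seven datatypes, code lists, range
checks, units, scheduled/unscheduled events) plus two fixed fixtures: the
blood-pressure worked example and a full-coverage study exercising every
mapping rule.

## Worked example

The classic illustration is a blood-pressure reading of 119/79 mmHg taken at
10:00 by a nurse from the left upper arm with the patient sitting.  As bare
ODM item data the context is invisible; converted with Observation routing
it becomes one coherent resource:

```python
from odmfhir import bp_fixture, map_study

study, cfg = bp_fixture()
result = map_study(study, cfg)
obs = result.bundle.by_type("Observation")[0]
for comp in obs.attrs["component"]:
    if "valueQuantity" in comp:
        print(comp["code"]["text"], comp["valueQuantity"])
print("effective:", obs.attrs["effectiveTime"])
print("body site:", obs.attrs["bodySite"]["text"])
print("performer:", obs.attrs["performer"][0]["reference"])
```

prints

```
Systolic blood pressure {'value': 119, 'unit': 'mmHg'}
Diastolic blood pressure {'value': 79, 'unit': 'mmHg'}
effective: 10:00:00
body site: Left upper arm structure
performer: Practitioner/practitioner-registered-nurse
```

— a single Observation coded as a LOINC blood-pressure panel whose two
components carry the pressures with SNOMED CT context attached, referencing
the Patient and the performing Practitioner.

## Command line

```bash
odmfhir generate --seed 1 --out study.xml --config-out map.yaml
odmfhir convert  --in study.xml --config map.yaml --out bundle.json --loss-report loss.json
odmfhir native   --in study.xml --protocol protocol.yaml --config map.yaml --out native.json
odmfhir who-check --in native.json --mode instance --out who.json
odmfhir validate --in bundle.json
odmfhir loss-report --in loss.json
```

Exit codes: 0 success, 1 hard error, 2 validation violations, 64 usage
error.  Every successful run writes a `<out>.manifest.json` recording
inputs, a config digest, outputs and summary counts; all outputs are
byte-deterministic for identical inputs.

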