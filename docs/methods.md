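# Methods

This note records the models, conventions and numerical choices behind
`odmfhir`, and what the synthetic studies do and do not establish about
real data.

## The ODM model and its pinning

The parser accepts CDISC ODM 1.3 only (namespace
`http://www.cdisc.org/ns/odm/v1.3`); any other namespace is rejected with an
explicit message rather than best-effort parsed, because the mapping's loss
accounting is only meaningful against a known source vocabulary.  For the
same reason the datatype vocabulary is closed over seven tokens (`text`,
`integer`, `float`, `date`, `time`, `datetime`, `boolean`) and an unknown
token is a hard error naming the offending ItemDef, not a passthrough.

Document order is preserved in every collection, so the round trip
`read ∘ write` is the identity on the in-memory model and
`write ∘ read ∘ write` is byte-idempotent.  Serialization stamps a fixed
`CreationDateTime` (epoch): output is content-addressed, never clocked.
SubjectKey and repeat keys are opaque text; no numeric interpretation is
attempted.  Elements outside the supported model (audit trails, vendor
extensions such as `Alias`) are preserved verbatim, whitespace-normalized,
as `extras` on the nearest typed node and surfaced downstream as
`dropped-attribute` ledger entries.  Unknown *attributes* are not preserved
— a known limitation.

A measurement unit is carried as the `MeasurementUnitOID` of a
`MeasurementUnitRef`, read back as plain text; full `BasicDefinitions`
support (and Admin/ReferenceData, signatures, Define-XML) is out of scope.

Value validation (`validate_item_value`) checks, in order: datatype parse,
declared length (digit count for numerics, character count for text),
significant digits (decimal places, float only), every range check, and
code-list membership.  Problems are returned as violation values carrying
the failed comparator and bound — validation never throws.  Range-check
bounds are held as `Decimal` so that printed bounds round-trip exactly.

## The FHIR layer

The eight legacy resource shapes are pinned to the STU3 snapshot of
September 2016 — the specification of that era changed shape between
releases, so the shape table is data (`data/fhir_shapes.yaml`, versioned
`STU3-2016-09`), not code.  The per-field `modifier`/`summary` flags on the
two study resources are recorded there as documentation metadata with no
runtime behaviour.

Resource attributes are plain JSON trees: the in-memory form *is* the wire
form.  This makes `parse(serialize(b)) == b` exact and serialization
injective on valid bundles; JSON is the only wire form (stable key order,
two-space indent) so equal bundles always produce identical bytes.
References are dicts carrying a `reference` key of the shape
`ResourceType/id`; bundle validation walks every resource for reference
dicts and reports one violation per dangling target with its attribute
path.  Resource ids are deterministic slugs of (resource type, source OID,
subject key, repeat key), which is what makes whole-bundle byte determinism
possible.

Validation rules per type: attribute names must belong to the pinned shape;
Questionnaire/QuestionnaireResponse group nodes may define subgroups or
questions but never both; an Observation carries at most one `value[x]` and
each component needs a code.

## The legacy mapping

Routing between the question-answer style (QuestionnaireResponse) and the
observation style (Observation) is genuinely study-specific — questionnaire
studies suit the former, longitudinal measurement studies the latter — and
no mechanism exists in ODM to express it.  The converter therefore takes an
explicit configuration: routing per item group with per-item overrides,
plus a code map, demographic-item designations and context-item
designations.  Config OIDs that do not resolve in the study metadata are a
hard error before any output.

Design choices worth recording:

* **Study title.**  CarePlan has no designated attribute for it; the title
  is carried in `description` plus an identifier, and the ledger flags the
  mapping as inferred.
* **Multi-component observations.**  Items of one observation-routed group
  sharing a configured parent code become components of a single
  Observation; otherwise each routed item becomes its own Observation.
  This mirrors how a blood-pressure panel is one observation with systolic
  and diastolic components, not two unrelated values.
* **Context items.**  Designated items attach to the group's Observation:
  body site and performer role as concepts (the performer also becomes a
  referenced Practitioner), position as an additional coded component,
  measurement time as the effective time.  A time-of-day-only value stays
  a `time` — it is not promoted to a fabricated full timestamp (a
  `retyped` ledger entry records this).
* **Visits.**  ODM has no visit element; the study-event repeat occurrence
  is the only observable proxy, so each repeat yields one EpisodeOfCare and
  one Encounter.
* **Demographics.**  ODM records no subject attributes; when the config
  designates gender/birth-date items they populate the Patient (an
  unparseable birth date leaves the field empty with a ledger entry), and
  a subject with no such items gets a "demographics unavailable" entry.
* **Range checks** become Observation reference ranges (GE/GT as low,
  LE/LT as high, original comparator retained); EQ/NE have no range form
  and are dropped with a ledger entry.  Answer nodes can carry no
  constraint at all, so range checks, significant digits and lengths on
  answer-routed items are always `dropped-constraint` entries.
* **Repurposing.**  One `repurposed-resource` entry per CarePlan and
  ClinicalImpression instance, and per EpisodeOfCare/Encounter pair — all
  four are used outside their intended purpose, and downstream consumers
  should see that semantic debt explicitly.

**Leaf conservation.**  Every ItemData leaf must end somewhere: the
converter records a disposition per leaf (answer, observation value,
observation component, observation context attachment, or dropped) and the
identity `leaves = answers + observation contributions + dropped-leaf
entries` is asserted across fixtures and seeded studies.  Context leaves
count in the observation bucket — they are carried on the Observation, not
lost.  A leaf whose value fails validation is excluded with a
`dropped-attribute` entry rather than emitted as a corrupt value.

## The native resources

`ClinicalStudyPlan` fields are optional at the model level so partial plans
can be *validated* rather than refused at construction; `validate_plan`
enforces the invariants (mandatory status, three-part goals, positive
sample size, each activity carrying detail items or a Questionnaire
reference).  ODM supplies none of the registration content, so the plan
builder takes a protocol-metadata mapping (YAML in the CLI) for title,
sponsor(s), dates, sample size and goals; a missing status is a hard
error.  The builder also needs the routing configuration — activity
`detail` entries derive from observation-routed groups — which is why it
accepts an optional config beyond (study, metadata).  An
`externalIdentifier` field is included (secondary identifying numbers);
whether an activity may carry both `actionResulting` and `detail` is
unspecified, and both are permitted here.  `publicContact` is modelled as
(name, telecom list), one reasonable reading of an unspecified type.

`ClinicalStudyData` events group a subject's occurrences by event
definition, one visit per occurrence (`planned` for scheduled events,
`unplanned` otherwise).  The investigations choice admits exactly one
QuestionnaireResponse reference per visit, so the native path builds a
single response spanning the visit's forms (one root group per form); a
visit mixing answer- and observation-routed leaves cannot satisfy the
choice and is a hard build error rather than an emitted violation.  Event
status vocabulary is fixed to {planned, in-progress, finished, cancelled};
status-history periods must be pairwise non-overlapping and closed except
possibly the last.  Because clinical values land directly in first-class
resources, the native ledger never contains a `repurposed-resource` entry —
verified by test.

## WHO coverage

The twenty-item checklist ships with its static attribute mapping.  Items
4, 11 and 14 map to nothing (funding sources and recruitment countries are
clinical-trial concerns outside this model; eligibility criteria await a
machine-processable representation); item 15 always reports partial, since
the resource only implies a study type.  Items 5 and 6 both map to
`sponsor`: instance mode counts the secondary-sponsor item satisfied only
with ≥2 sponsors, partial with exactly one.  Items 19 and 20 both map to
`goal` and are counted together on goal presence.  Structural mode is a
function of the checklist alone and is constant across plans; both modes
always partition {1..20}.

## Synthetic data

The generator targets *structural* realism — the full hierarchy, OID
cross-references, all seven datatypes, code lists on some text items, GE/LE
range checks with units on some numerics, scheduled/unscheduled events,
and a configurable fraction of item groups routed to Observation — not
epidemiological realism.  Defaults (3 subjects, 2 events, 2 forms/event,
2 groups/form, 3 items/group, 40 % observation routing, 20 % unscheduled
events, code lists and range checks on) give a compact study exercising
every conversion path; sweep tests use a 2×2×1×2×2 shape (16 leaves) so
fifty-seed sweeps stay sub-second.  One private `random.Random(seed)`
drives everything; no global state.  Generated values are always valid
against their definitions — invalid-value cases are constructed explicitly
in tests, never sampled — so conversion tests isolate routing and loss
accounting from value-validation noise.

Consequently, passing tests demonstrate correctness of the structural
transformation, referential closure, loss accounting and determinism; they
say nothing about the messiness of real exports (vendor extensions beyond
the opaque-element path, inconsistent value conventions, partial dates),
nor about terminology-binding quality, which is exactly as good as the
supplied code map.

The blood-pressure fixture is reconstructed from its prose description
(one subject, one visit, 119/79 mmHg, measured at 10:00 by a nurse, left
upper arm, sitting) with standard LOINC codes for the panel and components
and SNOMED CT codes for site, position and performer role; the original
XML listing is not available, so the reconstruction is synthetic by
construction and marked as such.

## Numerical and tie-break choices

Floats are `Decimal` end-to-end in ODM (exact round-trip of printed
values) and become JSON numbers (`float`) only at the FHIR boundary.
Duplicate OIDs within a collection are structural errors at parse time;
duplicate subject keys likewise.  Within a mapping run, practitioners are
deduplicated by role display; across subjects in a native bundle the first
copy wins.  Status-history entries are sorted by period start before the
overlap check; ISO dates without times are compared as midnight instants.

## Known limitations

* FHIR XML and RESTful behaviour are out of scope; JSON is the one wire
  form.
* Mapping back from FHIR to ODM is not attempted.
* Terminology lookups are local code maps only; no terminology server.
* ImagingManifest investigations are modelled and validated but no ODM
  routing produces them (ODM carries no imaging payloads here).
* The PlanDefinition/ActivityDefinition draft resources are not
  implemented; the checklist ships their column for documentation only.
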