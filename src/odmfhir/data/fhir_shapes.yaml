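# Resource shape table pinned to the FHIR "Standard for Trial Use 3" snapshot
# of September 2016.  Each entry lists the attributes the converter may place
# on a resource of that type; the validator flags anything else.  The two
# study resources additionally record per-field documentation flags:
# modifier ('?!') marks elements that change the interpretation of the
# resource, summary ('Σ') marks elements in the summary view.  The flags have
# no runtime behaviour.
version: "STU3-2016-09"
resources:
  CarePlan:
    attributes: [status, participant, support, context, category, description, activity]
  Patient:
    attributes: [gender, birthDate, careProvider]
  ClinicalImpression:
    attributes: [status, patient, plan, trigger, investigations, summary, assessor]
  EpisodeOfCare:
    attributes: [status, patient, period]
  Encounter:
    attributes: [status, episodeOfCare, patient, period, participant]
  Questionnaire:
    attributes: [version, publisher, status, group]
  QuestionnaireResponse:
    attributes: [status, questionnaire, subject, encounter, group]
  Observation:
    attributes: [status, code, subject, encounter, performer, bodySite,
                 effectiveTime, effectiveDateTime, interpretation, component,
                 referenceRange, valueQuantity, valueInteger, valueDecimal,
                 valueString, valueBoolean, valueDate, valueTime,
                 valueDateTime, valueCoding, valueCodeableConcept]
  ImagingManifest:
    attributes: [patient, study, description]
  ImagingStudy:
    attributes: [patient, description, series]
  Practitioner:
    attributes: [name, role]
  Organization:
    attributes: [name, type]
  Group:
    attributes: [name, type, member]
  ClinicalStudyPlan:
    attributes: [title, officialTitle, registrationDate, authoringBody,
                 status, sponsor, publicContact, investigator, description,
                 dateFirstEnrolment, sampleSize, goal, activity, note,
                 externalIdentifier]
    flags:
      status: {modifier: true, summary: true}
      identifier: {summary: true}
      title: {summary: true}
      officialTitle: {summary: true}
      registrationDate: {summary: true}
      sponsor: {summary: true}
      investigator: {summary: true}
      dateFirstEnrolment: {summary: true}
      sampleSize: {summary: true}
      goal: {summary: true}
      activity: {summary: true}
  ClinicalStudyData:
    attributes: [externalIdentifier, patient, plan, status, statusHistory,
                 period, event]
    flags:
      status: {modifier: true, summary: true}
      statusHistory: {modifier: true}
      patient: {summary: true}
      plan: {summary: true}
      period: {summary: true}
      event: {summary: true}
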