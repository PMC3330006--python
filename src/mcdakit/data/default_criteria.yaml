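# Default decision-criteria configuration: the 15-criterion MCDA matrix used
# for appraisal of a cervical-screening technology by a South African health
# plan committee, plus the funder's four contextual (qualitative) criteria.
# Q1 is excluded from quantitative appraisal, leaving 14 active criteria.
criteria:
  - id: D1
    name: Disease severity
    cluster: disease_impact
    anchors: [Not severe, Very severe]
  - id: D2
    name: Size of population affected by disease
    cluster: disease_impact
    anchors: [Very rare disease, Very common disease]
  - id: I1
    name: Clinical guidelines
    cluster: intervention
    anchors: [Not recommended, Strong recommendation]
  - id: I2
    name: Comparative interventions limitations
    cluster: intervention
    anchors: [No or very minor limitations, Major limitations]
  - id: I3
    name: Improvement of efficacy/effectiveness
    cluster: intervention
    anchors: [Lower than comparators, Major improvement]
  - id: I4
    name: Improvement of safety & tolerability
    cluster: intervention
    anchors: [Lower than comparators, Major improvement]
  - id: I5
    name: Improvement of patient reported outcomes
    cluster: intervention
    anchors: [Lower than comparators, Major improvement]
  - id: I6
    name: Public health interest
    cluster: intervention
    anchors: [No risk reduction, Major risk reduction]
  - id: I7
    name: Type of medical service
    cluster: intervention
    anchors: [Minor service, Major service (e.g. cure)]
  - id: E1
    name: Budget impact on health plan
    cluster: economics
    anchors: [Substantial additional spending, Substantial savings]
  - id: E2
    name: Cost-effectiveness of intervention
    cluster: economics
    anchors: [Not cost-effective, Highly cost-effective]
  - id: E3
    name: Impact on other spending
    cluster: economics
    anchors: [Substantial additional spending, Substantial savings]
  - id: Q1
    name: Adherence to requirements of decisionmaking body
    cluster: quality_of_evidence
    anchors: [Low adherence, High adherence]
  - id: Q2
    name: Completeness and consistency of reporting evidence
    cluster: quality_of_evidence
    anchors: [Many gaps/inconsistent, Complete & consistent]
  - id: Q3
    name: Relevance and validity of evidence
    cluster: quality_of_evidence
    anchors: [Low relevance/validity, High relevance/validity]
excluded_ids: [Q1]
contextual:
  - name: Impact on future decisions
    narrative: >-
      Funding coverage for a technology not considered cost-effective sets a
      precedent as the technology is expanded to other tests.
    impact: negative
  - name: Relationship with pathology providers
    narrative: >-
      Ongoing negotiations with pathology groups in other areas may be
      impacted.
    impact: positive
  - name: Impact on screening intervals
    narrative: >-
      Screening interval may be extended from annually to every 2 to 3 years.
    impact: positive
  - name: Patient expectation
    narrative: >-
      Plan members expect screening to be paid in full and are likely to
      resist any benefit design implementing a co-payment for a more
      expensive technology.
    impact: negative
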