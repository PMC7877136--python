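# The 26 derivation rules of the Complexity Index, one per reference
# checklist item 1a-6a.  Each rule is a declarative predicate over item
# positivity (as declared in the coding dictionary) and a few derived
# quantities (condition_count, medication_count, bmi, provider counts).
#
# Predicate node forms understood by the engine:
#   {item: ID}                      item positive per the coding dictionary
#   {any: [nodes]} / {all: [nodes]} three-valued OR / AND
#   {count_ge: {n: N, items: [..]}} at least N of the items positive
#   {quantity: {name: Q, ge: N}}    derived quantity threshold (ge or gt)
#
# uncertainty_positive: an UNCERTAIN code counts as positive (only the three
# rules whose wording includes "(or uncertainty about)").

rules:
  - rule_id: "1a"
    comid_label: "Several chronic diseases (more than 2) and/or unexplained symptoms"
    description: "More than 2 chronic diseases among a list of 13 (plus one counted for any response to 'other diagnoses')"
    items: [I1c, I1d, I1f, I1h, I1j, I1k, I1l, I1m, I1t, I1u, K1a, K1b, J3u, J4, I2]
    predicate: {quantity: {name: condition_count, gt: 2}}

  - rule_id: "1b"
    comid_label: "Chronic pain"
    description: "Any pain"
    items: [J6a]
    predicate: {item: J6a}

  - rule_id: "1c"
    comid_label: "Any allergies and/or drug intolerances"
    description: "A known drug allergy"
    items: [M2]
    predicate: {item: M2}

  - rule_id: "1d"
    comid_label: "Polymedication"
    description: "Five or more substances regularly taken"
    items: [M1f, M2f, M3f, M4f, M5f, M6f, M7f, M8f, M9f]
    predicate: {quantity: {name: medication_count, ge: 5}}

  - rule_id: "1e"
    comid_label: "Cognitive deficits"
    description: "Short-term memory problem and at least one other deficit (decision-making, procedural or long-term memory)"
    items: [C2a, C1, C2b, C2c]
    predicate:
      all:
        - {item: C2a}
        - any: [{item: C1}, {item: C2b}, {item: C2c}]

  - rule_id: "2a"
    comid_label: "Financial difficulties and/or inability to afford assistance, care, treatments, devices, transportation or food"
    description: "Financial difficulties"
    items: [Q4]
    predicate: {item: Q4}

  - rule_id: "2b"
    comid_label: "No informal care, an exhausted informal caregiver and/or family tensions"
    description: "No informal helper and no supportive family relationship, OR a helper unable to continue / distressed / overwhelmed"
    items: [P1a1, P1a2, P4, P2a, P2b, P2c]
    predicate:
      any:
        - all: [{item: P1a1}, {item: P1a2}, {item: P4}]
        - {item: P2a}
        - {item: P2b}
        - {item: P2c}

  - rule_id: "2c"
    comid_label: "Low level of literacy (alphabetization, language and/or cultural barriers)"
    description: "Understanding of others not good and clear"
    items: [D2]
    predicate: {item: D2}

  - rule_id: "2d"
    comid_label: "Social isolation"
    description: "Living alone and (no visits and no other interactions in last 3 days, or a decline in social activities)"
    items: [A13a, F1b, F1c, F3]
    predicate:
      all:
        - {item: A13a}
        - any:
            - all: [{item: F1b}, {item: F1c}]
            - {item: F3}

  - rule_id: "2e"
    comid_label: "Inadequate housing and/or environmental barriers"
    description: "Any problem with (or uncertainty about) degradation, squalid conditions or limited access to housing"
    items: [Q1a, Q1b, Q1e]
    uncertainty_positive: true
    predicate:
      any: [{item: Q1a}, {item: Q1b}, {item: Q1e}]

  - rule_id: "3a"
    comid_label: "Depression and/or suicidal ideation"
    description: "Depression diagnosis or self-reported depressed mood"
    items: [I1p, E2c]
    predicate:
      any: [{item: I1p}, {item: E2c}]

  - rule_id: "3b"
    comid_label: "Psychiatric diseases and/or mental disorders"
    description: "Abnormal thought process, delusions or hallucinations, or a diagnosis of psychosis or bipolar disorder"
    items: [J3g, J3h, J3i, I1q, I1o]
    predicate:
      any: [{item: J3g}, {item: J3h}, {item: J3i}, {item: I1q}, {item: I1o}]

  - rule_id: "3c"
    comid_label: "Addiction"
    description: "Daily smoking or at least 5 drinks of alcohol in one sitting"
    items: [J9a, J9b]
    predicate:
      any: [{item: J9a}, {item: J9b}]

  - rule_id: "3d"
    comid_label: "Anxiety or anguish rendering the clinical picture unclear"
    description: "Anxiety diagnosis or self-reported anxious mood"
    items: [I1n, E2b]
    predicate:
      any: [{item: I1n}, {item: E2b}]

  - rule_id: "3e"
    comid_label: "Variations in mental function during the day"
    description: "Mental function varies over the course of the day"
    items: [C3c]
    predicate: {item: C3c}

  - rule_id: "4a"
    comid_label: "Recurring solicitations of the primary and/or secondary network"
    description: "Repetitive anxious complaints"
    items: [E1e]
    predicate: {item: E1e}

  - rule_id: "4b"
    comid_label: "Ambivalent and/or conflictual communication with the network"
    description: "Conflict/anger with friends or family and a persistent anger against oneself or others"
    items: [F1d, E1b]
    predicate:
      all: [{item: F1d}, {item: E1b}]

  - rule_id: "4c"
    comid_label: "Worries about symptoms, health conditions and/or medical information"
    description: "Repetitive health complaints"
    items: [E1d]
    predicate: {item: E1d}

  - rule_id: "4d"
    comid_label: "Aggressiveness (verbal and/or physical) or mutism"
    description: "Any manifestation of verbal or physical aggressiveness"
    items: [E3b, E3c]
    predicate:
      any: [{item: E3b}, {item: E3c}]

  - rule_id: "4e"
    comid_label: "Resistance or opposition to care, active or passive"
    description: "Manifestation of resistance to care"
    items: [E3f]
    predicate: {item: E3f}

  - rule_id: "5a"
    comid_label: "Recent degradation of health status perceived by the patient"
    description: "Acute crisis or flare-up of a recurrent or chronic problem"
    items: [J7b]
    predicate: {item: J7b}

  - rule_id: "5b"
    comid_label: "Overall change in the degree of independence (ADL/IADL) in the last month"
    description: "Deterioration (or uncertainty) of ADL performance, or a significant change in general independence"
    items: [G6, R2]
    uncertainty_positive: true
    predicate:
      any: [{item: G6}, {item: R2}]

  - rule_id: "5c"
    comid_label: "Transition period (diagnosis announcement, hospital discharge, bereavement, ...)"
    description: "Major life stressor, hospitalization, or change in household composition"
    items: [F5, A14, A13b]
    predicate:
      any: [{item: F5}, {item: A14}, {item: A13b}]

  - rule_id: "5d"
    comid_label: "Acute change in cognitive abilities"
    description: "Deterioration (or uncertainty) of decision-making capacities in the last 3 months"
    items: [C5]
    uncertainty_positive: true
    predicate: {item: C5}

  - rule_id: "5e"
    comid_label: "Unpredictability of health status"
    description: "Conditions making status unstable, end-stage disease, acute change in mental state, or at least two emergency-room visits"
    items: [J7a, J7c, C4, N4b]
    predicate:
      any: [{item: J7a}, {item: J7c}, {item: C4}, {item: N4b}]

  - rule_id: "6a"
    comid_label: "Multiple care providers in the secondary network"
    description: "At least three providers"
    items: [N3aA, N3bA, N3cA, N3dA, N3eA, N3fA, N3gA, N3hA, O1]
    predicate:
      count_ge:
        n: 3
        items: [N3aA, N3bA, N3cA, N3dA, N3eA, N3fA, N3gA, N3hA, O1]
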