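# Catalogue of the 22 staging/diagnosis questions answered per report.
# answer_type: boolean | numeric | text.  stage: TNM category or null
# (questions 20-22 inform benign/malignant diagnosis, not staging).
schema_version: 1
questions:
  - id: 1
    text: "Is a primary tumor visible on imaging?"
    answer_type: boolean
    stage: "TX"
  - id: 2
    text: "Greatest dimension of the primary tumor (mm)?"
    answer_type: numeric
    stage: "T1-4"
  - id: 3
    text: "Does the tumor invade the lobar bronchus?"
    answer_type: boolean
    stage: "T1"
  - id: 4
    text: "Does the tumor invade the visceral pleura?"
    answer_type: boolean
    stage: "T2"
  - id: 5
    text: "Is there atelectasis or obstructive pneumonitis extending to the hilar region?"
    answer_type: boolean
    stage: "T2"
  - id: 6
    text: "Are there separate tumor nodules in the same lobe as the primary?"
    answer_type: boolean
    stage: "T3"
  - id: 7
    text: "Does the tumor invade the great vessels?"
    answer_type: boolean
    stage: "T4"
  - id: 8
    text: "Does the tumor invade a vertebral body?"
    answer_type: boolean
    stage: "T4"
  - id: 9
    text: "Are there separate tumor nodules in a different ipsilateral lobe?"
    answer_type: boolean
    stage: "T4"
  - id: 10
    text: "Is there regional lymph node metastasis?"
    answer_type: boolean
    stage: "N0"
  - id: 11
    text: "Is there metastasis in ipsilateral hilar lymph nodes?"
    answer_type: boolean
    stage: "N1"
  - id: 12
    text: "Is there metastasis in ipsilateral mediastinal lymph nodes?"
    answer_type: boolean
    stage: "N2"
  - id: 13
    text: "Is there metastasis in subcarinal lymph nodes?"
    answer_type: boolean
    stage: "N2"
  - id: 14
    text: "Is there metastasis in contralateral mediastinal lymph nodes?"
    answer_type: boolean
    stage: "N3"
  - id: 15
    text: "Is there metastasis in contralateral hilar lymph nodes?"
    answer_type: boolean
    stage: "N3"
  - id: 16
    text: "Is there metastasis in supraclavicular lymph nodes?"
    answer_type: boolean
    stage: "N3"
  - id: 17
    text: "Are there separate tumor nodules in a contralateral lobe?"
    answer_type: boolean
    stage: "M1a"
  - id: 18
    text: "Are there pleural nodules?"
    answer_type: boolean
    stage: "M1a"
  - id: 19
    text: "Is there malignant pleural or pericardial effusion?"
    answer_type: boolean
    stage: "M1a"
  - id: 20
    text: "What is the shape of the tumor?"
    answer_type: text
    stage: null
  - id: 21
    text: "What is the density of the tumor?"
    answer_type: text
    stage: null
  - id: 22
    text: "What is the enhancement extent of the tumor?"
    answer_type: text
    stage: null
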