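# Sex/gender search terms (with automatic plural expansion), the fields they
# are searched in, and a sex-class per term used to decide whether a
# recruitment statement covers both sexes.
terms:
  - surface: sex
    plural: true
    sex_class: neutral
  - surface: gender
    plural: true
    sex_class: neutral
  - surface: woman
    plural: true
    sex_class: female
  - surface: female
    plural: true
    sex_class: female
  - surface: man
    plural: true
    sex_class: male
  - surface: male
    plural: true
    sex_class: male
  - surface: girl
    plural: true
    sex_class: female
  - surface: boy
    plural: true
    sex_class: male
  - surface: pregnan*
    wildcard: true
    sex_class: female
  - surface: transg*
    wildcard: true
    sex_class: neutral
scope:
  - OfficialTitle
  - BriefTitle
  - BriefSummary
  - DetailedDescription
  - EligibilityPopulation
  - EligibilityGenderDescription
  - EligibilityCriteria
  - GroupTitle
  - GroupDescription
  - InterventionDescription
  - PrimaryOutcomeTitle
  - PrimaryOutcomeDescription
  - SecondaryOutcomeTitle
  - SecondaryOutcomeDescription
  - OtherOutcomeTitle
  - OtherOutcomeDescription
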