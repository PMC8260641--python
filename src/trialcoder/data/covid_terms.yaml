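# COVID-19 search terms and the registration fields they are searched in.
# Matching is case-insensitive and blind to hyphen/space use inside a term.
terms:
  - surface: Coronavirus
  - surface: Corona Virus
  - surface: SARS-CoV-2
  - surface: SARS CoV2
  - surface: SARSCoV2
  - surface: COVID
  - surface: 2019 nCov
  - surface: 2019nCoV
scope:
  - OfficialTitle
  - BriefTitle
  - BriefSummary
  - DetailedDescription
  - Conditions
  - PrimaryOutcomeTitle
  - PrimaryOutcomeDescription
  - SecondaryOutcomeTitle
  - SecondaryOutcomeDescription
  - OtherOutcomeTitle
  - OtherOutcomeDescription
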