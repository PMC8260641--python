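# Rule bank for coding the context around each sex/gender term occurrence.
#
# Each rule carries cue terms evaluated inside the context window (the
# sentence containing the match, clamped to +/-120 characters). Negative
# (spurious) rules are evaluated before positive ones: a window holding a
# spurious cue contributes no positive evidence.
rules:
  # --- spurious contexts: mentions with no design meaning ---------------
  - id: spurious.contraception
    kind: spurious
    cues:
      - {surface: "contracept*", wildcard: true}
      - {surface: condom, plural: true}
  - id: spurious.pregnancy_test
    kind: spurious
    cues:
      - {surface: "pregnancy test", plural: true}
  - id: spurious.donor
    kind: spurious
    cues:
      - {surface: "donor*", wildcard: true}
  - id: spurious.parent
    kind: spurious
    cues:
      - {surface: "parent*", wildcard: true}
  - id: spurious.literature
    kind: spurious
    cues:
      - {surface: "previous studies"}
      - {surface: "prior studies"}
      - {surface: "has been shown"}
      - {surface: "have shown"}
      - {surface: "it is known"}
      - {surface: "recent reports"}
      - {surface: "literature"}

  # --- analysis criterion: planned use of sex/gender in the analysis ----
  - id: analysis.stratified
    kind: analysis
    cues:
      - {surface: "stratif*", wildcard: true}
  - id: analysis.subgroup
    kind: analysis
    cues:
      - {surface: "sub group*", wildcard: true}
  - id: analysis.covariate
    kind: analysis
    cues:
      - {surface: "covariat*", wildcard: true}
  - id: analysis.interaction
    kind: analysis
    cues:
      - {surface: "interaction*", wildcard: true}
  - id: analysis.adjusted
    kind: analysis
    cues:
      - {surface: "adjust*", wildcard: true}
  - id: analysis.disaggregated
    kind: analysis
    cues:
      - {surface: "disaggregat*", wildcard: true}
  - id: analysis.hypothesis
    kind: analysis
    cues:
      - {surface: "hypothes*", wildcard: true}

  # --- other mentions: matching/representation or record/report intent --
  - id: other.matched
    kind: other_mention
    subtag: MatchedOrRepresentative
    cues:
      - {surface: "match*", wildcard: true}
  - id: other.representative
    kind: other_mention
    subtag: MatchedOrRepresentative
    cues:
      - {surface: "representativ*", wildcard: true}
  - id: other.balanced
    kind: other_mention
    subtag: MatchedOrRepresentative
    cues:
      - {surface: "balanc*", wildcard: true}
  - id: other.record
    kind: other_mention
    subtag: RecordOrReport
    cues:
      - {surface: "record*", wildcard: true}
  - id: other.report
    kind: other_mention
    subtag: RecordOrReport
    cues:
      - {surface: "report*", wildcard: true}

  # --- recruitment statements -------------------------------------------
  - id: recruitment.eligible
    kind: recruitment
    cues:
      - {surface: "eligib*", wildcard: true}
  - id: recruitment.inclusion
    kind: recruitment
    cues:
      - {surface: "inclusion", plural: true}
  - id: recruitment.enrol
    kind: recruitment
    cues:
      - {surface: "enrol*", wildcard: true}
  - id: recruitment.recruit
    kind: recruitment
    cues:
      - {surface: "recruit*", wildcard: true}
  - id: recruitment.aged
    kind: recruitment
    cues:
      - {surface: "aged"}
      - {surface: "years of age"}
      - {surface: "years old"}
  - id: recruitment.both_sexes_phrase
    kind: recruitment
    cues:
      - {surface: "men and women"}
      - {surface: "women and men"}
      - {surface: "male and female", plural: true}
      - {surface: "female and male", plural: true}
      - {surface: "male or female", plural: true}
      - {surface: "female or male", plural: true}
      - {surface: "both sexes"}
      - {surface: "both genders"}
      - {surface: "either sex"}
      - {surface: "all sexes"}
      - {surface: "all genders"}
      - {surface: "any sex"}
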