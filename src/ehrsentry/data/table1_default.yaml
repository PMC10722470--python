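# Default computational-phenotype history: quarterly keyword/ICD-10-CM
# additions for human-trafficking risk surveillance, 2019Q3 through 2021Q2.
#
# Notes on transcription choices:
#   * Each quarter's entries take effect on the quarter's first day; the one
#     mid-quarter dated addition (Z91.41, 2019-07-22) is its own version.
#   * "Rapped (sp)" is a deliberate-misspelling trap; "(sp)" is an
#     annotation, so the stored keyword is "rapped".
#   * Z91.42 is listed four times in the source material; duplicates
#     collapse on assembly and are counted.
#   * The 2020Q1 male-specific list adds male-scoped anatomy terms and
#     subtracts phrases that are nonspecific for males; "black eye" is the
#     printed exemplar of those phrases, so it is carried here as a general
#     keyword narrowed away from the male scope in the same version.
#   * Codes default to prefix matching so a pattern like T74.21 also fires
#     on extended recorded codes such as T74.21XA.
versions:
  - id: 2019Q3
    effective_from: 2019-07-01
    add_keywords:
      - abdominal
      - abuse
      - abusive
      - anorexia
      - assault
      - contusion
      - dehydration
      - exploitation
      - malnutrition
      - maltreatment
      - neglect
      - trauma
    add_codes:
      - {code: "O9A.4", description: "Sexual abuse complicating pregnancy, childbirth, and the puerperium"}
      - {code: "T74.21", description: "Adult sexual abuse, confirmed"}
      - {code: "T74.22", description: "Child sexual abuse, confirmed"}
      - {code: "T74.51", description: "Adult forced sexual exploitation, confirmed"}
      - {code: "T74.52", description: "Child sexual exploitation, confirmed"}
      - {code: "T74.61", description: "Adult forced labor exploitation, confirmed"}
      - {code: "T74.62", description: "Child forced labor exploitation, confirmed"}
      - {code: "T76.12", description: "Current child sexual abuse"}
      - {code: "T76.21", description: "Adult sexual abuse, suspected"}
      - {code: "T76.21 XA", description: "Adult sexual abuse, suspected, initial encounter"}
      - {code: "T76.22", description: "Child sexual abuse, suspected"}
      - {code: "T76.51", description: "Adult forced sexual exploitation, suspected"}
      - {code: "T76.52", description: "Child sexual exploitation, suspected"}
      - {code: "T76.61", description: "Adult forced labor exploitation, suspected"}
      - {code: "T76.62", description: "Child forced labor exploitation, suspected"}
      - {code: "Y07.6", description: "Multiple perpetrators of maltreatment and neglect"}
      - {code: "Z04.81", description: "Encounter for examination and observation of victim following forced sexual exploitation"}
      - {code: "Z04.82", description: "Encounter for examination and observation of victim following forced labor exploitation"}
      - {code: "Z62.81", description: "Personal history of physical and sexual abuse in childhood"}
      - {code: "Z62.813", description: "Personal history of forced labor or sexual exploitation in childhood"}
      - {code: "Z91.4", description: "Personal history of psychological trauma, not elsewhere classified"}
      - {code: "Z91.411", description: "Personal history of adult psychological abuse"}
      - {code: "Z91.412", description: "Personal history of adult neglect"}
      - {code: "Z91.419", description: "Personal history of unspecified adult abuse"}
      - {code: "Z91.42", description: "Personal history of forced labor or sexual exploitation"}
      - {code: "Z91.42", description: "Personal history of forced labor or sexual exploitation"}
      - {code: "Z91.42", description: "Personal history of forced labor or sexual exploitation"}
      - {code: "Z91.42", description: "Personal history of forced labor or sexual exploitation"}

  - id: 2019Q3-late
    effective_from: 2019-07-22
    add_codes:
      - {code: "Z91.41", description: "Personal history of adult abuse"}

  - id: 2019Q4
    effective_from: 2019-10-01
    add_keywords:
      - adult abuse
      - aids
      - anal
      - anus
      - cws
      - dysuria
      - farm worker
      - field worker
      - force%
      - forced labor
      - gonorrhea
      - herpe%
      - hiv
      - laborer
      - migrant
      - neglect
      - physical abuse
      - physical and sexual abuse
      - psych%
      - psychological abuse
      - psychological trauma
      - rectum
      - run away
      - runaway
      - sex%
      - sexual abuse
      - suicid%
      - syphilis
      - traffic%
      - trans-sexual
      - transgender
      - transsexual
      - transvestite
      - troubled teen
      - urinary tract
      - vagin%
      - violence

  - id: 2020Q1
    effective_from: 2020-01-01
    add_keywords:
      - pelvic
      - perineal
      - perineum
      - ptsd
      - stress disorder
      - transgender
      - transsexual
      - trans-sexual
      - transvestite
      - black eye
      - {pattern: penis, sex_scope: male_only, source_tag: 2020Q1-male}
      - {pattern: testic%, sex_scope: male_only, source_tag: 2020Q1-male}
    remove_keywords:
      - {pattern: black eye, sex_scope: male_only}

  - id: 2020Q2
    effective_from: 2020-04-01
    add_keywords:
      - rape
      - raped
      - rapped
      - molestation
      - molested

  - id: 2020Q4
    effective_from: 2020-10-01
    add_keywords:
      - pushed by
      - struck by husband
      - struck by wife
      - struck by spouse
      - struck by boyfriend
      - struck by girlfriend
      - struck by significant other
      - struck by so

  - id: 2021Q2
    effective_from: 2021-04-01
    add_keywords:
      - safe house
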