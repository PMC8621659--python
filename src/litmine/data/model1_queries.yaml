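# Default PubMed query clauses for the optional E-utilities fetcher.
# Each clause is issued as a separate esearch; results are unioned by PMID.
queries:
  - "(maternal* OR paternal*) AND (weight OR obes* OR nutrition OR diet* OR stress OR social support) AND (child OR infant) AND (programming AND development)"
  - "mother-child relation* AND programming"
  - "child* AND development AND programming AND (stress OR depression OR anxiety OR sensitivity OR temperament) AND mental health"
  - "parent-child relation* AND programming"
  - "programming AND *natal"
  - "development* AND origins AND programming"
  - "development* origins of health and disease"
  - "(maternal* OR paternal*) AND (gene* OR immune* OR metabol* OR inflam* OR brain OR neuro* OR cardio* respiratory) AND (development OR growth OR programming) AND (child OR infant)"
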