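# Query codes indicative of sleep problems, plus childhood-adversity labels.
# Codes ending in ".x" match every vocabulary token with that prefix.
sleep_terms:
  - [Nonorganic sleep disorders, F51.x, diagnosis]
  - [Organic sleep disorders, G47.x, diagnosis]
  - [Melatonin receptor agonists, N05CH, medication]
  - [Melatonin, N05CH01, medication]
  - [Benzodiazepine-related drugs, N05CF, medication]
  - [Phenothiazine derivatives, R06AD, medication]
  - [Promethazine, R06AD02, medication]
adversity_terms:
  - poverty
  - parental_unemployment
  - parental_death
  - sibling_death
  - parental_severe_disease
  - parental_divorce
  - foster_care
  - sibling_psychiatric_illness
  - parental_psychiatric_illness
  - parental_alcohol_abuse
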