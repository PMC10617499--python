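schema_version: 1
format: "comma-separated long-format family table, one row per person; missing values are empty fields"
columns:
  family_id: "extended-family identifier (two linked nuclear units)"
  nuclear_id: "nuclear unit within the family: 1 or 2"
  role: "mother | child"
  person_id: "unique person identifier"
  mother_id: "person_id of the child's mother (empty for mothers)"
  adult_rel: "relationship of the two mothers: MZ | DZ | FULL_SIB | MAT_HALF_SIB | PAT_HALF_SIB | COUSIN | SINGLETON"
  sex: "0 = female, 1 = male"
  birth_year: "calendar year of birth (child) or of first recorded birth (mother)"
  maternal_age: "mother's age in years at the child's birth"
  parity: "mother's number of previous births"
  adhd_adult: "maternal adult ADHD symptom score (6-item self-report screener, reported at child age 3)"
  adhd_age5: "child ADHD symptom score at age 5 (12-item parent rating)"
  adhd_age8: "child ADHD symptom score at age 8 (18-item disruptive-behaviour rating)"
  odd_age8: "child oppositional defiant disorder score at age 8 (8 items)"
  conduct_age8: "child conduct disorder score at age 8 (8 items)"
  anxiety_age8: "child anxiety score at age 8 (5-item screener)"
  depression_age8: "child depression score at age 8 (13-item mood questionnaire)"
derived_columns:
  "<measure>_resid": "ordinary-least-squares residual of the measure on maternal age, parity, birth year (and child sex for child measures)"
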