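# data/

Drop-in location for the original cohort's deposited tables, which are
not redistributed with this package. When present, the acceptance tests
re-run the full pipeline on them and check the published numbers; when
absent, those tests fail with a message naming the missing file.

Expected files (CSV, UTF-8, comma-delimited — export the deposited
spreadsheets verbatim):

- `exp1_expression.csv` — pCREB expression cohort, long layout:
  `subject, group, region, value` with groups `SHAM` / `dHPC` and region
  abbreviations matching the packaged catalogue (case-insensitive).
- `exp1_behavior.csv` — memory-test cohort: `subject, group, freezing`
  with groups `SHAM` / `dHPC` / `Imm`.
- `exp3_behavior.csv` — double-lesion cohort: `subject, group, freezing`
  with groups `SHAM` / `dHPC` / `RSC` / `dHPC-RSC`.
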