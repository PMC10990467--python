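# verbagg

Analysis pipeline for studying how exposure to different kinds of verbally
aggressive language at work relates to depressive symptoms and sleep
disturbance in a two-wave worker cohort.

The package provides:

- **`verbagg.lexicon`** — multi-label classification of free-text aggressive
  utterances into three explicit categories (`job_performance`,
  `personality_looks`, `life_threat`) plus a residual `other` class.
  Matching is case-insensitive substring/regex on the NFKC-normalized
  utterance, so multi-word patterns work. Lexicons, lemma maps and
  conjugation-grouped word-frequency tables (for word clouds) are all
  file-configurable; the built-in default lexicon is illustrative only.
- **`verbagg.scoring`** — CES-D scoring (20 items, standard reverse-keyed
  items, caseness at total ≥ 16), PSQI scoring (7 components, poor sleep at
  global ≥ 6) and dichotomization of the five-level exposure frequency item
  ("never" vs anything else).
- **`verbagg.effects`** — 2×2 exposure-by-outcome tables, crude odds ratios
  with Woolf 95% confidence intervals and two-sided Wald p-values, optional
  Haldane–Anscombe zero-cell correction (off by default), and a battery that
  estimates every exposure definition (overall + four categories) against
  both outcomes.
- **`verbagg.logistic`** — from-scratch Newton/IRLS logistic regression with
  step-halving, rank-deficiency and separation diagnostics, and
  covariate-adjusted odds ratios (sex, age class, job class, night shift,
  marital status, baseline instrument score).
- **`verbagg.simulate`** — a seeded synthetic two-wave cohort generator
  (covariate margins, truncated-normal baseline scores, Bernoulli exposure
  with an optional baseline-score confounding hook, independent multi-label
  aggression types with lexicon-consistent utterance text, attrition, and
  logistic wave-2 outcomes) plus hidden truth bookkeeping for oracle tests.
- **`verbagg.pipeline` / `verbagg.cli`** — end-to-end orchestration and a
  `verbagg` command line tool.

## Command line

```sh
# generate a synthetic cohort (reproducible under --seed)
verbagg simulate --seed 7 --out cohort.csv --truth-out truth.tsv

# classify free-text utterances (participant_id,text,perpetrator CSV)
verbagg classify --utterances utterances.csv --out flags.csv

# crude + adjusted odds ratios for every exposure definition and outcome
verbagg analyze --cohort cohort.csv --out estimates.csv --zero-cell-correction

# full report bundle: demographics, flag counts, effect table,
# per-category word-frequency TSVs, machine-readable run log
verbagg report --cohort cohort.csv --out reports/ --zero-cell-correction

# check a lexicon file (YAML or TSV) for structural/regex errors
verbagg validate-lexicon --lexicon lexicon.yaml
```

Custom lexicons are YAML (`categories: {name: [{pattern, type}]}`) or TSV
(`category  pattern  pattern_type`), with an optional two-column
`surface → lemma` TSV for conjugation grouping.

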