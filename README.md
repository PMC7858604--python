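# shiftmethyl

Paired vacation-effect methylome analysis: a tested, reusable pipeline for
paired EWAS cohorts (two samples per subject — a working period and a
vacation measurement — in an SWD group and a control group), together with
a synthetic 450K-style cohort simulator so every stage can be exercised
end-to-end without any external data.

## What it does

* **`shiftmethyl.synthetic`** — generates paired cohorts (sample sheet,
  M-value matrix, probe annotation, GMT gene-set library) with planted
  vacation effects, covariate structure, per-subject recovery degrees
  linked to questionnaire answers, and a ground-truth record for every
  planted coefficient. All randomness flows from one root seed through
  named `SeedSequence` sub-streams; identical seeds give byte-identical
  fixture files.
* **`shiftmethyl.ewas`** — fits, per probe, an OLS model with
  group-specific intercepts and group-specific vacation effects plus
  nuisance covariates (age, sex, plate, alcohol, smoking), and tests four
  null hypotheses by nested-model F tests: no effect in the SWD group, no
  effect in controls, no effect in either group (joint 2-df test), and the
  union null "no effect in at least one group" via the intersection–union
  `max(p_swd, p_ctrl)` construction. Benjamini–Hochberg q-values are
  computed per hypothesis family; each probe is labelled
  `hypo_at_work` / `hyper_at_work` by the sign of its vacation-minus-work
  coefficient (positive = methylation gained on vacation = hypomethylated
  during work).
* **`shiftmethyl.pathways`** — gene ranking by best probe p-value,
  hypergeometric over-representation against a user-supplied GMT library
  with a methylation-aware background, pathway CpG universes, and the two
  pathway scores: DMP enrichment score (`100 × n_DMPs / n_CpGs`) and
  hypomethylation score (`100 × n_hypo_DMPs / n_DMPs`).
* **`shiftmethyl.recovery`** — symptom change scores
  (`(A+B)_work − (A+B)_vacation`), per-subject methylation changes
  (`M_work − M_vacation`), Spearman correlation between the two (exact
  permutation p below n=10, t approximation otherwise), recovery-group
  assignment (tertiles or explicit cutpoints), work-period one-way ANOVA,
  and a t-SNE embedding of global profiles.
* **`shiftmethyl.io` / `shiftmethyl.pipeline` / `shiftmethyl.cli`** —
  TSV/CSV/GMT/JSON readers and writers with validation, a YAML-configured
  end-to-end driver, and a `shiftmethyl` command with subcommands
  `simulate`, `ewas`, `pathways`, `recovery`, `embed`, `run`.

A small worked-example dataset (38 pathway DMPs with direction labels,
ANOVA and recovery-correlation statistics) ships in
`shiftmethyl.datasets` and is used by the worked-example tests.

### Reporting conventions

Headline EWAS percentages at one decimal are *truncated* (28,419/433,479
reports as 6.5%), matching the convention of the reference results, while
integer percentages and the pathway scores round half-up (38/458 → 8.3%,
28/38 → 74%). Both helpers are exported (`ewas.percent_one_decimal`,
`ewas.percent_integer`, `pathways.score_one_decimal`,
`pathways.score_integer`).

The model is deliberately plain OLS with iid errors and *no* subject-level
pairing term; the simulator's `subject_intercept_sd` knob exists to
quantify the consequence of that assumption.

## CLI

```bash
# simulate a paired cohort with ground truth
shiftmethyl simulate --outdir data --seed 1

# per-probe four-hypothesis scan
shiftmethyl ewas --matrix data/matrix.tsv --samples data/samples.csv \
    --covariates age,sex,plate,alcohol,smoking --alpha 0.05 \
    --out ewas.tsv --summary-json summary.json

# gene-set enrichment + pathway DMP scores
shiftmethyl pathways --ewas ewas.tsv --gmt data/library.gmt \
    --annotation data/annotation.tsv --group swd --top 30 --pcut 1e-5 \
    --out enrichment.tsv --scores-out pathway_scores.tsv

# recovery correlations (SWD group), t-SNE embedding, full pipeline
shiftmethyl recovery --matrix data/matrix.tsv --samples data/samples.csv --out recovery.tsv
shiftmethyl embed --matrix data/matrix.tsv --samples data/samples.csv \
    --perplexity 10 --iterations 10000 --seed 1 --out embedding.tsv
shiftmethyl run --config config.yaml
```

A pipeline YAML holds either a simulation block (`cohort`, `effects`,
`library`) or input paths (`matrix_path`, `samples_path`,
`annotation_path`, `gmt_path`), plus `covariates`, `alpha`, top-gene and
embedding parameters, `seed`, and `outdir`; see
`tests/test_pipeline_cli.py` for a complete example.

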