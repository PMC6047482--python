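# bwsurvey

Analysis pipeline for a blocked outcome-prioritization survey. Respondents
rank seven benefit-side items outright, and — assigned by birth month to one
of 12 sets of 7 drawn from 21 harm items — rank the harms of their set.
The package provides:

- **outcome catalog & response I/O** (`bwsurvey.catalog`): CSV schemas for
  the item catalog and one-row-per-respondent response tables, with strict
  ranking validation (partial rankings allowed, duplicates and
  out-of-range ranks rejected).
- **block design** (`bwsurvey.design`): seeded construction of
  equal-frequency incomplete block designs (each of 21 harms in exactly 4
  of 12 blocks of 7) by simulated annealing on pairwise co-occurrence
  variance, with a provable lower bound used as the stopping criterion,
  plus the birth-month → set assignment rule.
- **synthetic respondents** (`bwsurvey.simulate`): Plackett–Luce rankings
  from latent utilities (Gumbel-max sampling), demographics, and four
  independent item-nonresponse channels.
- **inclusion filters** (`bwsurvey.filters`): the fixed cascade
  condition → demographics → ranking completeness, with full
  participant-flow accounting and arithmetic invariants.
- **scoring** (`bwsurvey.scoring`): per-item median/IQR benefit summaries;
  best-worst scaling scores `P(ranked 1) − P(ranked 7)` per set, averaged
  across the sets containing each item; benefit-vs-harm trade-off tally;
  per-set group-balance table.
- **recovery diagnostics** (`bwsurvey.recovery`): seeded
  simulate → filter → score experiments measuring Kendall tau between the
  recovered ordering and the true utility ordering.

## CLI

Every stage is independently invocable; `run` wires them end to end.

```sh
bwsurvey design --items 21 --blocks 12 --block-size 7 --seed 1 --out design.csv
bwsurvey simulate --design design.csv --n 746 --seed 1 --out responses.csv
bwsurvey filter --in responses.csv --invited 4130 --design design.csv \
    --out-flow flow.csv --out-benefit benefit_cohort.csv --out-harm harm_cohort.csv
bwsurvey score benefits --in benefit_cohort.csv --out benefits_summary.csv
bwsurvey score harms --in harm_cohort.csv --design design.csv \
    --out bws.csv --out-by-set bws_by_set.csv
bwsurvey score tradeoff --in responses.csv --out tradeoff.csv
bwsurvey score balance --in harm_cohort.csv --design design.csv --out balance.csv
bwsurvey diagnose recovery --design design.csv --ns 480,1200,4800 --reps 100 \
    --seed 1 --out recovery.csv
bwsurvey run --config pipeline.yaml --out-dir out/
```

A pipeline config is a single YAML file; any value can be overridden by a
CLI flag:

```yaml
mode: simulate        # or: ingest (+ responses_path)
seed: 1
n: 746
invited: 4130
design: {n_items: 21, n_blocks: 12, block_size: 7}
model:
  utilities: {pain_relief: 2.5}   # unlisted items default to 0
  demographics: {proportion_female: 0.92, age_median: 52, age_iqr: 8}
  missingness: {p_missing_demographics: 0.05, p_incomplete_benefits: 0.14,
                p_incomplete_harms: 0.15, p_non_tmj: 0.25}
```

`run` writes the design, responses, flow counts, both cohorts, all score
tables and `report.md` into the output directory; outputs are byte-identical
for a fixed config (provenance headers carry version, seed and input
digests, never timestamps).

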