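# semloss

Tools for quantifying semantic storage loss from a four-task naming battery:
spontaneous naming (max 64), cued naming, word-picture matching (WPMT), and
the MMSE (max 30). The semantic storage loss (SSL) score is the unweighted
mean of three components, each in [0, 1]:

1. **cue retrieval** — proportion of items missed in spontaneous naming that
   were retrieved with a phonemic cue;
2. **consistency** — proportion of items missed in spontaneous naming that
   were recognized in WPMT;
3. **naming/general ratio** — naming proportion divided by the sum of naming
   and MMSE proportions.

Scores near 0 indicate severe semantic storage loss; near 1, preserved
storage with impairment attributable to general cognition. The package also
provides normative screening rules (mean − 2 SD cut-offs), cohort validation
statistics (one-way ANOVA with Scheffé post hoc, Pearson correlations,
hierarchical regression with an R²-change F test), a synthetic cohort
simulator with group-specific deficit profiles and coupled ROI uptake
ratios, and an embedded 28-participant reference cohort.

## Library quick start

```python
import semloss as sl

# score one participant from aggregate counts
rec = sl.ParticipantRecord(participant_id="MR", naming_correct=51,
                           cued_correct=61, wpmt_correct=63, mmse=19)
comp = sl.ssl_score(rec)
print(comp.ssl, comp.ssl_display)   # 0.7498... 0.75

# score the embedded reference cohort and summarize by group
fixture = sl.load_fixture()
scored = sl.score_cohort(fixture.records)
print(sl.group_summary(fixture.frame.ssl_printed, fixture.frame.group_label))

# simulate a synthetic cohort, bit-reproducible under the seed
cohort = sl.simulate_cohort([(p, 100) for p in sl.default_profiles()], seed=1)
```

Item-level scoring (`ItemOutcomes`, `mode="item_level"`) is canonical when
per-item data exist; aggregate scoring reconstructs the consistency
component under the assumption that every spontaneously named item was also
recognized, and is flagged `aggregate-mode`.

## CLI

Installed as `semloss`:

```sh
semloss score --fixture                        # scored CSV on stdout
semloss score --input cohort.csv --out scores.csv
semloss screen --input cohort.csv              # eligibility with reason codes
semloss summarize --fixture --var ssl_printed  # group means, ANOVA, Scheffé
semloss simulate --n 100,100,100 --seed 1 --out simdir/
semloss correlate --input simdir/cohort_aggregate.csv --scores ssl,c_ratio
```

Input is comma-delimited UTF-8 CSV. Aggregate schema:
`participant_id, naming_correct, cued_correct, wpmt_correct, mmse` plus
optional `group_label, moca, cct_picture, atl_left, atl_right, dlpfc_left,
dlpfc_right`. Item-level schema (long format): `participant_id, item_index,
category, named_spontaneously, named_with_cue, recognized_in_wpmt, mmse`.
Screening thresholds can be overridden with `--config` (INI-style
`[screening]` section).

## Notes

- Two reference rows (DL, WB) do not reproduce their published SSL from
  their published task counts; they are retained verbatim and flagged
  `reproducible=False`.
- Display rounding is 2 decimals, half away from zero; all statistics run on
  unrounded values unless explicitly pointed at the published column.
- The scores are not diagnostic on their own and cover concrete-object
  naming only.
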