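# File formats

All files are plain CSV with a header row; timestamps are seconds from
session start; landmark indices follow the 1-based 68-point facial
annotation convention (jawline 1–17, brows 18–27, nose 28–36, eyes 37–48,
mouth 49–68).  Readers validate headers and log row-level problems.

## frames.csv

One row per video frame.

| column | unit | notes |
|---|---|---|
| `timestamp_s` | s | strictly increasing |
| `happiness_pct`, `surprise_pct`, `sadness_pct`, `anger_pct`, `fear_pct`, `disgust_pct` | % | non-negative; sum ≤ 100 |
| `neutral_pct` | % | optional seventh channel |
| `attention` | bool | `true`/`false`, `1`/`0`, or blank (missing) |

Rows with missing emotion values or a missing attention flag are removed
by cleaning.  Derived `valence`/`engagement` columns are computed in
memory, never stored.

## landmarks.csv

`timestamp_s, x1, y1, x2, y2, …, x68, y68` — pixel coordinates.  A reader
for 0-based landmark sources must re-index to this convention first.

## gaze.csv

`timestamp_s, gaze_x_cm, gaze_y_cm, available` — screen coordinates in cm
with the origin at the top-left corner.  Only the x coordinate is used by
the attention rule; `available = false` marks frames without a gaze
prediction.

## schedule.csv

One row per pairwise comparison:
`comparison_index, sound_first, sound_second, t_start_first, t_end_first,
t_start_second, t_end_second`.  Windows are half-open `[start, end)`.  For
*n* sounds the AB–BA design has *n·(n−1)* rows.

## answers.csv

`comparison_index, q1_choice, q2_choice` with choices `first`, `second` or
`none` (no choice made).  q1 = "Which sound is more annoying?",
q2 = "Which one appears to be from a higher-quality car?".

## questionnaire.csv

`juror_id, period, state` with `period` ∈ {beginning, during, end} and
`state` ∈ {fully_focused, actively_involved, partially_focused,
distracted, feeling_bored, heavy_eyed, mentally_fatigued}.

## Outputs

* `reliability.csv` — `juror_id, question, variant (all|filtered), rho, n`.
* `summary.json` — threshold curves (juror counts per ρ threshold per
  variant), median attention per (state, period) cell, reduction
  fractions.
* `deltas.csv` — `juror_id, state, delta` baseline deltas.
* `manifest.json` (synthetic sessions) — generator spec and seed.
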