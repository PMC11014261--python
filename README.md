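# jurysense

Attention-aware analysis of facial-expression data recorded during
paired-comparison (AB–BA) sound-quality jury tests.

In a listening jury test, jurors hear every pair of candidate sounds in both
orders and answer two forced-choice questions per pair — *which sound is more
annoying?* (q1) and *which sounds like the higher-quality car?* (q2).  A
webcam pipeline emits, per video frame, probabilities for Ekman's six
universal emotions, 68-point facial landmarks and a gaze point on the
screen.  `jurysense` turns those streams into an objective read-out of the
jurors' choices and of how much each juror can be trusted:

* **Per-frame affect metrics.**  With emotion percentages normalised to 100,

  ```
  valence    = H − Sa − A − F − D           ∈ [−100, 100]
  engagement = H + Su + A + F − Sa          reported in [0, 100]
  ```

  (H happiness, Su surprise, Sa sadness, A anger, F fear, D disgust; the
  engagement formula can go negative and is clipped at 0, with the raw
  value retained).

* **A landmark-geometry attention classifier.**  Head pose is proxied by
  landmark-distance ratios: yaw = |d(2,31)/d(31,16)| folded into (0, 1],
  pitch = d(28,31)/d(37,40), plus the eye aspect ratio
  EAR = (‖p₂−p₆‖+‖p₃−p₅‖)/(2‖p₁−p₄‖) of blink detection.  A frame is
  attentive when yaw ≥ 0.4, the pitch gate (pitch > 5 **and** EAR < 0.10,
  so blinks never flag inattention) does not fire, and the horizontal gaze
  coordinate lies strictly inside (1, 25) cm on the screen.

* **Segmentation-regression choice inference.**  An OLS line is fitted to
  the valence series of each sound sub-segment; within a comparison the
  sub-segment with the larger slope is the predicted higher-quality choice
  and the smaller one the predicted more-annoying choice.  The Spearman
  correlation ρ between these trend-derived choices and the juror's actual
  answers — computed on all frames and again on attentive frames only —
  quantifies each juror's reliability and the benefit of attention
  filtering (juror-count-vs-ρ-threshold curves).

* **Questionnaire cross-validation.**  Per-period mean attention is
  compared with the self-reported concentration state (fully focused …
  mentally fatigued) via median cells, baseline deltas against each juror's
  *fully focused* period, and per-state reduction fractions.

* **A seeded synthetic-session generator** (3-D face template → projected
  landmarks, attentive/inattentive dwell processes, injected valence trends,
  criterion-consistent answers) so the whole pipeline is testable without
  access to private recordings.

## Worked example

```python
import jurysense as js

spec = js.SyntheticSessionSpec(seed=7)          # 7 sounds, 42 comparisons, 14 fps
session = js.synth_session(spec, juror_id="juror_7")
analysis = js.analyze_session(session)
r = analysis.reliability
print(f"attentive fraction      : {session.frames['attention'].mean():.3f}")
print(f"rho_q2 (all frames)     : {r.rho_q2_all:+.3f}  (n = {r.n_comparisons_all})")
print(f"rho_q2 (attentive only) : {r.rho_q2_filtered:+.3f}  (n = {r.n_comparisons_filtered})")
```

prints

```
attentive fraction      : 0.764
rho_q2 (all frames)     : +0.631  (n = 42)
rho_q2 (attentive only) : +0.949  (n = 39)
```

The generated juror pays attention on 76% of frames (attention declines
over the session); fitting the valence trends on *all* frames yields an
answer–trend correlation of 0.63, while restricting the fits to attentive
frames raises it to 0.95 at the cost of three comparisons with too few
attentive frames — the attention-filtering effect the package is built to
measure.  Individual sub-segment fits are available too:

```python
seg = analysis.segments[0]
fit = js.fit_segment_trend(seg.frames_first)
# slope -1.96 valence/s, R^2 0.68, rho -0.82
choice = js.simulate_choices(seg)
# predicted q1=first, q2=second; juror answered q1=first, q2=second
```

The same pipeline runs from the shell:

```bash
jurysense simulate --n-jurors 10 --seed 3 --out data/
jurysense analyze data/ --out reports/     # reliability.csv, summary.json, deltas.csv
jurysense report  data/ --out figures/     # valence timelines, threshold curves
```

## Documentation

* `docs/methods.md` — models, assumptions, parameter defaults and known
  limitations.
* `docs/FORMATS.md` — the CSV dialects read and written by the package.
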