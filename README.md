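# fmscore

Automated scoring of upper-extremity **Fugl-Meyer Assessment (FMA)** motor
items from depth-camera skeletal joint trajectories, with a dimensionless
**normalized-jerk** movement-smoothness statistic and a synthetic-motion
generator that makes the whole pipeline testable without patient data.

The FMA is the standard post-stroke motor impairment scale: a therapist
scores each motor item 0 (cannot perform), 1 (partial) or 2 (full). This
package targets the 13 upper-extremity items that are observable as arm
motion by a seated depth camera (flexor/extensor synergy items, hand to
lumbar spine, shoulder flexion/abduction items). It is intended for
researchers and engineers building tele-rehabilitation or home-assessment
systems who need (a) reproducible score prediction from skeletal time
series and (b) a quantitative smoothness measure that observation-based
scoring cannot provide.

## What it computes

**Score prediction.** Each 30 Hz recording (time + 10 joints × 3
coordinates = 31 variables per frame) is mirrored to a common side, clipped
to the active movement, normalized for seating position and body size, and
summarized into ~100 kinematic features (joint-angle and joint-distance
statistics, per-axis displacements, bounding area, normalized jerk,
duration). Per item, features are standardized, reduced by PCA to 4–10
components and classified by a small neural network (one 16-unit logistic
hidden layer, softmax over scores {0, 1, 2}) — identical architecture for
every item. Class imbalance is handled by random oversampling inside
training folds; validation is stratified 8–10-fold cross-validation.

**Smoothness.** With P(t) the 18-dimensional vector of the six moving-side
joints and jerk its third time-derivative,

```
NJ = sqrt( 1/2 ∫_{T1}^{T2} ||d³P/dt³||² dt × duration⁵ / length² )
```

with duration = T2 − T1 the clipped window and length the maximum
displacement from the starting posture. NJ is dimensionless — invariant to
movement size and speed — and equals √360 ≈ 18.97 for a perfectly smooth
(minimum-jerk) reach; tremor and corrective submovements raise it. Cohort
analyses use log10 NJ.

## Worked example

Generate a tiny synthetic cohort (one subject per score class, one item),
then score the smoothness of two of its recordings:

```
$ fms simulate --n 1 --seed 4 --item elbow_flexion --out-dir demo
wrote 6 recordings + cohort.csv to demo

$ fms validate demo/S0000_right_elbow_flexion.txt
OK: S0000 right elbow_flexion 122 frames @ 30 Hz, 4.03 s

$ fms jerk demo/S0000_right_elbow_flexion.txt --smooth   # non-hemiplegic side
{
  "duration": 2.1333333333333333,
  "length": 1.3148615292530914,
  "normalized_jerk": 22.390215710351764,
  "log_jerk": 1.3500582776506775
}

$ fms jerk demo/S0000_left_elbow_flexion.txt --smooth    # hemiplegic, severe
{
  "duration": 3.166666666666667,
  "length": 0.1749283686670336,
  "normalized_jerk": 874.6657601050764,
  "log_jerk": 2.9418421258525953
}
```

The non-hemiplegic side scores log-jerk 1.35, just above the smooth-reach
floor of log10 √360 ≈ 1.28 (the residue is sensor noise). The severely
impaired side barely moves (length 0.17 body-lengths instead of 1.31) and
trembles, so its normalized jerk is ~40× higher. `fms features` exports the
feature matrix as CSV, `fms train` / `fms cv` / `fms predict` fit, validate
and apply per-item score models, and `fms evaluate` recomputes cohort
statistics (Pearson agreement of summed scores, paired hemiplegic vs
non-hemiplegic log-jerk comparison, Spearman correlation with Brunnstrom
stage) from a score table.

The same functionality is available as a library:

```python
from fmscore import FMAItem, normalized_jerk, preprocess_recording, read_recording

rec = read_recording("demo/S0000_right_elbow_flexion.txt")
clipped, window = preprocess_recording(rec)
print(normalized_jerk(clipped, smooth=True).log_jerk)
```

See `docs/methods.md` for the full description of the preprocessing rules,
the feature roster, the numerical differentiation scheme and the synthetic
generator.

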