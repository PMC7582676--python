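# p300balance

Class-imbalance resampling and SVM classification for P300 oddball
brain–computer interfaces, driven by a synthetic ERP session generator.

## The problem

A P300-based BCI selects one of N stimuli (N = 4 or 6 here — appliance
control menus) by flashing each stimulus repeatedly and detecting the P300,
a positive EEG deflection 250–500 ms after the *attended* stimulus lights
up. The oddball design makes the training data inherently imbalanced: each
50-block training session yields 50 target ERP samples against 150 (1:3)
or 250 (1:5) nontarget samples. The imbalance biases a classifier toward
the nontarget class — targets are missed (low recall) even while target
calls are precise.

This package implements the full analysis of that problem for researchers
studying resampling in BCI pipelines: five oversamplers (ROS, SMOTE,
borderline-SMOTE, SVM-SMOTE, ADASYN — all synthesizing via
`s = p + r·(q − p)` toward K = 5 nearest minority neighbors), three
undersamplers (RUS, neighborhood cleaning rule, Tomek links), a weighted
undersampling bagging ensemble (SVMs on disjoint nontarget subsets voting
with exact rational weights 1/6, 2/6, 3/6 or 1/15…5/15 by training-accuracy
rank), and a weighted-C SVM. The classifier is a soft-margin SVM
(`½‖w‖² + C Σᵢ ξᵢ`, C = 1, linear kernel) with Platt-calibrated target
probabilities; a block's selected stimulus is `argmax_j P(target | x_j)`.
Performance is reported as block accuracy, recall/precision/F1 from the
target/nontarget confusion matrix, and the information transfer rate
`ITR = [log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))]/T` bits/min.

Because the underlying recordings of such studies are rarely deposited, the
package ships a first-class synthetic session generator: multichannel
oddball EEG (32 channels, 500 Hz, 62.5 ms highlights, 10 per stimulus per
block, 50 training + 30 test blocks) with a rhythmic low-rank background,
unreliable single-trial P300 elicitation and latency jitter — the features
that make the imbalance bias real in feature space. See `docs/methods.md`
for the model and its limits.

## Worked example

```python
from p300balance import *
from p300balance.balance import SamplerParams

cfg = SyntheticConfig(n_channels=8, p300_amplitude=9.0, seed=12)  # poor performer
session = generate_session(cfg)
train, test = session_features(session)
print(f"training samples: {train.n_minority} target / {train.n_majority} nontarget")
for method in ("none", "b-smote"):
    rep = run_subject(session, method, params=SamplerParams(seed=0),
                      features=(train, test), selection_minutes=10/60)
    print(method, rep.block_accuracy, rep.confusion.recall,
          rep.confusion.precision, rep.itr_bpm, rep.sv["sv_count_target"])
```

prints

```
training samples: 50 target / 150 nontarget, 2000 features
none     block accuracy 0.767  recall 0.67  precision 0.87  F1 0.75  ITR 5.08 bpm  target SVs 22
b-smote  block accuracy 0.700  recall 0.83  precision 0.57  F1 0.68  ITR 3.86 bpm  target SVs 29
```

Read: without balancing this low-SNR subject's classifier is conservative —
it finds only 67 % of true targets but is right 87 % of the time when it
calls one. Borderline-SMOTE synthesizes minority points along the class
border, grows the target-class support-vector count (22 → 29), and
shifts the operating point to high recall at the cost of precision. Block
accuracy (the argmax over stimuli) moves much less than the binary metrics
— the central observation of this analysis. Cohort-level means, the
significance tests and the ratio sweep are produced by
`evaluate.run_comparison` and `evaluate.ratio_sweep`.

A command-line interface mirrors the library
(`p300balance simulate|features|balance|train|evaluate|compare|sweep`),
e.g.:

```bash
p300balance simulate --subjects 3 --amplitude 9 --seed 1 --out scratch/cohort
p300balance features scratch/cohort/subject_00 --out scratch/feat
p300balance balance scratch/feat/train.tsv scratch/balanced.tsv --method b-smote --seed 1
```

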