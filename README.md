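# sleeptriage

Human-computer collaborative sleep scoring for polysomnography (PSG)
recordings.

Visual sleep staging — classifying each 30-second epoch of an overnight
EEG/EOG/EMG recording into the AASM stages W, N1, N2, N3 and R — is slow and
subjective, and experts distrust fully automatic scorers enough to rescore
everything anyway. `sleeptriage` implements a middle path: a transparent
rule-based automatic stager produces a first-pass hypnogram, then every epoch
is annotated as *high* or *low* reliability, and only the low-reliability
epochs (typically a quarter to a third of the night) are sent to a human
expert. The expert's corrections are merged back over the automatic scoring.

It is intended for sleep researchers and PSG software developers who want an
interpretable scoring pipeline with an explicit, auditable notion of per-epoch
confidence — not another black-box classifier.

## Method

**Features.** Each 30-s epoch yields 12 features from one EEG derivation
(C3-M2, falling back to C4-M1), one EOG and the chin EMG: total 0–30 Hz power
(EEG, EMG), band-power ratios 0–4/0–30, 8–13/0–30, 22–30/0–30 Hz (EEG) and
0–4/0–30 Hz (EOG), spectral mean frequencies (EEG, EMG), duration ratios of
alpha, spindle and slow-wave activity (EEG), and mean rectified EMG
amplitude. Features are normalized per recording by robust min–max.

**Staging.** A layered decision tree (≤ 13 binary nodes) assigns stages
easiest-first — W by alpha/tone, N3 by slow waves, R by atonia, N2 by
spindles, N1 as fall-through — followed by temporal smoothing (singleton
island removal, short-N1 bridging). A calibration routine can refit node
features and thresholds from any labeled recording using a total-variation
distribution distance.

**Reliability triage.** Three per-epoch signals vote:

* **SWR** — for N2/N3 epochs, three slow-wave-related features (EEG 0–30 Hz
  power, slow-wave ratio, EOG 0–4/0–30 ratio) are tested against the
  boundary range [mean<sub>N2</sub>+SD<sub>N2</sub>,
  mean<sub>N3</sub>−SD<sub>N3</sub>] learned from labeled training epochs;
* **SCD** — stage-change distance, the distance in epochs to the nearest
  epoch of a different stage (high-reliability vote iff SCD > 5 in the
  normal mode);
* **SCF** — stage-change frequency, the number of transitions in the
  centered 11-epoch window (vote iff SCF ≤ 2).

An epoch is high reliability iff at least 2 of the 3 votes pass. A less
stringent mode (SCD > 4, SCF ≤ 3) flags fewer epochs. Evaluation reports
epoch agreement (overall and by reliability class), unweighted Cohen's κ,
confusion matrices and sleep efficiency.

Because overnight PSG data cannot be shipped, the package includes a
first-class synthetic generator: Markov-chain hypnograms, stage-archetype
signal synthesis (alpha runs, spindles, >75 µV slow waves on an N2↔N3 depth
continuum, REM atonia), EDF fixtures, and a simulated "disagreeing scorer"
whose errors cluster near stage transitions — the regime the triage is
designed to catch.

## Worked example

```
$ sleeptriage simulate --n-epochs 80 --seed 3 --out-dir night/
$ sleeptriage score night/fixture_3.edf \
      --out-hypnogram night/auto.txt --out-features night/feats.csv \
      --out-raw-hypnogram night/raw.txt
INFO sleeptriage: scored 80 epochs; stage counts {'W': 15, 'N1': 10,
  'N2': 11, 'N3': 43, 'R': 1}; sleep efficiency 81.2%
$ sleeptriage calibrate --features night/feats.csv \
      --labels night/fixture_3_truth.csv --out-swr night/cal.yaml
$ sleeptriage annotate --hypnogram night/raw.txt --features night/feats.csv \
      --calibration night/cal.yaml \
      --out-annotations night/ann.csv --out-review night/review.csv
INFO sleeptriage: 30 of 80 epochs (37.5%) are low-reliability (level1, rule=vote)
```

`review.csv` now lists the 30 epochs the expert must look at (epoch number,
start time, automatic stage, and the SCD/SCF/SWR evidence). Answering those
30 epochs with the ground-truth labels and merging:

```
$ sleeptriage merge --auto night/auto.txt --annotations night/ann.csv \
      --answers night/answers.csv --out night/final.txt
INFO sleeptriage: merged 30 expert answers; 5 epochs changed
$ sleeptriage evaluate night/final.txt night/fixture_3_truth.csv \
      --annotations night/ann.csv --out night/report.yaml
INFO sleeptriage: overall agreement 100.00%, kappa 1.000
```

All five automatic-scoring errors on this night sat inside the review list,
so rescoring 37.5% of the epochs recovered a perfect hypnogram. The report
decomposes agreement into the high- and low-reliability subsets — the
quantity that tells you whether the triage sent the *right* epochs to the
human.

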