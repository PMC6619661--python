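# Methods

## Scope and data model

`sleeptriage` scores overnight polysomnography on the fixed AASM grid: the
recording is cut into contiguous 30-s epochs (a trailing partial epoch is
dropped), each epoch receives one stage label from {W, N1, N2, N3, R}, and
each automatically scored epoch additionally receives a binary reliability
verdict. Recordings travel as EDF; reading goes through `mne`, writing
through a built-in 16-bit EDF writer (1-s records, per-channel symmetric
physical range, so the quantization step is `range/65535`). Channels are
resolved to the roles EEG/EOG/EMG by label heuristics (C3/C4 → EEG,
EOG/LOC/ROC → EOG, chin/EMG → EMG), overridable by an explicit map. When
both C3-M2 and C4-M1 are present, C3-M2 is the staging derivation and C4-M1
the fallback; channels may have different sampling rates and are processed
at their native rate.

## Features

Twelve features per epoch. Spectral quantities use Welch's method with 2-s
Hamming windows at 50% overlap (0.5 Hz resolution — enough to resolve the
0–4, 8–13 and 22–30 Hz bands without excessive variance at 30 s). Band power
integrates the PSD over the half-open interval [f_lo, f_hi); power ratios
carry a denominator floor of 1e−12 µV² and are clipped to [0, 1]; mean
frequency is the spectral centroid over 0–30 Hz and is defined as 0 (with a
logged warning) for a zero-power epoch. The EMG total power is integrated
over 0–30 Hz like the EEG's, matching the feature table this pipeline is
built around even though chin EMG is conventionally filtered 5–100 Hz.

The three duration ratios slide a 1-s window in 0.5-s steps and report the
covered fraction of the epoch:

| detector | criterion (window counts if …) | default |
|---|---|---|
| alpha    | relative 8–13 Hz power > 0.5 **and** 8–13 Hz band-passed p-p > 10 µV | — |
| spindle  | relative 11–16 Hz power > 0.5 (1-s window ≥ AASM 0.5-s minimum) | — |
| sws      | 0.5–2 Hz band-passed p-p > 75 µV (AASM slow-wave amplitude) | — |

Relative power for the alpha and spindle rules is computed against a 4–30 Hz
reference band rather than 0–30 Hz: AASM counts a spindle even when it rides
on a slow wave, and a 0–30 Hz denominator lets delta power mask genuine
spindle windows precisely at the N2 boundaries where staging is hardest. All
detector constants live in `DetectorConfig` and are user-settable.

Per-recording normalization maps each feature to [0, 1] by robust min–max
over its 2.5th–97.5th percentiles, then clips. The robust band exists to
absorb artifact epochs; it is set at 2.5/97.5 rather than a wider trim
because a feature's extreme values are often produced by a minority stage —
a good sleeper may spend under 5% of the night awake, and trimming at 5%
would collapse the EMG-tone scale that identifies wake. A constant column
maps to 0.5.

## Staging

The default tree has 9 binary decision nodes over normalized features,
layered easiest-first with N1 — the stage humans agree on least — as the
fall-through:

1. `alpha_E > 0.60` → W; 2. `amp_M > 0.70` → W
3. `sws_E > 0.75` → N3; 4. `r0_4_E > 0.85` → N3
5.–7. `amp_M < 0.25` and `mf_M < 0.45` and `r0_4_O > 0.15` → R
8. `spindle_E > 0.50` and 9. `p0_30_E > 0.03` → N2; otherwise N1.

The final power gate (node 9) exists because spindle activity bleeding
across a boundary can light up the spindle detector in an epoch whose EEG is
otherwise near-silent; genuine N2 always carries appreciable total power.
Ties at a threshold resolve toward the earlier (upper) node, classification
is a pure function of (features, tree), and a NaN feature raises an error
naming the feature. Trees serialize to YAML (`{id, feature, op, threshold,
if_true, if_false}` with stage tokens as terminals), so a recalibrated tree
is a config file, not a code change.

`calibrate_tree` refits the tree from a labeled recording in the fixed
stage-separation order W | N3 | R | N2: at each node it selects the feature
with the largest total-variation distance between the target stage and the
remaining stages (20 equal-width bins on [0, 1]) and places the threshold at
the maximal CDF gap, the minimal-overlap cut for unimodal classes. If no
feature separates (distance < 0.05) the node keeps threshold 0.5 and warns.
Every stage must have ≥ 5 labeled epochs.

Smoothing applies two context rules to a fixed point (at most n passes):
singleton-island removal (an epoch differing from two identical flanking
neighbors takes their stage) and N1 bridging (an N1 run of ≤ 2 epochs
flanked by N2 becomes N2). Running to a fixed point rather than one pass
makes the operation idempotent — the property a post-processing step should
have — without changing the outcome on typical hypnograms. Inputs shorter
than 3 epochs are returned unchanged with a warning.

## Reliability triage

Three signals vote per epoch; an epoch is high reliability iff ≥ 2 votes
pass, and low otherwise (the review set).

**SWR (slow-wave-related) boundary ranges.** For each of `p0_30_E`, `sws_E`
and `r0_4_O`, the N2 and N3 populations of a labeled training recording
define the range `[mean_N2 + sd_N2, mean_N3 − sd_N3]` (Bessel-corrected
SDs). Deep N2 and light N3 — where the slow-wave evidence is genuinely
borderline — fall inside; membership is inclusive at both ends. If the
populations overlap so much that the bounds invert, the interval is
canonicalized to `[min, max]` and flagged `inverted`. For an epoch staged
N2/N3, each feature contributes a bit (1 = outside its range) and the SWR
vote passes iff ≥ 2 bits are 1. For any other stage the check carries no
evidence; the vote defaults to 0, so wake/N1/REM epochs are vouched for only
when *both* stage-change votes pass. (The alternative — defaulting to 1 — is
one argument away; with it, an epoch at an isolated W↔N1 or N2↔R boundary
can essentially never be flagged, although those boundaries are
high-disagreement territory.) Calibration is a training step: the reference
pipeline computes it against the expert-labeled hypnogram, as a deployment
would against its labeled training set.

**SCD** is the distance (in epochs) to the nearest epoch of a different
stage; a single-stage recording gets the sentinel `len(h)`. **SCF** counts
stage transitions within the 11-epoch window centered on the epoch (±5,
truncated at the record edges, no padding). Under the normal mode (level 1)
the SCD vote passes iff SCD > 5 — equivalently, an epoch within 5 epochs of
a change cannot earn it — and the SCF vote iff SCF ≤ 2; the less stringent
level 2 uses SCD > 4 and SCF ≤ 3, so level-1 high-reliability sets are
always subsets of level-2 sets. An alternative `rule="or"` reproduces the
simpler two-signal disjunction (high iff SCD *or* SCF alone passes).

The stage-change statistics are computed on the classifier output *before*
smoothing: smoothing deliberately erases boundary flicker and short N1
bouts, and that flicker is itself evidence of unreliability. The smoothed
hypnogram remains the reported scoring.

`merge_rescored` overlays expert answers (epoch index → stage) on the
automatic hypnogram; answers for high-reliability epochs are rejected in
strict mode and applied with a warning otherwise.

## Evaluation

Percent epoch agreement (overall or over an index subset — the weighted
subset agreements recompose exactly to the overall figure), unweighted
Cohen's κ (stage labels are nominal; κ defined as 1 when both scorers are
constant and identical), 5×5 confusion matrices in stage order W/N1/N2/N3/R,
sleep efficiency as the percent of scored epochs not staged W (lights-off
annotations are outside the data model), and *disagreement capture*: of the
epochs where two hypnograms disagree, the fraction flagged low-reliability —
the single number that says whether the triage sends the disputed epochs to
the human. It is undefined (an error) when there are no disagreements.

## Synthetic data

The generator exists so the entire pipeline is testable without clinical
recordings; its defaults are the package's reference study conditions.

*Hypnograms* are sampled from a first-order Markov chain (5×5 row-stochastic
matrix, initial state W). The default chain has all self-transitions ≥ 0.85
— runs of several minutes per stage — with long consolidated wake and N3
bouts (self-transition 0.93), most traffic through N2, and N2↔N3 deepening
cycles as the dominant transition class. Its stationary distribution is
roughly 13% W, 10% N1, 38% N2, 28% N3, 12% R, the N3-heavy end of a young
adult's night.

*Signals* are per-stage mixtures of burst-gated sinusoids (random phase and
burst placement, per-burst lognormal amplitude jitter σ = 0.05) over pink
noise (σ = 3 µV): W has 10 Hz/30 µV alpha at 0.9 duty and the largest EMG
tone (30 µV); N1 low theta; N2 theta plus 13.5 Hz/40 µV spindle bursts of
1 s; R theta with EMG atonia (2 µV tone) and intermittent slow 60 µV EOG
deflections. The chin EMG is broadband noise scaled by the stage tone plus a
small 2 Hz baseline component; under atonia the baseline dominates and the
EMG mean frequency collapses, which is what the tree's REM node reads.

N2 and N3 are not two fixed recipes but points on a *depth continuum*: the
slow-wave component has peak-to-peak amplitude `40 + 85·depth` µV and duty
`0.20 + 0.65·depth`, with N2 at depth 0.30 (p-p ≈ 66 µV, below the 75 µV
scoring criterion) and N3 at 0.90 (p-p ≈ 117 µV). Each epoch's depth gets
N(0, 0.03) jitter. The EOG of NREM epochs mixes in 0.4× the slow-wave
signal (frontal delta bleeds into the eye electrodes) over broadband 14 µV
noise, so the EOG delta ratio tracks depth.

Epochs within 2 epochs of a stage transition drift toward the stage across
the boundary with weight `0.42·0.85^(d−1)` at distance d: within N2↔N3 the
drift acts on depth (slow-wave amplitude ramps *through* the 75 µV
criterion), for any other pair the rendered waveforms are cross-faded. This
reproduces the two phenomena the triage is built around — slow-wave features
hovering in the N2/N3 boundary range exactly where scorers disagree, and
feature ambiguity concentrated at transitions.

The *disagreeing scorer* relabels each epoch within `near_radius` (2) of a
transition with probability `p_near` to the stage on the other side of the
nearest transition (the typical boundary call), and every other epoch with
probability `p_far ≤ p_near`; at the reference setting (0.4/0.02) over 90%
of its disagreements fall near transitions, mirroring interscorer-program
findings.

What the generator does **not** emulate: K-complexes, sawtooth waves,
arousals and movement artifacts, EEG nonstationarity within a stage,
realistic 1/f spectra beyond the pink background, and ultradian cycle
structure (the Markov chain is time-homogeneous). Passing the end-to-end
tests therefore shows that the pipeline's logic behaves as designed under
its intended signal model — not that the shipped default tree would reach
the same accuracy on clinical recordings, where recalibration
(`calibrate_tree`, `calibrate_swr`) on local labeled data is expected.

## Reference problem sizes

The end-to-end checks and the acceptance script use one 500-epoch night
(≈ 4.2 h at 256 Hz, five channels) and 20 simulated scorers, sizes at which
the measured quantities (staging agreement, low-reliability fraction,
disagreement capture) are stable to a few percent across generator seeds
while the whole pipeline runs in well under a minute.

## Known limitations

* The default tree thresholds are tuned to the synthetic archetypes'
  normalized feature geometry; on real PSG they are a starting point for
  calibration, not a validated clinical scorer.
* The SWR construction assumes the N2/N3 populations are unimodal with a
  gap; heavily fragmented nights inflate the class SDs and shrink (or
  invert) the boundary ranges, which the calibration flags but cannot
  repair.
* Sleep efficiency uses the scored grid as time in bed.
* EDF writing truncates to whole seconds and does not emit EDF+
  annotations.
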