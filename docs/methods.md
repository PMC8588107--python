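# Methods

## Problem and model

The package regresses the intensity of a primary-taste stimulus (Sour,
Sweet, Bitter, Salty, Umami; tastant solutions at six concentrations
each, including deionized water) from six channels of facial surface
EMG. The working assumption, borne out for negative-hedonic tastes, is
that taste intensity modulates the activation energy of specific facial
muscles, and that this energy is recoverable from windowed spectral and
amplitude features of the sEMG after removal of baseline wander and
mains interference.

## Stimulus grid and labels

Each taste has a fixed concentration series (mol/L), descending by half
an order of magnitude per step, e.g. citric acid 0.200, 0.063, 0.020,
0.006, 0.002, 0; sodium chloride runs 2.000 down to 0.020. Matching a
concentration to the grid uses relative tolerance 1e-6, because printed
values are rounded (0.316 ≈ 10^−0.5). Three label schemes attach to each
window:

* **strength label** (0–5): 5 at the series maximum, −1 per half-decade,
  0 for water — exponential in concentration;
* **relative concentration** (0–1): concentration over the series
  maximum — linear in concentration;
* **scale score** (0–10): the subject's own rating.

Off-grid concentrations are refused with an error naming the taste; no
nearest-grid snapping is done, since a silently mislabeled trial is
worse than a failed load.

## Synthetic generator

No recordings are deposited, so a generator produces trials whose
statistical structure matches what the analysis assumes. Per channel,

    x(t) = A·g·c(t) + w(t) + p(t)

with `c(t)` a unit-RMS Gaussian carrier band-passed to 20–450 Hz (the
standard sEMG energy band; 4th-order Butterworth applied forward and
backward), `A` = 10 µV nominal base amplitude, and the activation gain

    g = 1 + slope_ch · hedonic_gain[taste] · intensity.

Channel slopes default to (0.15, 0.60, 0.35, 0.15, 0.45, 0.15): the
depressor anguli oris (ch 2) and procerus (ch 5) respond most strongly,
matching the observed ordering of facial responses. Hedonic gains
default to 1.0 for Sour/Bitter/Salty and ~0 (0.05/0.1) for Sweet/Umami,
so positive-hedonic tastes give a flat intensity response while keeping
normal baseline muscle tone — the gain multiplies the intensity-dependent
term, not the whole carrier, precisely so that "no hedonic response"
means "flat", not "silent".

`w(t)` is baseline wander: five random-phase sinusoids below 2 Hz plus a
slow ramp, scaled to 100 µV (10× the carrier base RMS) so the baseline
stage has realistic work to do. `p(t)` is mains interference: 50 Hz plus
harmonics at 20/10/5 µV with random phases.

Scale scores are `clip(2·intensity + N(0, sd), 0, 10)` with sd = 1 by
default (subjects find absolute scoring hard; the noise models that).

Per-trial seeds are CRC32 hashes of (master seed, subject, session,
taste, intensity), so any single trial regenerates bit-identically
regardless of generation order, and every generator output is a pure
function of its arguments.

**What the generator does not emulate:** motor-unit physiology,
electrode geometry and skin impedance, cross-channel correlation of
genuine facial gestures, nonstationarity within a trial, or
subject-level drift between sessions. Units are nominal µV (no dynamic
range is documented for the original hardware). Because the synthetic
intensity→energy mapping is clean and monotone, CV R² values on
synthetic data (~0.99 sample-grouped) are upper bounds on what
heterogeneous human data can give; passing tests demonstrate the
machinery is correct, not that human-data effect sizes are reproduced.

## Preprocessing

Windows are 1 s at a 0.25 s step; offsets are left-closed sample
indices and the last partial window is discarded (a 12 s trial yields
45 windows). QVR solves `(I + λDᵀD)s = z̃` per channel with λ = 2 via a
banded Cholesky solve and subtracts the smooth baseline `s`; λ = 0
returns zero (the baseline is the signal itself) and λ → ∞ returns the
demeaned signal. QVR runs before the notch; the canonical presentation
of the preprocessing shows baseline removal first.

The adaptive notch works in the discrete spectrum of each 1 s window
(1 Hz bins). For each harmonic k·50 Hz up to k = 9 (450 Hz, below
Nyquist), the peak magnitude within ±1 bin is compared against 5× the
median magnitude of the flanking bins (offsets 3–8 bins on both sides);
only if abnormal is the notch band replaced by linear interpolation of
the flanking medians, phases kept, before inverse transform. Clean
signals therefore pass through bit-identically (the adaptivity
contract), and re-applying the notch is a near no-op. A window is
rejected when notching removed more than 80% of any channel's power —
what remains is interference residue rather than muscle signal. The
detection ratio, flank offsets, halfwidth and rejection threshold are
configuration, not constants, since none of them is canonical.

## Features

Per channel of a 1 s, 1 kHz window: the one-sided unnormalized magnitude
spectrum (500 bins, no taper — scale-invariant model metrics make
normalization moot, and tapering is deliberately omitted to keep the
band partition exact); 50 band sums over [(n−1)·10, n·10) Hz including
DC in band 1; FC, RMSF and RVF treating magnitudes as a mass
distribution over bin frequencies (so RMSF² = FC² + RVF² identically);
and time-domain RMS and MAV. An all-zero channel has undefined moments:
they are emitted as NaN and such rows are dropped (with a warning) by
the model stage. The 330-vector is channel-major; feature j belongs to
channel ⌈j/55⌉, and each channel's 55 features split into 11 consecutive
groups of 5 — the granularity of feature selection.

## Model and evaluation

ε-SVR with RBF kernel; C = 1, ε = 0.1, γ = 1/(d·var(X)) after
standardization. These are deliberately plain defaults — no
hyperparameter search is in scope — and all are exposed per call.
Standardization is fit on the training folds only, so the held-out fold
never leaks into the scaler. R² is computed by the package's own
implementation of the coefficient of determination (cross-checked
against scikit-learn in the tests).

Fold assignment is a seeded shuffle at the window level by default,
mirroring the original evaluation; because adjacent windows overlap by
0.75 s, sample-level CV is optimistic, so a `grouping="trial"` mode
assigns whole trials to folds and is reported alongside. Shuffling is
unstratified (neither intensity- nor subject-stratification is claimed
by the procedure being followed). Constant labels are an error; constant
feature columns are dropped with a warning.

## Feature selection

Per channel, greedy forward selection over the 11 groups: at each step
every remaining group is scored by 5-fold CV R² of (chosen ∪ candidate),
costing 11 + 10 + … + 1 = 66 fits per channel; ties break to the lowest
group index (the procedure's prose contains index slips, so the
implemented rule is simply "add the group that achieved the best
score"). The inflection point is the largest NF whose R² is within 0.02
of the curve maximum. The reduced set is the union of each channel's
groups up to its inflection, so its dimensionality is exactly the sum of
the per-channel inflection NFs; it is refit once for the
before/after comparison. Whether the per-step score should be a single
split or full CV is not canonical; full 5-fold CV is used for
consistency with the evaluation stage.

## Activity maps

S_{T,I,C} is the mean over windows of the channel's spectral amplitude
integral (sum of the 500 magnitude bins — identically the sum of the 50
band features). Channels 2–6 stand for the five muscles; channel 1 (the
masseter differential pair) is excluded because the single-electrode
channel 6 reflects raw masseter signal strength more directly.
Normalization divides by the same (taste, channel)'s intensity-0 mean
and is refused (NaN + warning) when that mean is zero or missing; empty
cells are NaN with n = 0. The full design gives 150 S values. Rendering
maps normalized values linearly onto a sequential light-to-dark
colormap (darker = stronger); one panel per (taste, nonzero intensity)
plus a single no-stimulus panel where every muscle is 1 by construction.
Integrals are computed after full preprocessing (the defensible default;
computing them pre-notch would count interference as muscle energy).

## Cohort analysis

For a pool of P subjects, every nonempty subset (2^P − 1; 31 for P = 5)
gets a pooled dataset and one CV fit; R²_NS averages subsets of equal
size. Reduced feature sets are the natural input at this stage (the
selection step precedes it), but the functions accept any column list.
Pooled fits use the same unstratified seeded shuffling as the base
evaluator.

## Problem sizes used in tests

The default verification dataset is 1 subject × 2 sessions × Salty
(12 trials, 540 windows) — the smallest configuration that exercises
every intensity with two repeats; cohort tests use 2–3 subject pools at
1 session. These sizes were fixed as the package's standard smoke-scale
conditions and are generated fresh at test time; nothing is stored on
disk.

## Known limitations

* The notch design (spectral interpolation) is one reasonable reading of
  an "adaptive notch"; IIR/FIR alternatives are out of scope.
* 60 Hz regions are supported via `powerline_freq` but not exercised by
  the test suite.
* The generator's separability means selection curves on synthetic data
  rarely decay: most groups carry signal, so inflections sit high
  (NF = 55). The inflection rule itself is pinned by a worked curve in
  the tests.
* Classification of taste *type* is explicitly not attempted; the target
  is intensity regression within a taste.
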