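# Methods

This note records the model, the parameter choices and the numerical
conventions behind `adlike`, and what the synthetic tests do and do not
demonstrate.

## Signal model and preprocessing

The pipeline assumes a 14-channel 10–20 recording (AF3…AF4) at 128 Hz in
microvolts, preceded by a 15 s stimulus-free baseline. Front-end
filtering is a 2 Hz high-pass plus 47 Hz low-pass, each an order-4
Butterworth applied forward–backward (`sosfiltfilt`), i.e. zero phase
with effective order 8. The order is a package choice: analysis is
offline, so IIR phase nonlinearity is irrelevant, and zero-phase
application keeps windows aligned with stimulus timing; order 4 keeps
the transition bands narrow without numerical fragility at 128 Hz.
Band decomposition uses order-4 Butterworth band-passes at θ 3–7,
α 8–13, β 14–29, γ 30–47 Hz, also zero-phase. No notch filter is
needed: the 47 Hz low-pass already excludes mains.

Artifact handling is deterministic amplitude-threshold rejection:
samples exceeding 100 µV (configurable) on any channel, dilated by
±0.25 s, are flagged and *excluded* from every downstream statistic
(never interpolated). ICA-style component removal was deliberately not
used — it requires interactive component selection and is not
reproducible in an automated pipeline. Filtering precedes rejection;
the flag train marks the filtered signal. A recording with more than
half its samples flagged is refused as unusable.

Baseline correction happens twice, in different domains: the baseline
*mean* is subtracted from each channel (DC drift), and the baseline
*band power* (same Welch settings) is subtracted from each window's band
power before the logarithm. Corrected powers are floored at 1e-12
before the log, so a window spectrally indistinguishable from rest
collapses to the floor and is flagged degenerate.

## Features

Windows are 10 s long with 4 s overlap (hop 6 s); a 30 s ad yields 5
windows. A final window running past the clip end is truncated for
time-domain statistics and zero-padded to 10 s for spectral estimation;
this convention is what makes the 5-windows-per-30 s count exact.

The 19 per-series statistics (the count is fixed; the set is standard
EEG window practice) are, in schema order: mean, standard deviation,
variance, min, max, range, median, Q1, Q3, IQR, skewness, excess
kurtosis, RMS, mean absolute deviation, line length (mean |first
difference|), zero-crossing count, Hjorth mobility, Hjorth complexity,
and total energy. Conventions: sample (n−1) variance for `var`/`sd`;
population moments inside skewness/kurtosis/Hjorth; excess kurtosis
(normal → 0); shape statistics of a constant series are defined as 0.
Difference-based statistics only use sample pairs adjacent in the
original series and both artifact-free, so excised stretches do not
create spurious jumps (the three junctions of the concatenated
asymmetry series are the one remaining, and negligible, exception).

Band power is the Welch PSD (Hann, 128-sample segments, 64 overlap,
`detrend=False`) *integrated* over the band's inclusive bins. The
integral, not the bin mean, is used so that a flat spectrum yields power
proportional to bandwidth; band-power logs are natural logs.

The Z-index of channel c for video v is Z = (X̄ − μ)/(σ/√N) where X is
the distribution of the video's N per-window broadband (3–47 Hz) powers
and μ, σ are the mean and standard deviation of that channel's power
over all windows of the session. It is appended, constant per video, to
each of the video's windows. A video with fewer than 2 windows, or a
constant-power session, has no defined Z; the pipeline emits 0 with a
warning rather than failing. The valence-split left/right Pearson
correlations of Z require ratings, so they are exposed as a
training-time diagnostic (`valence_pair_correlation`) and are never part
of the prediction-time feature vector; "pleasant" is rating > 3,
"unpleasant" rating < 3, rating 3 excluded.

The default vector is 1064 (stats) + 56 (log PSD) + 133 (asymmetry) +
14 (Z) = 1267 features in a fixed, versioned order
(`{block}.{channel|pair}.{band}.{stat}`); blocks can be toggled in the
config.

## Discretization

Candidate cuts are midpoints between consecutive distinct sorted values
whose class compositions differ; cutting between identically-composed
groups leaves χ² unchanged while increasing k, so such cuts can never
raise the criterion. The **original** variant greedily adds the
candidate maximizing Ameva(k) = χ²/(k(l−1)), stopping when no candidate
improves it by more than 1e-12; ties go to the leftmost cut for
determinism. Classes with zero total are excluded from l. On tiny
datasets the greedy value matches exhaustive enumeration over all cut
subsets of the same cardinality (verified in the acceptance suite);
greedy forward selection is not guaranteed optimal in general.

The **optimized** variant is described here constructively, as one
consistent reading of a behavioural description: seed with the original
variant's cuts, then one ascending pass over the remaining candidates,
accepting each cut that strictly reduces the summed within-interval
variance of the class labels *taken as numbers on the rating scale*
(ratings are ordinal, so the numeric reading is an explicit modeling
choice). Prefix sums of labels and squared labels are computed once, so
each candidate costs O(1) and is touched exactly once. This
construction guarantees the subset property cuts(original) ⊆
cuts(optimized) and generally produces more intervals. The
`n_criterion_evals` counter reports each variant's own search-loop
evaluations (the optimized variant's seeding reuses the original cut
list) as an operation-count proxy for runtime.

Outermost intervals extend to ±∞, so unseen extreme values at
prediction time always fall in an interval; interval membership is
half-open right, x ∈ (L^l, L^u].

## Classification

AIm[c,i,s] = (Cm[c,i,s]/total[c,s]) · 1/(l−1) · Σ_{j≠c}(1 − Cm[j,i,s]/total[j,s])
lies in [0, 1] by construction, is exactly 1 for a perfectly
discriminative interval and exactly 0 wherever Cm is 0. Prediction sums
AIm entries over all statistics with equal weight and takes the argmax;
exact ties break toward the smaller rating. Classes absent from
training have zero likelihood everywhere, can never be predicted, and
are flagged on the model. A single-class training set produces a
flagged degenerate model whose AIm degenerates to the within-class
interval probabilities.

The evaluation protocol is 10 repetitions of stratified random 70/15/15
subsampling (a compromise rendering of a "10-fold 70/15/15" protocol,
which is self-contradictory as stated — reports label it as
subsampling). The validation part is merged into training by default;
it exists as a separate split for callers that want to use it for
variant selection. Classes with fewer than 7 instances cannot give all
three parts at least one instance and are reported unsplittable.

## Synthetic data

Each channel is a sum of four band-limited Gaussian noise carriers (unit
RMS, scaled per band and per rating), a 1/f background, and white sensor
noise; blinks are 0.4 s raised-cosine transients of 300–600 µV on
AF3/AF4 (and 0.6× on F7/F8). Defaults: carrier RMS θ 4, α 5, β 3,
γ 2 µV; background 3 µV; sensor noise 1.5 µV; blinks 2/min — amplitudes
chosen so that the composite stays far below the 100 µV rejection
threshold while blinks far exceed it, as in real recordings. The
default ("hard") signature encodes the reported liking correlates
qualitatively and with overlap: FC5 alpha multiplier rising 0.7→1.8 and
O1 broadband falling 1.4→0.6 from rating 1 to 5. The "separable"
signature spreads strong monotone multipliers over six frontal channels
(alpha), P7/P8 (beta) and O1/O2 (broadband) with a lower noise floor,
giving disjoint class-conditional band powers.

What passing synthetic tests show: that the pipeline's filtering,
masking, feature arithmetic, discretization and voting recover a known
rating-conditioned band-power structure end to end, and that accuracy
collapses to chance when labels are permuted. What they do not show:
performance on real EEG — real recordings have volume conduction,
non-stationarity, correlated channels, non-Gaussian artifacts and far
weaker, subject-specific liking correlates, none of which the generator
models. Published accuracies on real recordings are therefore not
reproduced here; the recordings they depend on are not available.

## Problem sizes

The end-to-end checks use 20 videos per rating class, 22 s each (3
windows per video, 300 windows total, 1267 features) — chosen as the
smallest configuration with comfortable per-class test counts
(9 windows per class per split, 450 test decisions over 10
repetitions). The discretizer-vs-enumeration check uses ≤ 12-point
datasets with ≤ 3 candidate cuts, where exhaustive enumeration is
exact. The worked example in the README uses 6 videos per class.

## Known limitations

* The optimized variant is one constructive reading of a behavioural
  description; other readings (e.g. different purity functionals) would
  also satisfy the subset property.
* Equal per-statistic vote weights assume feature independence; with
  1267 highly correlated features the vote is redundant, which the
  method tolerates but does not exploit.
* EDF import is read-only and untested against reference files (no EDF
  writer exists in the dependency set); CSV is the canonical format.
* Per-window degenerate spectra (all-floor PSD) are kept as floor
  values rather than dropping the window; only windows with < 2 clean
  samples are dropped.
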