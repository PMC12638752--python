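# Methods

This note documents the models, conventions and numerical choices behind
`ratstates`, and what the synthetic-data experiments do and do not show.

## Signal model and preprocessing

A recording is a `C × T` matrix in microvolts with sampling rate `fs`
(250 Hz throughout the examples) and a named montage; the built-in 19-
and 21-channel layouts mirror a rodent cortical-screw implantation
homologous to the human 10–20 set. Preprocessing follows standard
resting-state practice: average reference (instantaneous channel mean
subtracted), zero-phase band-pass 1–40 Hz via a windowed-sinc
(Hamming) FIR applied forward and backward (default 2000 coefficients —
an even count is bumped by one so the impulse response is symmetric;
two-pass filtering squares the magnitude response, so the effective
attenuation is twice the single-pass value in dB), then extraction of
annotated behavioural-inactivity intervals of at least 2 s, concatenated
without tapering. Seam transients are accepted because all clustering
operates on GFP peaks, not segment boundaries; an option to exclude
peaks near seams was considered and deliberately left out of the default
path to keep the sample bookkeeping exact.

## Microstate segmentation

* **GFP** is the *population* (ddof = 0) standard deviation across
  channels — for average-referenced data this equals the RMS amplitude —
  so a two-channel sample `[1, −1]` has GFP 1.
* **Peaks** are strict interior local maxima; a flat plateau counts once,
  at its first sample (deterministic, order-stable); plateaus touching an
  edge are discarded.
* **AAHC.** Peak maps start as singleton clusters. A cluster's GEV
  contribution equals the top eigenvalue of its GFP-weighted spatial
  scatter matrix divided by the total squared GFP, and its template is
  the corresponding eigenvector — the dominant spatial component, which
  is both the polarity-invariant mean and the GEV-optimal representative.
  Each step dissolves the cluster with the smallest contribution and
  reassigns its members by largest |Pearson r| to the surviving
  templates (ties to the lowest index). One model per K is snapshotted
  on the way down; the hierarchy is deterministic given the input order,
  and template signs are fixed so the largest-magnitude channel is
  positive. Exhaustive-enumeration checks at ≤ 12 peaks confirm the
  greedy attains the partition optimum when planted clusters have
  balanced total strength; with strongly unbalanced strengths it
  dissolves the weakest true cluster first — an inherent property of
  GEV-greedy agglomeration that the test suite documents rather than
  hides.
* **Backfitting** labels *all* samples (parameters are reported in
  seconds of coverage), with zero-GFP samples left unassigned and
  excluded from coverage denominators so coverages sum to one. No
  temporal smoothing or minimum-duration rejection is applied.
* **GEV** uses the spatial Pearson correlation `C_ik` (squared, so
  polarity cancels) and is computed over GFP-peak samples by default,
  with an all-samples option; both scopes are exposed because the
  convention differs between toolchains.
* **Durations** follow the halfway-boundary convention: runs begin and
  end midway between samples of different classes, and the recording
  edges sit half a sample outside the first/last sample, so an L-sample
  run lasts exactly `L/fs`. This makes coverage = occurrence × mean
  duration an identity rather than an approximation. Durations are
  exposed in both seconds and milliseconds, as both reporting
  conventions circulate in the literature.

## Transition structure

Observed transitions are run-to-run frequencies (self-transitions
impossible by construction), row-normalised. The occurrence-based null

    ExpTM(k1,k2) = (Occ(k1)/MeanOcc · Occ(k2)/MeanOcc) / (1 − Occ(k1)/MeanOcc)

is reported verbatim, but it is singular when a class's occurrence equals
the mean (+inf sentinel and a warning, never silently patched) and
negative when it exceeds the mean. Wherever the formula is regular,
row-normalising it gives off-diagonal entries proportional to `Occ(k2)`,
i.e. `Occ(k2)/(ΣOcc − Occ(k1))` — the standard no-self-transition chance
level — which stays well-defined everywhere; the observed-minus-expected
difference matrix therefore uses this row-stochastic form.

## Choosing K

All selection criteria operate on the polarity-invariant distance
`d(u, v) = 1 − |r(u, v)|`. Within-cluster dispersion W(K) is the sum over
clusters of size × mean pairwise squared distance. The preferred
criterion is Krzanowski–Lai,

    DIFF(K) = (K−1)^(2/m) W(K−1) − K^(2/m) W(K),  KL(K) = |DIFF(K)|/|DIFF(K+1)|,

with m = the number of channels as the feature dimension (maps live in
channel space); KL needs both neighbours, so endpoint K values are never
selectable and the dispersion curve is computed from K = 1. The CV
criterion is the predictive residual variance penalised by
`((C−1)/(C−1−K))²`; Davies–Bouldin, Dunn and Frey–Van Groenewoud use
their standard definitions on d; the metacriterion takes the median of
the per-criterion optima with ties resolved to the smaller K (its
composition is configurable — no canonical weighting exists). W(K) is
also reported directly as a "dispersion" column for inspection; it has
no argbest of its own.

## Surrogate validation

A surrogate rotates each channel circularly by an independent random
offset (one random cut; beginning and end blocks swapped) — the most
literal single-cut reading of temporal shuffling; a multi-cut policy is
available behind a flag. This preserves each channel's sample multiset
bit for bit while destroying instantaneous cross-channel topography.
Ten surrogates per recording is the default. By default a fresh model is
fitted per surrogate (backfitting the real model is available), because
refitting is the conservative choice: the surrogate gets its own best
chance to explain variance. Groups are screened with the scaled-MAD rule
(1.4826 × MAD, 3 MADs; a zero MAD disables the filter with a warning),
tested for normality with a one-sample KS test on z-scored values
(refused below 4 values rather than returning a meaningless p), and
compared with the two-sample KS test. GEVs are fractions internally;
percent only at presentation.

## Source association

The stage consumes source-space time series from any origin — inverse
modelling itself is out of scope; the toy scene generator provides
band-limited sources with a planted coupling, and `pca_orientation`
reduces three-orientation series for users bringing real inverse
solutions. Band-limited power is the analytic-signal magnitude after a
two-pass order-3 Butterworth band-pass (δ 2–4, θ 4–8, α 8–12, β 12–20 Hz,
broadband unfiltered). The per-source model

    BLP = β0 + β1·B_k + β2·GFP + β3·GMD + ε

is ordinary least squares at the full sampling rate (no envelope
smoothing by default), with `B_k(t) = |x_t · map_k|` the continuous
microstate regressor and GMD the RMS difference between consecutive
GFP-normalised topographies (0 identical, √2 orthogonal, 2 antipodal;
undefined across zero-GFP samples, and NaN GMD values enter the design
as 0). Group inference on β1 uses sign-flip permutations with TFCE
(E = 0.5, H = 2, 100 midpoint integration steps — the cited method's
standard parameters, stated here prominently because they are
conventions, not fitted values) over the source neighbourhood graph;
the corrected p-value of a source is the exceedance fraction of the
two-sided max-enhanced null with the +1 correction, at α = 0.001
two-sided by default. Statistical maps are summarised by the fraction of
significant sources and by Pearson correlations of mask-weighted t maps
on union supports, omitting maps with no significant source.

## Synthetic data

The generator emulates the structure microstate analysis assumes: a
semi-Markov label sequence (uniform off-diagonal transitions unless
specified; gamma dwell times with shape 2 and mean 0.1 s — strictly
positive and unimodal; the empirical dwell distribution of cortical
microstates is not established, so this is a modelling choice), an
amplitude envelope `A·|sin(2π·10 t)|·(1 + 0.3 sin(2π·0.17 t))` that
guarantees dense GFP peaks (~20 per second), planted zero-mean unit-norm
topographies (orthogonalised by default, with a controllable common
component to emulate the inter-correlated maps seen empirically), and
white sensor noise projected onto the average-reference subspace. SNR
is per-channel signal RMS over noise SD; the factory computes the noise
scale for a target SNR analytically. Everything is reproducible from
(parameters, seed).

What this does *not* emulate: movement and electrode artifacts, volume
conduction from a realistic head model, non-stationary band power,
1/f background structure, or gradual (non-instantaneous) topography
transitions. Passing tests therefore show the *algorithms* are correct
and well-calibrated under the assumed generative structure, not that
real rodent EEG satisfies that structure.

## Problem sizes and defaults used in the experiments

Template-recovery runs use a 120-s, 19-channel, SNR-5 recording (≈2400
GFP peaks); criterion-selection runs use twenty 60-s datasets; the
surrogate contrast uses thirty 30-s recordings with ten surrogates each;
GLM recovery uses 200 sources × 20 subjects at 60 s per subject; null
calibration uses 50 repetitions of 200 sign-flip permutations at a
nominal α of 0.05 (at α = 0.001 the expected false-positive count over
50 runs is 0.05, so the binomial check would be vacuous). The
acceptance script runs moderately smaller instances of the same
experiments, sized to complete in a few minutes on one CPU.

## Known limitations

* The greedy AAHC gap under unbalanced cluster strengths (above).
* The ExpTM formula's singular/negative regime is reported as-is; only
  the normalised difference matrix is safe to interpret throughout.
* EDF output quantises to 16 bits over the observed per-channel range;
  physical limits are rounded to their 8-character header
  representation before scaling, so the round-trip error is bounded by
  the quantisation step.
* The KS normality test uses estimated mean/SD (no Lilliefors
  correction); with the group sizes used here the p-values are
  indicative, and the decisive comparison is the two-sample test.
* Group-level clustering pools GFP peaks across recordings if callers
  concatenate them; an explicit subject→group two-stage hierarchy is not
  provided.
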