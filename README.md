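# ratstates

EEG microstate analysis for rodent recordings: segmentation of
multichannel EEG into quasi-stable topographic microstates, classical
microstate parameters and transition statistics, cluster-number
selection, surrogate-based validation, and association of microstate
time courses with frequency-specific source-space band power.

## Who this is for

Electrophysiologists analysing multichannel rodent (or other small-array)
EEG who want the standard human microstate toolchain — GFP-peak
clustering, backfitting, GEV, surrogate nulls — as a tested, scriptable
Python library rather than a GUI plugin. Real cortical-screw recordings
of this kind are rarely shared, so the package ships a synthetic-data
generator with known ground truth that makes every stage verifiable end
to end.

## The model

An average-referenced EEG sample `x_t ∈ R^C` is summarised by its global
field power, the population standard deviation across channels,
`GFP_t = std(x_t)`. At GFP peaks — the moments of strongest, most stable
topography — the topographies are clustered by atomize-and-agglomerate
hierarchical clustering (AAHC): every peak map starts as its own cluster,
and the cluster contributing least global explained variance is
repeatedly dissolved, its members reassigned by absolute spatial
(Pearson) correlation. Polarity is ignored throughout. The K templates
are backfitted to every sample (`L_t = argmax_k |r(x_t, map_k)|`), and
the segmentation is described by the classical parameters plus

    GEV_k  = Σ_i GFP_i² · C_ik² · δ(L_i = k)  /  Σ_i GFP_i²
    totGEV = Σ_k GEV_k

where `C_ik` is the spatial correlation between sample i and template k.
K is chosen with the Krzanowski–Lai criterion (plus CV, Davies–Bouldin,
Dunn, Frey–Van Groenewoud and a median-vote metacriterion); genuineness
of the topographic structure is checked by contrasting totGEV against
per-channel temporally shuffled surrogates; and each microstate's
continuous expression `B_k(t) = |x_t · map_k|` can be regressed against
band-limited source power (`BLP = β0 + β1 B_k + β2 GFP + β3 GMD + ε`)
with sign-flip permutation + TFCE group inference.

## Worked example

`examples/01_segment_microstates.py` simulates a 60-s, 19-channel
recording from a planted 5-state process (SNR 5), preprocesses it,
fits AAHC at K = 5 and prints:

```
per-class parameters (rows = microstates):
   gfp_mean  duration_s  duration_ms  occurrence_per_s  coverage  n_runs
0    1.1967      0.0184      18.4399           13.0333    0.2403   782.0
1    1.1940      0.0176      17.5591           12.4000    0.2177   744.0
2    1.2348      0.0180      17.9788           11.0167    0.1981   661.0
3    1.2852      0.0181      18.1367            9.2667    0.1681   556.0
4    1.2362      0.0172      17.2353           10.2000    0.1758   612.0

total GEV: 89.9 %   (fraction of GFP-weighted topographic variance explained)
planted-map recovery |r|: [0.966 0.966 0.968 0.968 0.97 ]
```

Each row is one recurring topography: coverage is its share of recording
time, occurrence its onsets per second, duration its mean dwell, and the
recovery line shows that the fitted templates match the planted ground
truth. The other examples walk through cluster-number selection
(`02`), surrogate validation (`03` — totGEV drops from ≈98 % to ≈40 % on
shuffled data, two-sample KS p = 1.7e-05 at that group size), source
association (`04`) and file round-trips (`05`).

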