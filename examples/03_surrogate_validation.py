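"""Validate microstate structure against temporally shuffled surrogates.

Each channel of a surrogate is circularly rotated by an independent
random offset, preserving its amplitude histogram exactly while
destroying cross-channel topography.  If microstates capture genuine
topographic structure, total GEV must drop sharply on surrogates.
"""

import ratstates as rs

FS = 250.0

recordings = []
for i in range(6):
    truth = rs.make_ground_truth(k=5, n_channels=19, snr=5.0, seed=20 + i)
    labels = rs.simulate_state_sequence(truth, 30.0, FS)
    recordings.append(rs.simulate_recording(truth, labels, FS))

contrast = rs.gev_contrast(recordings, model_k=5,
                           spec=rs.SurrogateSpec(n_repeats=4, seed=0))
s = contrast.summary()
print(f"real data:  totGEV = {100 * s['real_mean']:.2f} "
      f"± {100 * s['real_sd']:.2f} %")
print(f"surrogates: totGEV = {100 * s['surrogate_mean']:.2f} "
      f"± {100 * s['surrogate_sd']:.2f} %")
print(f"difference: {100 * s['mean_difference']:.2f} percentage points")
print(f"two-sample KS: D = {s['ks_two_sample']['statistic']:.3f}, "
      f"p = {s['ks_two_sample']['p']:.2e}")
print("\nA large GEV gap with a tiny p-value means the segmentation "
      "captures real\ncross-channel structure, not an artefact of the "
      "channels' spectra.")
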