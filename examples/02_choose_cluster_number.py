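"""Choose the number of microstate classes with the criterion battery.

Fits AAHC models for K = 1..10 on a synthetic dataset with 5 planted
topographies and prints the criterion table: within-cluster dispersion W,
the Krzanowski-Lai (KL) elbow score, cross-validation (CV),
Davies-Bouldin, Dunn and Frey-Van Groenewoud, plus the median-vote
metacriterion.
"""

import ratstates as rs

FS = 250.0

truth = rs.make_ground_truth(k=5, n_channels=19, snr=5.0, seed=7)
labels = rs.simulate_state_sequence(truth, 60.0, FS)
rec = rs.simulate_recording(truth, labels, FS)

models = rs.fit_recording(rec, 10, k_min=1)
gfp = rs.compute_gfp(rec)
peak_maps = rec.data[:, gfp.peak_indices].T
table = rs.score_models(peak_maps, gfp.values[gfp.peak_indices], models,
                        rec=rec)

print(table.to_frame().round(4).to_string())
print("\nper-criterion optima:", table.chosen_k)
print("metacriterion (median vote):", rs.metacriterion_select(table))
print("\nThe KL score spikes at the elbow of the dispersion curve; with "
      "5 planted maps the\nbattery should converge on K = 5.")
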