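"""Associate a microstate's time course with band-limited source power.

Builds one recording per subject, derives the continuous microstate
regressor B_k(t) = |x_t . map_k|, plants a coupling between that
regressor and the alpha-band envelope of a toy source scene, fits the
GLM BLP = b0 + b1 B_k + b2 GFP + b3 GMD per source, and runs the
group-level sign-flip permutation test with TFCE correction.
"""

import numpy as np

import ratstates as rs

FS = 250.0
N_SRC, N_SUBJ = 80, 12

rng = np.random.default_rng(3)
coupling = np.zeros(N_SRC)
coupling[:10] = 1.0  # one cluster of strongly coupled sources

betas = np.empty((N_SUBJ, N_SRC))
graph = None
for s in range(N_SUBJ):
    truth = rs.make_ground_truth(5, 19, 5.0, seed=200 + s)
    labels = rs.simulate_state_sequence(truth, 30.0, FS)
    rec = rs.simulate_recording(truth, labels, FS)
    model = rs.fit_recording(rec, 5)[5]
    regs = rs.build_regressors(rec, model)
    scene = rs.simulate_source_scene(N_SRC, "alpha", coupling, FS, 30.0,
                                     seed=300 + s, regressor=regs.b[0])
    blp = rs.band_envelope(scene.source_series, "alpha", FS)
    betas[s] = rs.fit_source_glm(blp, regs, 0).beta1
    graph = scene.neighbor_graph

stat = rs.group_permutation_test(betas, graph, alpha=0.01, n_perm=500,
                                 seed=4)
print(f"sources significant after TFCE correction: "
      f"{stat.signif_mask.sum()} / {N_SRC} "
      f"(cluster-size fraction {100 * stat.cluster_size_fraction:.1f} %)")
print(f"coupled sources recovered: "
      f"{stat.signif_mask[:10].sum()} / 10")
print(f"mean |beta1| coupled vs uncoupled: "
      f"{np.abs(betas.mean(0)[:10]).mean():.4f} vs "
      f"{np.abs(betas.mean(0)[10:]).mean():.4f}")
print("\nbeta1 measures how strongly a source's alpha-band power follows "
      "the microstate's\ncontinuous expression; TFCE + sign-flip "
      "permutations control the family-wise error.")

fractions, corr = rs.summarize_statmaps({("MS1", "alpha"): stat})
print("\ncluster-size fractions:", {k: round(v, 3)
                                    for k, v in fractions.items()})
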