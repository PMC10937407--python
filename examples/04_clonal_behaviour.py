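"""Clonal output activity and lineage biases over two timepoints.

Uses clone assignments and simulated cell states to measure each clone's
progeny output (normalised by stem-cell count) and test lineage biases
with exact binomial tests combined across timepoints.
"""

from mtlineage.clonal import clonal_output, lineage_bias
from mtlineage.simulate import SimConfig, simulate_dataset

cfg = SimConfig(n_clones=20, cells_per_clone=60, bias_alpha=0.5, seed=7)
truth, reads, states = simulate_dataset(cfg)

# use the simulated truth assignment directly: the propagation example
# shows how to obtain assignments from data
progeny = states[~states["is_hsc"]]
clone_sizes = states[states["is_hsc"]]["clone"].value_counts()
out = clonal_output(progeny[["clone"]], clone_sizes, states["timepoint"])
print(f"Pearson r of clonal output between timepoints: "
      f"{out['timepoint_pearson_r']:.2f}")
print(f"top-vs-bottom decile output fold change (t1): "
      f"{out['decile_fold_change'][1]:.1f}")

bias = lineage_bias(progeny[["clone"]], states["lineage"],
                    states["timepoint"])
n_biased = bias.loc[bias["biased"], "clone"].nunique()
print(f"{n_biased}/{clone_sizes.size} clones show a consistent lineage "
      "bias at FDR < 0.2 (direction agrees at both timepoints)")
print(bias[bias["biased"]][["clone", "lineage", "fc_t1", "fc_t2", "q",
                            "bias_class"]].head().to_string(index=False))
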