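"""Clonal diversity, coalescent expansion test and LOY detection.

Compares a polyclonal ("young") and an oligoclonal ("aged") simulated
population by Shannon diversity and expanded-clade fraction, then runs
loss-of-chromosome-Y detection on synthetic fragment counts.
"""

import numpy as np
import pandas as pd

from mtlineage.aging import (LOYConfig, detect_loy, expansion_test,
                             shannon_diversity)

rng = np.random.default_rng(7)

# polyclonal vs oligoclonal clone-size compositions
young_sizes = [40] * 50
aged_sizes = [600, 300, 150] + [20] * 47
print(f"Shannon index, young: {shannon_diversity(young_sizes):.2f} "
      f"(max for 50 clones = {np.log(50):.2f})")
print(f"Shannon index, aged:  {shannon_diversity(aged_sizes):.2f}")

# coalescent expansion test on clone-level (multifurcating) topologies:
# the sister comparison has no power on strictly binary nodes, so clone
# backbones are represented as multifurcations (see
# mtlineage.tree.collapse_short_branches for NJ trees)
from skbio import TreeNode


def clone_star_tree(sizes):
    clades = []
    c = 0
    for s in sizes:
        leaves = ",".join(f"c{c + i}:1" for i in range(s))
        clades.append(f"({leaves}):1")
        c += s
    return TreeNode.read([f"({','.join(clades)});"])


res_y = expansion_test(clone_star_tree(young_sizes))
res_a = expansion_test(clone_star_tree(aged_sizes))
print(f"cells in expanded clades (p < 0.01, >= 5% of cells): "
      f"young {res_y['fraction_expanded']:.1%}, "
      f"aged {res_a['fraction_expanded']:.1%}")

# LOY: 3% of cells with zero chrY fragments at an expected fraction 0.004
n_cells = 2000
totals = rng.integers(2000, 15000, n_cells)
loy_true = rng.random(n_cells) < 0.03
ys = np.where(loy_true, 0, rng.binomial(totals, 0.004))
frags = pd.DataFrame({
    "cell": np.repeat([f"c{i}" for i in range(n_cells)], 2),
    "chrom": ["chrY", "chr_rest"] * n_cells,
    "n_fragments": np.column_stack([ys, totals - ys]).ravel()})
calls = detect_loy(frags, LOYConfig())
print(f"LOY calls: {int(calls['loy'].sum())} of {n_cells} cells "
      f"({loy_true.sum()} simulated LOY cells)")
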