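"""Trace the shrinkage path: how the surviving-gene count and cross-validated
accuracy change as the shrinkage threshold delta grows.

Larger delta shrinks more standardized class differences to zero, so fewer
genes survive; accuracy stays high as long as the informative genes remain.
"""

from tgxddi import SimulationSpec, shrinkage_path, simulate_reference_set

spec = SimulationSpec(n_ddi=11, n_nonddi=17, n_genes=500, n_informative=20,
                      effect=3.0, sigma=0.3, seed=42)
matrix, labels, informative = simulate_reference_set(spec)
table = shrinkage_path(matrix, labels, deltas=[0, 1, 2, 4, 6, 8, 10], k=10, seed=42)
print(table.to_string(index=False))
print(f"\n{len(informative)} genes carry planted signal; the surviving count "
      "plateaus near that value over the deltas where CV accuracy is perfect.")
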