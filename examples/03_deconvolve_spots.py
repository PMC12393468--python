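"""Estimate per-spot cell-type fractions and allocate counts to types.

Builds reference profiles phi from labeled cells, runs the multinomial-
mixture EM per spot, and re-allocates each spot's counts into cell-type-
specific expression Z with exact count conservation.
"""

import numpy as np

from spotcell import (
    TissueConfig, build_reference, deconvolve_all,
    generate_reference_cells, generate_tissue,
)
from spotcell.deconv import filter_reference_genes

config = TissueConfig()
spots_list, truth = generate_tissue(config, samples_per_group=1, seed=3)
cells, labels, genes = generate_reference_cells(config, 200, seed=4)
panel = filter_reference_genes(build_reference(cells, labels, genes))

sm = spots_list[0]
result = deconvolve_all(sm, panel)

order = [panel.cell_types.index(ct) for ct in truth.cell_types]
est = result.theta[:, order]
true = truth.samples[sm.sample_id].theta
r = np.mean([np.corrcoef(est[i], true[i])[0, 1] for i in range(sm.n_spots)])
rmse = np.sqrt(((est - true) ** 2).mean())
print(f"{sm.n_spots} spots deconvolved ({result.method})")
print(f"mean per-spot Pearson r vs truth: {r:.3f}; RMSE: {rmse:.3f}")

gi = {g: i for i, g in enumerate(sm.gene_ids)}
x = sm.counts[:, [gi[g] for g in result.gene_ids]]
err = np.abs(result.allocations.sum(axis=1) - x).max()
print(f"max |sum_k Z - x| over all spots and genes: {err:.2e}")
# r near 1 and RMSE well under 0.05 mean the EM recovers the simulated
# composition; the conservation error is at float precision because the
# allocation is a conditional expectation that splits each observed count.
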