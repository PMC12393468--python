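"""Concentric vessel-proximity rings and proximal-vs-distal DGE.

Spots are binned by distance to the nearest vascular (VAS) spot: level 1
within 200 px (~um), 2 in (200, 400], 3 in (400, 600], 4 beyond.  The ring
DGE contrasts level 1 against level 3 pseudo-cells of one type per group,
recovering the planted AD-only astrocyte gradient.
"""

import numpy as np

from spotcell import (
    TissueConfig, build_psm, build_reference, deconvolve_all,
    generate_reference_cells, generate_tissue, qc_filter,
)
from spotcell.context import ring_dge, ring_levels
from spotcell.deconv import filter_reference_genes
from spotcell.psm import PseudoCellMatrix, concat_psm

config = TissueConfig()
spots_list, truth = generate_tissue(config, samples_per_group=1, seed=9)
cells, labels, genes = generate_reference_cells(config, 200, seed=10)
panel = filter_reference_genes(build_reference(cells, labels, genes))

parts = []
for sm in spots_list:
    ra = ring_levels(sm)
    lv, ct_ = np.unique(ra.level, return_counts=True)
    if sm.group == "AD":
        print(f"{sm.sample_id} ring occupancy:", dict(zip(lv, ct_)))
    parts.append(build_psm(deconvolve_all(sm, panel), sm, 0.02, levels=ra.level))
psm = qc_filter(concat_psm(parts), min_genes=30, min_cells=3)

grad = truth.vessel_gradient
for group in ("AD", "AC"):
    mask = (psm.meta["group"] == group).to_numpy()
    sub = PseudoCellMatrix(
        counts=psm.counts[mask], fractional=psm.fractional[mask],
        gene_ids=psm.gene_ids, meta=psm.meta.loc[mask].reset_index(drop=True),
    )
    table = ring_dge(sub, grad.cell_type, "1", "3")
    row = table.set_index("gene").loc[grad.gene]
    print(f"{group} {grad.cell_type} level 1 vs 3, {grad.gene}: "
          f"log2FC {row['log2FC']:.2f}, p_adj {row['p_adj']:.2e}")
# The gradient gene is upregulated near vessels only in the AD group, so
# the AD contrast is strongly significant while AC stays at the null.
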