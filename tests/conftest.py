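"""Shared fixtures: one default synthetic study reused across the suite.

The heavy objects (tissue, reference, deconvolution results, annotated PSM)
are session-scoped so parameter-recovery tests and acceptance checks share
a single simulation at the default study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from spotcell import deconv, psm as psm_mod, simulate
from spotcell import context as ctx
from spotcell.io import build_reference


@pytest.fixture(scope="session")
def default_config():
    return simulate.TissueConfig()


@pytest.fixture(scope="session")
def tissue(default_config):
    """Six default samples (two per group) plus ground truth."""
    return simulate.generate_tissue(default_config, samples_per_group=2, seed=101)


@pytest.fixture(scope="session")
def reference(default_config):
    counts, labels, genes = simulate.generate_reference_cells(
        default_config, n_cells_per_type=200, seed=102
    )
    return counts, labels, genes


@pytest.fixture(scope="session")
def panel(reference, default_config):
    counts, labels, genes = reference
    return deconv.filter_reference_genes(
        build_reference(counts, labels, genes), max_fraction=0.1
    )


@pytest.fixture(scope="session")
def deconv_results(tissue, panel):
    spots_list, _ = tissue
    return {sm.sample_id: deconv.deconvolve_all(sm, panel) for sm in spots_list}


@pytest.fixture(scope="session")
def type_order(tissue, panel):
    """Permutation aligning panel cell-type order to the truth's order."""
    _, truth = tissue
    return np.asarray([panel.cell_types.index(ct) for ct in truth.cell_types])


@pytest.fixture(scope="session")
def annotated_psm(tissue, panel, deconv_results):
    """QC'd and annotated pseudo-cell matrix over all six samples."""
    spots_list, truth = tissue
    parts = []
    for sm in spots_list:
        ra = ctx.ring_levels(sm)
        parts.append(
            psm_mod.build_psm(
                deconv_results[sm.sample_id], sm, min_theta=0.02, levels=ra.level
            )
        )
    full = psm_mod.concat_psm(parts)
    filtered = psm_mod.qc_filter(full, min_genes=30, min_cells=3)
    marker_sets = {ct: list(g) for ct, g in truth.marker_genes.items()}
    annotated, confusion = psm_mod.cluster_annotate(
        filtered, panel, marker_sets, seed=103
    )
    return annotated, confusion
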