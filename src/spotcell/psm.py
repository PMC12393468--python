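"""Pseudo-single-cell matrix (PSM) construction, QC and annotation.

Each deconvolved spot is exploded into one pseudo-cell per cell type whose
estimated fraction clears a small floor; the pseudo-cell's counts are the
type's allocated expression, rounded half-up (the fractional allocation is
retained alongside for statistics that do not need integers).  QC follows
the cells-then-genes rule: drop cells with too few detected genes, then
genes detected in too few remaining cells, in a single pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .deconv import DeconvolutionResult
from .domains import normalize_expression
from .io import ReferencePanel, SpotMatrix


@dataclass
class PseudoCellMatrix:
    """Exploded cells x genes matrix with per-cell provenance."""

    counts: np.ndarray
    fractional: np.ndarray
    gene_ids: np.ndarray
    meta: pd.DataFrame  # cell_id, spot_id, type_origin, type_inferred, domain, sample_id, group, level, theta

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.meta):
            raise ValueError("meta length mismatch with counts rows")
        if self.meta["cell_id"].duplicated().any():
            raise ValueError("cell_id must be unique")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes_detected(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=1)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def build_psm(
    result: DeconvolutionResult,
    spots: SpotMatrix,
    min_theta: float = 0.02,
    levels=None,
) -> PseudoCellMatrix:
    """Explode one sample's deconvolution result into pseudo-cells.

    A pseudo-cell is emitted for every (spot, type) with theta >= min_theta;
    metadata (domain, group, ring level when supplied) is copied from the
    spot.
    """
    if not 0 <= min_theta < 1:
        raise ValueError("min_theta must lie in [0, 1)")
    rows, frac_rows, meta = [], [], []
    domain = spots.domain if spots.domain is not None else np.full(
        spots.n_spots, "UNASSIGNED", dtype=object
    )
    for s in range(len(result.spot_ids)):
        for k, ct in enumerate(result.cell_types):
            th = result.theta[s, k]
            if th < min_theta or th == 0:
                continue
            z = result.allocations[s, k, :]
            frac_rows.append(z)
            rows.append(_round_half_up(z))
            meta.append(
                {
                    "cell_id": f"{result.spot_ids[s]}|{ct}",
                    "spot_id": result.spot_ids[s],
                    "type_origin": ct,
                    "type_inferred": "",
                    "domain": domain[s],
                    "sample_id": spots.sample_id,
                    "group": spots.group,
                    "level": "" if levels is None else levels[s],
                    "theta": float(th),
                }
            )
    counts = (
        np.vstack(rows) if rows else np.zeros((0, len(result.gene_ids)), dtype=np.int64)
    )
    frac = (
        np.vstack(frac_rows) if frac_rows else np.zeros((0, len(result.gene_ids)))
    )
    return PseudoCellMatrix(
        counts=counts,
        fractional=frac,
        gene_ids=result.gene_ids,
        meta=pd.DataFrame(
            meta,
            columns=[
                "cell_id", "spot_id", "type_origin", "type_inferred",
                "domain", "sample_id", "group", "level", "theta",
            ],
        ),
    )


def concat_psm(parts: list[PseudoCellMatrix]) -> PseudoCellMatrix:
    if not parts:
        raise ValueError("no PSM parts to concatenate")
    gene_ids = parts[0].gene_ids
    for p in parts[1:]:
        if not np.array_equal(p.gene_ids, gene_ids):
            raise ValueError("PSM parts have different gene universes")
    return PseudoCellMatrix(
        counts=np.vstack([p.counts for p in parts]),
        fractional=np.vstack([p.fractional for p in parts]),
        gene_ids=gene_ids,
        meta=pd.concat([p.meta for p in parts], ignore_index=True),
    )


def qc_filter(
    psm: PseudoCellMatrix, min_genes: int = 300, min_cells: int = 3
) -> PseudoCellMatrix:
    """Single-pass QC: cells with < min_genes detected genes are dropped
    first, then genes detected in < min_cells of the remaining cells."""
    if min_genes < 0 or min_cells < 0:
        raise ValueError("QC thresholds must be >= 0")
    keep_cells = psm.n_genes_detected >= min_genes
    if not keep_cells.any():
        raise ValueError(
            "QC removed every pseudo-cell; review min_genes against the gene "
            "universe size"
        )
    counts = psm.counts[keep_cells]
    keep_genes = (counts > 0).sum(axis=0) >= min_cells
    return PseudoCellMatrix(
        counts=counts[:, keep_genes],
        fractional=psm.fractional[keep_cells][:, keep_genes],
        gene_ids=psm.gene_ids[keep_genes],
        meta=psm.meta.loc[keep_cells].reset_index(drop=True),
    )


def cluster_annotate(
    psm: PseudoCellMatrix,
    panel: ReferencePanel,
    marker_sets: dict,
    seed: int = 0,
):
    """Cluster pseudo-cells into K = n_types groups and name each cluster.

    Pseudo-cells are normalized, z-scored per gene, summarized as a per-cell
    vector of mean marker scores (one feature per reference type), and
    clustered by seeded k-means in that score space; each cluster is then
    assigned the type with the highest mean z-scored marker score.  Marker
    scores rather than raw-gene principal components drive the clustering
    because pseudo-cells of low-fraction types carry small libraries whose
    gene-level noise swamps a Euclidean embedding.  Returns the annotated
    PSM (``type_inferred`` filled) and the origin-vs-inferred confusion
    matrix.
    """
    K = panel.n_types
    gene_index = {g: i for i, g in enumerate(psm.gene_ids)}
    usable: dict = {}
    for ct, genes in marker_sets.items():
        present = [g for g in genes if g in gene_index]
        dropped = set(genes) - set(present)
        if dropped:
            warnings.warn(
                f"marker genes absent from PSM for {ct!r}: {sorted(dropped)}",
                stacklevel=2,
            )
        if not present:
            raise ValueError(f"all marker genes of type {ct!r} absent from PSM")
        usable[ct] = present

    totals = psm.counts.sum(axis=1)
    nz = totals > 0
    if not nz.all():
        raise ValueError("pseudo-cells with zero counts present; run qc_filter first")
    logn = normalize_expression(psm.counts)
    sd = logn.std(axis=0)
    z = (logn - logn.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    types = sorted(usable)
    scores = np.column_stack(
        [z[:, [gene_index[g] for g in usable[ct]]].mean(axis=1) for ct in types]
    )
    labels = KMeans(n_clusters=K, random_state=seed, n_init=10).fit_predict(scores)

    mapping = {}
    for c in np.unique(labels):
        mask = labels == c
        cluster_scores = scores[mask].mean(axis=0)
        mapping[int(c)] = types[int(np.argmax(cluster_scores))]
    inferred = np.asarray([mapping[int(c)] for c in labels], dtype=object)
    meta = psm.meta.copy()
    meta["type_inferred"] = inferred
    annotated = PseudoCellMatrix(
        counts=psm.counts, fractional=psm.fractional, gene_ids=psm.gene_ids, meta=meta
    )
    confusion = pd.crosstab(
        meta["type_origin"], meta["type_inferred"], dropna=False
    )
    return annotated, confusion
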