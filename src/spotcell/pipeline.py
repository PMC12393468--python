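"""End-to-end orchestration of the spot-to-pseudo-cell analysis.

``run(config, outdir)`` executes: simulate (or load) -> spatial domains ->
deconvolution -> vessel rings -> pseudo-cell matrix + QC -> marker / DGE /
composition / unique-set statistics -> communication networks (inter-
subregion with distance decay; cell-cell per ring level) -> ring DGE ->
optional split-half consistency benchmark, writing deterministic TSV report
tables, a manifest and a log.  Identical config + seed give byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import context as ctx
from . import deconv, domains, psm as psm_mod, simulate, stats
from .io import (
    LRTable,
    SpotMatrix,
    build_reference,
    read_lr_table,
    read_spot_matrix,
    write_lr_table,
    write_spot_matrix,
    write_table,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All pipeline settings; mirrors the structured YAML config file."""

    mode: str = "simulate"
    tissue: simulate.TissueConfig = field(default_factory=simulate.TissueConfig)
    samples_per_group: int = 2
    n_reference_cells: int = 200
    # spatial domains
    k_range: tuple = (8, 10, 12, 14)
    beta: float = 1.0
    n_hvg: int = 2000
    n_pcs: int = 20
    m_neighbors: int = 6
    # deconvolution / PSM
    ref_max_fraction: float = 0.1
    min_theta: float = 0.02
    qc_min_genes: int = 30  # scaled to the synthetic gene universe; 300 genome-wide
    qc_min_cells: int = 3
    # rings & communication
    ring_radii: tuple = (200.0, 400.0, 600.0)
    Kh: float = 0.5
    trim: float = 0.1
    n_perm: int = 100
    # consistency benchmark
    run_consistency: bool = True
    n_splits: int = 4
    # load-mode inputs
    sample_dirs: tuple = ()  # entries: (dir, sample_id, group)
    reference_dir: str = ""
    lr_table_path: str = ""
    marker_sets_path: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.tissue, dict):
            self.tissue = simulate.TissueConfig(**self.tissue)
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        r1, r2, r3 = self.ring_radii
        if not 0 < r1 < r2 < r3:
            raise ValueError("ring radii must be strictly increasing")
        for name in ("min_theta", "qc_min_genes", "qc_min_cells", "beta", "trim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed is None:
            raise ValueError("seed must be set")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "tissue" in data and isinstance(data["tissue"], dict):
            t = data["tissue"]
            for key in ("domain_bands", "group_effects"):
                if key in t and t[key] is not None:
                    t[key] = tuple(
                        simulate.GroupEffect(**e) if key == "group_effects" and isinstance(e, dict) else tuple(e) if isinstance(e, list) else e
                        for e in t[key]
                    )
            if isinstance(t.get("vessel_gradient"), dict):
                g = t["vessel_gradient"]
                g["multipliers"] = tuple(g.get("multipliers", (4.0, 2.5, 1.5, 1.0)))
                t["vessel_gradient"] = simulate.VesselGradient(**g)
        return cls(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stage-name hashed)."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Input acquisition
# ---------------------------------------------------------------------------

def acquire_inputs(config: PipelineConfig):
    """Simulate or load: returns (spots_list, ref_counts, ref_labels,
    ref_gene_ids, lr_table, marker_sets, cell_marker_sets, truth_or_None)."""
    if config.mode == "simulate":
        tissue = config.tissue
        spots_list, truth = simulate.generate_tissue(
            tissue,
            samples_per_group=config.samples_per_group,
            seed=stage_seed(config.seed, "tissue"),
        )
        ref_counts, ref_labels, gene_ids = simulate.generate_reference_cells(
            tissue,
            n_cells_per_type=config.n_reference_cells,
            seed=stage_seed(config.seed, "reference"),
        )
        lr_table = default_lr_table(tissue)
        marker_sets = simulate.domain_marker_sets(tissue)
        cell_markers = {
            ct: list(genes) for ct, genes in truth.marker_genes.items()
        }
        return spots_list, ref_counts, ref_labels, gene_ids, lr_table, marker_sets, cell_markers, truth
    # load mode
    spots_list = []
    for entry in config.sample_dirs:
        d, sid, group = entry
        spots_list.append(
            read_spot_matrix(
                os.path.join(d, "matrix.mtx"),
                os.path.join(d, "barcodes.tsv"),
                os.path.join(d, "features.tsv"),
                os.path.join(d, "tissue_positions.csv"),
                sample_id=sid,
                group=group,
            )
        )
    if not spots_list:
        raise ValueError("load mode requires sample_dirs")
    ref_counts, ref_labels, gene_ids = load_reference(config.reference_dir)
    lr_table = read_lr_table(config.lr_table_path)
    marker_sets = read_marker_sets(config.marker_sets_path)
    return spots_list, ref_counts, ref_labels, gene_ids, lr_table, marker_sets, None, None


def default_lr_table(tissue: simulate.TissueConfig) -> LRTable:
    """A synthetic LR table wired to the planted gene structure.

    The NT pair runs from the DG program gene to the CA4 program gene (the
    planted directional signal); the PTN pair targets a two-subunit vascular
    receptor; GAS and PDGF connect vascular markers to astrocyte markers for
    the per-ring cell-cell networks.
    """
    from .io import LREntry

    entries = [
        LREntry("NT", "prog-DG", ["prog-CA4"], "prog-DG-prog-CA4"),
        LREntry("PTN", "prog-SUB", ["VC-mk01", "VC-mk02"], "prog-SUB-(VC-mk01+VC-mk02)"),
        LREntry("GAS", "VC-mk03", ["Ast-mk01"], "VC-mk03-Ast-mk01"),
        LREntry("PDGF", "VC-mk04", ["Ast-mk02"], "VC-mk04-Ast-mk02"),
    ]
    return LRTable(entries=entries)


def load_reference(ref_dir):
    from scipy import io as spio

    counts = np.asarray(spio.mmread(os.path.join(ref_dir, "cell_counts.mtx")).todense())
    labels = pd.read_csv(
        os.path.join(ref_dir, "cell_labels.tsv"), header=None, sep="\t"
    )[0].to_numpy(dtype=object)
    genes = pd.read_csv(os.path.join(ref_dir, "genes.tsv"), header=None, sep="\t")[
        0
    ].to_numpy(dtype=object)
    return counts.astype(np.int64), labels, genes


def read_marker_sets(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        row["domain"]: row["genes"].split(";") for _, row in df.iterrows()
    }


def write_marker_sets(marker_sets: dict, path) -> None:
    rows = [
        {"domain": dom, "genes": ";".join(genes)}
        for dom, genes in sorted(marker_sets.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_simulation(config: PipelineConfig, outdir) -> None:
    """Write the simulated inputs as the Visium-convention file sets plus
    reference, LR table, marker sets and ground truth (CLI stage isolation)."""
    from scipy import io as spio
    from scipy import sparse

    (spots_list, ref_counts, ref_labels, gene_ids, lr_table, marker_sets,
     cell_markers, truth) = acquire_inputs(config)
    os.makedirs(outdir, exist_ok=True)
    info = []
    for sm in spots_list:
        d = os.path.join(outdir, "samples", sm.sample_id)
        write_spot_matrix(sm, d)
        info.append({"sample_id": sm.sample_id, "group": sm.group, "dir": d})
    write_table(pd.DataFrame(info), os.path.join(outdir, "sample_info.tsv"),
                key_columns=["sample_id"])
    ref_dir = os.path.join(outdir, "reference")
    os.makedirs(ref_dir, exist_ok=True)
    spio.mmwrite(
        os.path.join(ref_dir, "cell_counts.mtx"),
        sparse.coo_matrix(ref_counts),
        field="integer",
    )
    pd.Series(ref_labels).to_csv(
        os.path.join(ref_dir, "cell_labels.tsv"), index=False, header=False, sep="\t"
    )
    pd.Series(gene_ids).to_csv(
        os.path.join(ref_dir, "genes.tsv"), index=False, header=False, sep="\t"
    )
    write_lr_table(lr_table, os.path.join(outdir, "lr_pairs.tsv"))
    write_marker_sets(marker_sets, os.path.join(outdir, "marker_sets.tsv"))
    if cell_markers is not None:
        write_marker_sets(cell_markers, os.path.join(outdir, "cell_markers.tsv"))
    if truth is not None:
        simulate.truth_report(truth, os.path.join(outdir, "truth"))


# ---------------------------------------------------------------------------
# Stages (in-memory)
# ---------------------------------------------------------------------------

def domain_stage(spots_list, marker_sets, config: PipelineConfig):
    assigned, model, curve = domains.assign_domains(
        spots_list,
        marker_sets,
        k_range=list(config.k_range),
        beta=config.beta,
        n_hvg=config.n_hvg,
        d=config.n_pcs,
        m_neighbors=config.m_neighbors,
        seed=stage_seed(config.seed, "domains"),
    )
    rows = []
    offset = 0
    for sm in spots_list:
        for i in range(sm.n_spots):
            rows.append(
                {
                    "spot_id": sm.spot_ids[i],
                    "sample_id": sm.sample_id,
                    "cluster": int(model.labels[offset + i]),
                    "domain": assigned[offset + i],
                }
            )
        offset += sm.n_spots
    return pd.DataFrame(rows), model, pd.DataFrame(curve)


def deconvolve_stage(spots_list, ref_counts, ref_labels, gene_ids, config: PipelineConfig):
    panel = build_reference(ref_counts, ref_labels, gene_ids)
    panel = deconv.filter_reference_genes(panel, config.ref_max_fraction)
    results = {sm.sample_id: deconv.deconvolve_all(sm, panel) for sm in spots_list}
    rows = []
    for sm in spots_list:
        res = results[sm.sample_id]
        for i, spot in enumerate(res.spot_ids):
            rec = {"spot_id": spot, "sample_id": sm.sample_id}
            rec.update(
                {ct: res.theta[i, k] for k, ct in enumerate(res.cell_types)}
            )
            rows.append(rec)
    return panel, results, pd.DataFrame(rows)


def rings_stage(spots_list, config: PipelineConfig):
    rings = {}
    rows = []
    for sm in spots_list:
        ra = ctx.ring_levels(sm, config.ring_radii)
        rings[sm.sample_id] = ra
        for i in range(sm.n_spots):
            rows.append(
                {
                    "spot_id": ra.spot_ids[i],
                    "sample_id": sm.sample_id,
                    "distance_px": ra.distance_px[i],
                    "level": ra.level[i],
                }
            )
    return rings, pd.DataFrame(rows)


def psm_stage(results, spots_list, rings, panel, cell_markers, config: PipelineConfig):
    parts = []
    for sm in spots_list:
        parts.append(
            psm_mod.build_psm(
                results[sm.sample_id],
                sm,
                min_theta=config.min_theta,
                levels=rings[sm.sample_id].level,
            )
        )
    full = psm_mod.concat_psm(parts)
    filtered = psm_mod.qc_filter(full, config.qc_min_genes, config.qc_min_cells)
    annotated, confusion = psm_mod.cluster_annotate(
        filtered, panel, cell_markers, seed=stage_seed(config.seed, "psm")
    )
    return annotated, confusion


def dge_stage(spots_list, domain_df, results, psm_matrix, config: PipelineConfig):
    """Spot-level domain markers, composition tests and pseudo-cell
    unique-upregulation sets for the soma-layer Exc populations."""
    counts = np.vstack([sm.counts for sm in spots_list])
    gene_ids = spots_list[0].gene_ids
    dom = domain_df["domain"].to_numpy(dtype=object)
    marker_rows = []
    for d in sorted(set(dom)):
        if d == "UNASSIGNED" or (dom == d).sum() < 2 or (dom != d).sum() < 2:
            continue
        table = stats.rank_markers(counts, dom, d, gene_ids)
        gene = stats.pick_domain_marker(table)
        best = table.loc[table["gene"] == gene].iloc[0] if gene is not None else None
        marker_rows.append(
            {
                "domain": d,
                "marker": gene if gene is not None else "",
                "log2FC": float(best["log2FC"]) if best is not None else np.nan,
                "p_adj": float(best["p_adj"]) if best is not None else np.nan,
            }
        )
    markers_df = pd.DataFrame(marker_rows)

    theta = np.vstack([results[sm.sample_id].theta for sm in spots_list])
    groups = np.concatenate(
        [np.repeat(sm.group, sm.n_spots) for sm in spots_list]
    )
    cell_types = results[spots_list[0].sample_id].cell_types
    # composition tests only where every group has >= 2 spots in the domain
    group_names = sorted(set(groups))
    valid = np.isin(
        dom,
        [
            d
            for d in sorted(set(dom))
            if d != "UNASSIGNED"
            and all(((dom == d) & (groups == g)).sum() >= 2 for g in group_names)
        ],
    )
    composition_df = stats.composition_test(
        theta[valid], dom[valid], groups[valid], cell_types
    )

    unique_rows = []
    meta = psm_matrix.meta
    for d in simulate.SOMA_DOMAINS:
        for ct in ("Exc",):
            mask = (meta["domain"] == d) & (meta["type_origin"] == ct)
            if mask.sum() < 6:
                continue
            sub_groups = meta.loc[mask, "group"].to_numpy(dtype=object)
            if min((sub_groups == g).sum() for g in ("AC", "PART", "AD")) < 2:
                continue
            tables = stats.pairwise_group_dge(
                psm_matrix.counts[mask.to_numpy()],
                sub_groups,
                psm_matrix.gene_ids,
                groups=["AC", "PART", "AD"],
            )
            sets = stats.unique_up_sets(tables)
            for g, genes in sets.items():
                for gene in sorted(genes):
                    unique_rows.append(
                        {"domain": d, "cell_type": ct, "group": g, "gene": gene}
                    )
    unique_df = pd.DataFrame(
        unique_rows, columns=["domain", "cell_type", "group", "gene"]
    )
    return markers_df, composition_df, unique_df


def communication_stage(spots_list, domain_df, psm_matrix, lr_table, config: PipelineConfig):
    """Inter-subregion networks per group (distance decay) and cell-cell
    networks per group per ring level (no spatial covariate)."""
    lr_genes = sorted(lr_table.genes())
    gene_ids = spots_list[0].gene_ids
    gidx = [i for i, g in enumerate(gene_ids) if g in set(lr_genes)]
    dom_all = domain_df["domain"].to_numpy(dtype=object)
    seed0 = stage_seed(config.seed, "communication")

    inter_rows = []
    node_rows = []
    offset = 0
    by_group: dict = {}
    for sm in spots_list:
        by_group.setdefault(sm.group, []).append(
            (sm, dom_all[offset : offset + sm.n_spots])
        )
        offset += sm.n_spots
    for gi, (group, members) in enumerate(sorted(by_group.items())):
        counts = np.vstack([sm.counts for sm, _ in members])
        # normalize on the full universe, then restrict to LR genes
        logn = domains.normalize_expression(counts)[:, gidx]
        labels = np.concatenate([d for _, d in members])
        coords = np.vstack(
            [np.column_stack([sm.x, sm.y]) for sm, _ in members]
        )
        sample_ids = np.concatenate(
            [np.repeat(sm.sample_id, sm.n_spots) for sm, _ in members]
        )
        keep = labels != "UNASSIGNED"
        net = ctx.permutation_significance(
            logn[keep],
            labels[keep],
            _restrict_lr(lr_table),
            gene_ids=[gene_ids[i] for i in gidx],
            coords=coords[keep],
            mode="inter_subregion",
            n_perm=config.n_perm,
            seed=seed0 + gi,
            sample_ids=sample_ids[keep],
            Kh=config.Kh,
            trim=config.trim,
            normalized=True,
        )
        e = net.entries.copy()
        e.insert(0, "group", group)
        inter_rows.append(e)
        nd = net.nodes.copy()
        nd.insert(0, "group", group)
        node_rows.append(nd)
    inter_df = pd.concat(inter_rows, ignore_index=True)
    nodes_df = pd.concat(node_rows, ignore_index=True)

    cc_rows = []
    meta = psm_matrix.meta
    pgidx = [i for i, g in enumerate(psm_matrix.gene_ids) if g in set(lr_genes)]
    for gi, group in enumerate(sorted(meta["group"].unique())):
        for li, level in enumerate(("1", "3")):
            mask = (meta["group"] == group) & (meta["level"].astype(str) == level)
            if mask.sum() < 30:
                continue
            sub = psm_matrix.counts[mask.to_numpy()]
            nzc = sub.sum(axis=1) > 0
            labels = meta.loc[mask, "type_origin"].to_numpy(dtype=object)[nzc]
            if len(set(labels)) < 2:
                continue
            logn = domains.normalize_expression(sub[nzc])[:, pgidx]
            net = ctx.permutation_significance(
                logn,
                labels,
                _restrict_lr(lr_table),
                gene_ids=[psm_matrix.gene_ids[i] for i in pgidx],
                mode="cell_cell",
                n_perm=config.n_perm,
                seed=seed0 + 100 + 10 * gi + li,
                Kh=config.Kh,
                trim=config.trim,
                normalized=True,
            )
            e = net.entries.copy()
            e.insert(0, "level", level)
            e.insert(0, "group", group)
            cc_rows.append(e)
    cc_df = (
        pd.concat(cc_rows, ignore_index=True)
        if cc_rows
        else pd.DataFrame(
            columns=["group", "level", "pair_name", "pathway", "sender",
                     "receiver", "L", "R", "raw", "strength", "p_raw", "p_adj"]
        )
    )
    return inter_df, nodes_df, cc_df


def _restrict_lr(lr_table: LRTable) -> LRTable:
    return lr_table


def ring_dge_stage(psm_matrix, config: PipelineConfig, cell_types=("Ast", "Exc")):
    rows = []
    meta = psm_matrix.meta
    for group in sorted(meta["group"].unique()):
        gmask = meta["group"] == group
        sub = psm_mod.PseudoCellMatrix(
            counts=psm_matrix.counts[gmask.to_numpy()],
            fractional=psm_matrix.fractional[gmask.to_numpy()],
            gene_ids=psm_matrix.gene_ids,
            meta=meta.loc[gmask].reset_index(drop=True),
        )
        for ct in cell_types:
            try:
                table = ctx.ring_dge(sub, ct, "1", "3")
            except ValueError:
                continue
            table = table.rename(columns={"group": "target_level"})
            table.insert(0, "cell_type", ct)
            table.insert(0, "group", group)
            rows.append(table)
    if not rows:
        return pd.DataFrame(
            columns=["group", "cell_type", "gene", "log2FC", "p", "p_adj"]
        )
    return pd.concat(rows, ignore_index=True)


def consistency_stage(ref_counts, ref_labels, gene_ids, spots_list, panel, results, config: PipelineConfig):
    sm = spots_list[0]
    per_split, mean_corr = deconv.split_half_consistency(
        ref_counts,
        ref_labels,
        sm,
        gene_ids,
        n_splits=config.n_splits,
        seed=stage_seed(config.seed, "consistency"),
    )
    rows = []
    for i, d in enumerate(per_split):
        for ct, r in sorted(d.items()):
            rows.append({"split": i + 1, "cell_type": ct, "pearson_r": r})
    report = pd.DataFrame(rows)
    # cross-estimator comparison on the same sample
    res_nnls = deconv.deconvolve_all(sm, panel, method="nnls")
    comp = deconv.compare_proportions(
        results[sm.sample_id].theta, res_nnls.theta, res_nnls.cell_types
    )
    comp_df = pd.DataFrame(comp)
    return report, mean_corr, comp_df


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline; returns a dict of in-memory results and
    writes all report tables plus manifest.json and run.log to ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("spotcell")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    state: dict = {}
    try:
        t0 = time.time()
        (spots_list, ref_counts, ref_labels, gene_ids, lr_table, marker_sets,
         cell_markers, truth) = acquire_inputs(config)
        if cell_markers is None:
            cell_markers = marker_sets
        logger.info(
            "inputs: %d samples, %d genes (%.1fs)",
            len(spots_list), len(gene_ids), time.time() - t0,
        )
        state.update(spots_list=spots_list, truth=truth, lr_table=lr_table)

        t0 = time.time()
        domain_df, model, curve_df = domain_stage(spots_list, marker_sets, config)
        write_table(domain_df, os.path.join(outdir, "domains.tsv"),
                    key_columns=["sample_id", "spot_id"])
        write_table(curve_df, os.path.join(outdir, "bic_curve.tsv"), key_columns=["k"])
        logger.info("domains: k=%d (%.1fs)", model.k, time.time() - t0)
        state.update(domain_df=domain_df, domain_model=model)

        t0 = time.time()
        panel, results, theta_df = deconvolve_stage(
            spots_list, ref_counts, ref_labels, gene_ids, config
        )
        write_table(theta_df, os.path.join(outdir, "theta.tsv"),
                    key_columns=["sample_id", "spot_id"])
        logger.info("deconvolution: %d spots (%.1fs)", len(theta_df), time.time() - t0)
        state.update(panel=panel, results=results, theta_df=theta_df)

        rings, rings_df = rings_stage(spots_list, config)
        write_table(rings_df, os.path.join(outdir, "rings.tsv"),
                    key_columns=["sample_id", "spot_id"])
        state.update(rings=rings)

        t0 = time.time()
        psm_matrix, confusion = psm_stage(
            results, spots_list, rings, panel, cell_markers, config
        )
        _write_psm(psm_matrix, outdir)
        confusion.to_csv(os.path.join(outdir, "psm_confusion.tsv"), sep="\t")
        logger.info("psm: %d pseudo-cells (%.1fs)", psm_matrix.n_cells, time.time() - t0)
        state.update(psm=psm_matrix, confusion=confusion)

        t0 = time.time()
        markers_df, composition_df, unique_df = dge_stage(
            spots_list, domain_df, results, psm_matrix, config
        )
        write_table(markers_df, os.path.join(outdir, "markers.tsv"),
                    key_columns=["domain"])
        write_table(composition_df, os.path.join(outdir, "composition.tsv"),
                    key_columns=["domain", "cell_type", "contrast"])
        write_table(unique_df, os.path.join(outdir, "unique_up.tsv"),
                    key_columns=["domain", "cell_type", "group", "gene"])
        logger.info("dge stage done (%.1fs)", time.time() - t0)
        state.update(markers_df=markers_df, composition_df=composition_df,
                     unique_df=unique_df)

        t0 = time.time()
        inter_df, nodes_df, cc_df = communication_stage(
            spots_list, domain_df, psm_matrix, lr_table, config
        )
        write_table(inter_df, os.path.join(outdir, "network_subregion.tsv"),
                    key_columns=["group", "pair_name", "sender", "receiver"])
        write_table(nodes_df, os.path.join(outdir, "node_strengths.tsv"),
                    key_columns=["group", "node"])
        write_table(cc_df, os.path.join(outdir, "network_cell_ring.tsv"),
                    key_columns=["group", "level", "pair_name", "sender", "receiver"])
        logger.info("communication stage done (%.1fs)", time.time() - t0)
        state.update(inter_df=inter_df, nodes_df=nodes_df, cc_df=cc_df)

        ring_df = ring_dge_stage(psm_matrix, config)
        write_table(ring_df, os.path.join(outdir, "ring_dge.tsv"),
                    key_columns=["group", "cell_type", "gene"])
        state.update(ring_df=ring_df)

        if config.run_consistency:
            t0 = time.time()
            report, mean_corr, comp_df = consistency_stage(
                ref_counts, ref_labels, gene_ids, spots_list, panel, results, config
            )
            write_table(report, os.path.join(outdir, "consistency_report.tsv"),
                        key_columns=["split", "cell_type"])
            write_table(comp_df, os.path.join(outdir, "method_comparison.tsv"),
                        key_columns=["cell_type"])
            logger.info(
                "consistency: mean r=%.3f (%.1fs)", mean_corr, time.time() - t0
            )
            state.update(consistency=report, consistency_mean=mean_corr,
                         method_comparison=comp_df)

        _write_manifest(config, outdir)
    except Exception:
        logger.exception("pipeline stage failed; artifacts so far preserved")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return state


def _write_psm(psm_matrix, outdir) -> None:
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(
        os.path.join(outdir, "psm_counts.mtx"),
        sparse.coo_matrix(psm_matrix.counts),
        field="integer",
    )
    cells = psm_matrix.meta.drop(columns=["theta"])
    cells.to_csv(os.path.join(outdir, "psm_cells.tsv"), sep="\t", index=False)
    pd.Series(psm_matrix.gene_ids).to_csv(
        os.path.join(outdir, "psm_genes.tsv"), index=False, header=False, sep="\t"
    )


def load_psm(outdir):
    """Re-read the PSM written by the psm stage (stage isolation for CLI)."""
    from scipy import io as spio

    path = os.path.join(outdir, "psm_counts.mtx")
    if not os.path.exists(path):
        raise FileNotFoundError(f"expected PSM counts at {path}; run the psm stage first")
    counts = np.asarray(spio.mmread(path).todense()).astype(np.int64)
    meta = pd.read_csv(os.path.join(outdir, "psm_cells.tsv"), sep="\t", dtype=str)
    meta["level"] = meta["level"].fillna("")
    genes = pd.read_csv(
        os.path.join(outdir, "psm_genes.tsv"), header=None, sep="\t"
    )[0].to_numpy(dtype=object)
    return psm_mod.PseudoCellMatrix(
        counts=counts,
        fractional=counts.astype(float),
        gene_ids=genes,
        meta=meta.assign(theta=np.nan),
    )


def _write_manifest(config: PipelineConfig, outdir) -> None:
    cfg_yaml = config.to_yaml()
    tables = sorted(
        f for f in os.listdir(outdir)
        if f.endswith((".tsv", ".mtx")) and os.path.isfile(os.path.join(outdir, f))
    )
    hashes = {}
    for f in tables:
        with open(os.path.join(outdir, f), "rb") as fh:
            hashes[f] = hashlib.sha256(fh.read()).hexdigest()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "outputs": hashes,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
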