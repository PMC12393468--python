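"""Synthetic hippocampus tissue with known ground truth.

The generator emulates the statistical structure of a Visium study of the
hippocampus across three groups (AC / PART / AD): 7 brain cell types with
marker-gene blocks, 10 subregions laid out as horizontal bands plus vascular
foci, Dirichlet per-spot compositions that differ between soma layers, fiber
layers and vessels, multinomial count sampling at variable library sizes,
group x subregion x cell-type expression effects, and a vessel-distance
expression gradient present in one cell type of one group only.

Every downstream stage of the pipeline is testable against the returned
:class:`GroundTruth` without any external download.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import GROUPS, SpotMatrix

CELL_TYPES = ("Ast", "Exc", "Inh", "Mic", "Oli", "OPC", "VC")
SOMA_DOMAINS = ("SUB", "CA1", "CA2", "CA3", "CA4", "DG")
FIBER_DOMAINS = ("SO", "SR", "ML")

#: Horizontal bands (domain, first row, last row inclusive) on the default
#: 40-row lattice: soma layers interleaved with fiber layers, top to bottom.
DEFAULT_BANDS = (
    ("SUB", 0, 4),
    ("SO", 5, 8),
    ("CA1", 9, 13),
    ("SR", 14, 17),
    ("CA2", 18, 21),
    ("CA3", 22, 26),
    ("ML", 27, 30),
    ("CA4", 31, 34),
    ("DG", 35, 39),
)

#: Dominant glial host for each fiber-layer program gene.
FIBER_PROGRAM_HOST = {"SO": "Oli", "SR": "Ast", "ML": "Ast"}

# Dirichlet mean compositions, ordered as CELL_TYPES.
SOMA_MEAN = (0.10, 0.55, 0.10, 0.05, 0.10, 0.05, 0.05)
FIBER_MEAN = (0.30, 0.08, 0.05, 0.07, 0.33, 0.10, 0.07)
VAS_MEAN = (0.15, 0.05, 0.05, 0.08, 0.10, 0.07, 0.50)


@dataclass(frozen=True)
class GroupEffect:
    """A planted group x subregion x cell-type expression effect."""

    group: str
    domain: str
    cell_type: str
    gene: str
    log2_fold: float


@dataclass(frozen=True)
class VesselGradient:
    """A vessel-proximity expression gradient in one cell type of one group.

    ``multipliers`` scale the gene's expression at ring levels 1..4.
    """

    group: str
    cell_type: str
    gene: str
    multipliers: tuple = (4.0, 2.5, 1.5, 1.0)


@dataclass
class TissueConfig:
    """Study conditions for the synthetic tissue.

    Defaults are desk-scale: a 40 x 40 lattice per sample at 100 px pitch,
    300 genes with 10 markers per type at fold 8, 200-cell-per-type reference,
    and a median library size of ~4,000 counts per spot.
    """

    n_rows: int = 40
    n_cols: int = 40
    pitch: float = 100.0
    domain_bands: tuple = DEFAULT_BANDS
    n_vessels: int = 3
    vessel_radius: float = 160.0
    n_genes: int = 300
    markers_per_type: int = 10
    marker_fold: float = 8.0
    program_fold: float = 30.0
    dirichlet_conc: float = 10.0
    soma_mean: tuple = SOMA_MEAN
    fiber_mean: tuple = FIBER_MEAN
    vas_mean: tuple = VAS_MEAN
    library_meanlog: float = math.log(4000.0)
    library_sdlog: float = 0.35
    group_effects: tuple = (
        GroupEffect("AD", "CA1", "Exc", "eff-AD-CA1-Exc", 2.0),
        GroupEffect("PART", "CA2", "Exc", "eff-PART-CA2-Exc", 2.0),
    )
    vessel_gradient: VesselGradient | None = field(
        default_factory=lambda: VesselGradient("AD", "Ast", "grad-AD-Ast")
    )
    ring_radii: tuple = (200.0, 400.0, 600.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if self.marker_fold <= 0 or self.program_fold <= 0:
            raise ValueError("folds must be > 0")
        for mean in (self.soma_mean, self.fiber_mean, self.vas_mean):
            if len(mean) != len(CELL_TYPES) or abs(sum(mean) - 1.0) > 1e-9:
                raise ValueError("composition means must be simplex vectors over K=7")
        if self.vessel_gradient is not None and any(
            m <= 0 for m in self.vessel_gradient.multipliers
        ):
            raise ValueError("gradient multipliers must be > 0")


@dataclass
class GenePanel:
    """Gene universe with planted structure, shared by reference and tissue."""

    gene_ids: np.ndarray
    base_weights: np.ndarray  # K x G, unnormalized
    marker_genes: dict
    program_genes: dict  # domain -> (gene, host cell type)

    @property
    def profiles(self) -> np.ndarray:
        w = self.base_weights
        return w / w.sum(axis=1, keepdims=True)


@dataclass
class SampleTruth:
    spot_ids: np.ndarray
    theta: np.ndarray
    domain: np.ndarray
    level: np.ndarray  # 0 denotes VAS spots, else 1..4
    vessel_distance: np.ndarray
    vessel_centers: np.ndarray
    profile_key: list


@dataclass
class GroundTruth:
    cell_types: list
    gene_ids: np.ndarray
    samples: dict
    effective_profiles: dict  # (group, domain, level) -> K x G row-stochastic
    marker_genes: dict
    program_genes: dict
    group_effects: tuple
    vessel_gradient: VesselGradient | None

    def theta_for(self, sample_id: str) -> np.ndarray:
        return self.samples[sample_id].theta


def noisy_band_config(**overrides) -> TissueConfig:
    """The noisy band-recovery fixture: default tissue at a median library
    of ~1,200 counts, where expression alone under-determines the bands and
    spatial smoothing is required to recover them."""
    params = {"library_meanlog": math.log(1200.0)}
    params.update(overrides)
    return TissueConfig(**params)


def build_gene_panel(config: TissueConfig) -> GenePanel:
    """Deterministic gene universe + per-type base weights for a config.

    Depends only on ``config`` (via ``config.seed``) so that reference cells
    and tissue spots drawn with different sampling seeds share one biology.
    """
    rng = np.random.default_rng(config.seed + 987654321)
    K = len(CELL_TYPES)
    gene_ids: list[str] = []
    marker_genes: dict = {}
    for ct in CELL_TYPES:
        marker_genes[ct] = [
            f"{ct}-mk{i + 1:02d}" for i in range(config.markers_per_type)
        ]
        gene_ids.extend(marker_genes[ct])
    program_genes: dict = {}
    band_domains = [b[0] for b in config.domain_bands]
    for dom in band_domains:
        host = "Exc" if dom in SOMA_DOMAINS else FIBER_PROGRAM_HOST.get(dom, "Ast")
        gene = f"prog-{dom}"
        program_genes[dom] = (gene, host)
        gene_ids.append(gene)
    special_hosts: dict = {}
    for eff in config.group_effects:
        if eff.gene not in gene_ids:
            gene_ids.append(eff.gene)
            special_hosts[eff.gene] = eff.cell_type
    if config.vessel_gradient is not None and config.vessel_gradient.gene not in gene_ids:
        gene_ids.append(config.vessel_gradient.gene)
        special_hosts[config.vessel_gradient.gene] = config.vessel_gradient.cell_type
    if len(gene_ids) > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for the planted structure "
            f"({len(gene_ids)} structured genes)"
        )
    gene_ids.extend(f"gene{i:04d}" for i in range(config.n_genes - len(gene_ids)))
    gene_ids_arr = np.asarray(gene_ids, dtype=object)
    G = len(gene_ids_arr)

    base = rng.lognormal(mean=0.0, sigma=0.6, size=G)
    W = np.tile(base, (K, 1))
    idx = {g: i for i, g in enumerate(gene_ids_arr)}
    for k, ct in enumerate(CELL_TYPES):
        for g in marker_genes[ct]:
            W[k, idx[g]] *= config.marker_fold
    # Program and planted-effect genes live in their host type only, at a
    # modest base level; multipliers are applied at tissue-generation time.
    for dom, (gene, host) in program_genes.items():
        j = idx[gene]
        W[:, j] = 0.0
        W[CELL_TYPES.index(host), j] = base[j] * 0.3
    for gene, host in special_hosts.items():
        j = idx[gene]
        W[:, j] = 0.0
        W[CELL_TYPES.index(host), j] = base[j]
    return GenePanel(
        gene_ids=gene_ids_arr,
        base_weights=W,
        marker_genes=marker_genes,
        program_genes=program_genes,
    )


def _draw_library_sizes(rng, config: TissueConfig, n: int) -> np.ndarray:
    sizes = rng.lognormal(config.library_meanlog, config.library_sdlog, size=n)
    return np.maximum(np.round(sizes).astype(int), 50)


def generate_reference_cells(
    config: TissueConfig, n_cells_per_type: int = 200, seed: int = 0
):
    """Draw labeled single-nucleus-like reference cells.

    Each cell is Multinomial(library size, type profile).  Returns
    ``(cell_counts, cell_labels, gene_ids)`` with cells grouped by type in
    ``CELL_TYPES`` order.
    """
    if n_cells_per_type < 2:
        raise ValueError("need at least 2 cells per type")
    if config.marker_fold == 1.0:
        warnings.warn(
            "profiles indistinguishable: marker fold 1 leaves type profiles "
            "identical up to planted genes; deconvolution is unidentifiable",
            stacklevel=2,
        )
    panel = build_gene_panel(config)
    profiles = panel.profiles
    rng = np.random.default_rng(seed)
    counts = []
    labels = []
    for k, ct in enumerate(CELL_TYPES):
        sizes = _draw_library_sizes(rng, config, n_cells_per_type)
        for n in sizes:
            counts.append(rng.multinomial(n, profiles[k]))
        labels.extend([ct] * n_cells_per_type)
    return (
        np.asarray(counts, dtype=np.int64),
        np.asarray(labels, dtype=object),
        panel.gene_ids,
    )


def _band_domain_per_row(config: TissueConfig) -> list:
    rows = [None] * config.n_rows
    for dom, r0, r1 in config.domain_bands:
        for r in range(r0, r1 + 1):
            if r < config.n_rows:
                if rows[r] is not None:
                    raise ValueError(f"overlapping bands at row {r}")
                rows[r] = dom
    uncovered = [r for r, d in enumerate(rows) if d is None]
    if uncovered:
        raise ValueError(f"band layout leaves rows uncovered: {uncovered}")
    return rows


def _sample_vessel_centers(rng, config: TissueConfig) -> np.ndarray:
    if config.n_vessels == 0:
        return np.zeros((0, 2))
    xmax = (config.n_cols - 1) * config.pitch
    ymax = (config.n_rows - 1) * config.pitch
    centers: list = []
    for _ in range(10000):
        if len(centers) == config.n_vessels:
            break
        cand = np.array([rng.uniform(0, xmax), rng.uniform(0, ymax)])
        if all(
            np.hypot(*(cand - c)) >= 2 * config.vessel_radius for c in centers
        ):
            centers.append(cand)
    if len(centers) < config.n_vessels:
        raise RuntimeError("could not place vessels at least 2*radius apart")
    return np.vstack(centers)


def _ring_levels_from_vas(x, y, is_vas, radii) -> tuple[np.ndarray, np.ndarray]:
    """Distance to nearest VAS spot and ring level (0 = VAS, 1..4 bands).

    Kept independent of the spatial_context module so the two serve as
    cross-checking oracles for each other.
    """
    n = len(x)
    level = np.full(n, 4, dtype=int)
    dist = np.full(n, np.inf)
    vas_xy = np.column_stack([np.asarray(x)[is_vas], np.asarray(y)[is_vas]])
    if len(vas_xy):
        all_xy = np.column_stack([x, y])
        dist = cdist(all_xy, vas_xy).min(axis=1)
        r1, r2, r3 = radii
        level[(dist > 0) & (dist <= r1)] = 1
        level[(dist > r1) & (dist <= r2)] = 2
        level[(dist > r2) & (dist <= r3)] = 3
        level[dist > r3] = 4
        level[is_vas] = 0
        dist[np.asarray(is_vas, bool)] = 0.0
    return dist, level


def _effective_profile(panel: GenePanel, config: TissueConfig, key) -> np.ndarray:
    group, domain, level = key
    W = panel.base_weights.copy()
    idx = {g: i for i, g in enumerate(panel.gene_ids)}
    if domain in panel.program_genes:
        gene, host = panel.program_genes[domain]
        W[CELL_TYPES.index(host), idx[gene]] *= config.program_fold
    for eff in config.group_effects:
        if eff.group == group and eff.domain == domain:
            W[CELL_TYPES.index(eff.cell_type), idx[eff.gene]] *= 2.0 ** eff.log2_fold
    grad = config.vessel_gradient
    if grad is not None and grad.group == group and 1 <= level <= 4:
        W[CELL_TYPES.index(grad.cell_type), idx[grad.gene]] *= grad.multipliers[
            level - 1
        ]
    return W / W.sum(axis=1, keepdims=True)


def generate_tissue(
    config: TissueConfig,
    groups=GROUPS,
    samples_per_group: int = 2,
    seed: int = 0,
):
    """Generate spot-level tissue for every group and the full ground truth.

    Returns ``(spot_matrices, truth)`` where ``spot_matrices`` is a list of
    :class:`~spotcell.io.SpotMatrix` (one per sample, domains assigned from
    the band layout with VAS overriding inside vessel radii) and ``truth`` a
    :class:`GroundTruth`.
    """
    panel = build_gene_panel(config)
    row_domains = _band_domain_per_row(config)
    rng = np.random.default_rng(seed)
    K = len(CELL_TYPES)

    class_mean = {}
    for dom in SOMA_DOMAINS:
        class_mean[dom] = np.asarray(config.soma_mean)
    for dom in FIBER_DOMAINS:
        class_mean[dom] = np.asarray(config.fiber_mean)
    class_mean["VAS"] = np.asarray(config.vas_mean)

    spot_matrices = []
    samples = {}
    effective_profiles: dict = {}
    for group in groups:
        for j in range(samples_per_group):
            sample_id = f"{group}{j + 1}"
            rows, cols = np.divmod(np.arange(config.n_rows * config.n_cols), config.n_cols)
            x = cols * config.pitch
            y = rows * config.pitch
            n = len(x)
            domain = np.asarray([row_domains[r] for r in rows], dtype=object)
            centers = _sample_vessel_centers(rng, config)
            if len(centers):
                d_center = cdist(np.column_stack([x, y]), centers).min(axis=1)
                is_vas = d_center <= config.vessel_radius
            else:
                is_vas = np.zeros(n, dtype=bool)
            domain[is_vas] = "VAS"
            dist, level = _ring_levels_from_vas(x, y, is_vas, config.ring_radii)

            theta = np.empty((n, K))
            for dom in set(domain):
                mask = domain == dom
                alpha = config.dirichlet_conc * class_mean[dom]
                theta[mask] = rng.dirichlet(alpha, size=int(mask.sum()))

            sizes = _draw_library_sizes(rng, config, n)
            counts = np.empty((n, len(panel.gene_ids)), dtype=np.int64)
            keys = []
            for s in range(n):
                key = (group, domain[s], int(level[s]))
                if key not in effective_profiles:
                    effective_profiles[key] = _effective_profile(panel, config, key)
                keys.append(key)
                p = theta[s] @ effective_profiles[key]
                counts[s] = rng.multinomial(sizes[s], p)

            spot_ids = np.asarray(
                [f"{sample_id}-s{i:05d}" for i in range(n)], dtype=object
            )
            spot_matrices.append(
                SpotMatrix(
                    counts=counts,
                    spot_ids=spot_ids,
                    gene_ids=panel.gene_ids,
                    x=x.astype(float),
                    y=y.astype(float),
                    sample_id=sample_id,
                    group=group,
                    domain=domain,
                    is_vas=is_vas,
                )
            )
            samples[sample_id] = SampleTruth(
                spot_ids=spot_ids,
                theta=theta,
                domain=domain.copy(),
                level=level,
                vessel_distance=dist,
                vessel_centers=centers,
                profile_key=keys,
            )

    truth = GroundTruth(
        cell_types=list(CELL_TYPES),
        gene_ids=panel.gene_ids,
        samples=samples,
        effective_profiles=effective_profiles,
        marker_genes=panel.marker_genes,
        program_genes=panel.program_genes,
        group_effects=tuple(config.group_effects),
        vessel_gradient=config.vessel_gradient,
    )
    return spot_matrices, truth


def domain_marker_sets(config: TissueConfig) -> dict:
    """Marker sets for domain annotation: program genes plus, for VAS, the
    vascular-cell marker block."""
    panel = build_gene_panel(config)
    sets = {dom: [gene] for dom, (gene, _) in panel.program_genes.items()}
    sets["VAS"] = list(panel.marker_genes["VC"])
    return sets


def truth_report(truth: GroundTruth, out_dir) -> None:
    """Write the ground truth as TSV files under ``out_dir``.

    ``theta_true.tsv``: sample_id, spot_id, one column per cell type.
    ``domains_true.tsv``: sample_id, spot_id, domain.
    ``rings_true.tsv``: sample_id, spot_id, distance_px, level (VAS or 1..4).
    ``planted_genes.tsv``: kind, gene, cell_type, domain, group, detail.
    """
    import os

    import pandas as pd

    from .io import write_table

    os.makedirs(out_dir, exist_ok=True)
    theta_rows, dom_rows, ring_rows = [], [], []
    for sid in sorted(truth.samples):
        st = truth.samples[sid]
        for i, spot in enumerate(st.spot_ids):
            rec = {"sample_id": sid, "spot_id": spot}
            rec.update(
                {ct: st.theta[i, k] for k, ct in enumerate(truth.cell_types)}
            )
            theta_rows.append(rec)
            dom_rows.append(
                {"sample_id": sid, "spot_id": spot, "domain": st.domain[i]}
            )
            ring_rows.append(
                {
                    "sample_id": sid,
                    "spot_id": spot,
                    "distance_px": st.vessel_distance[i],
                    "level": "VAS" if st.level[i] == 0 else str(st.level[i]),
                }
            )
    write_table(
        pd.DataFrame(theta_rows),
        os.path.join(out_dir, "theta_true.tsv"),
        key_columns=["sample_id", "spot_id"],
    )
    write_table(
        pd.DataFrame(dom_rows),
        os.path.join(out_dir, "domains_true.tsv"),
        key_columns=["sample_id", "spot_id"],
    )
    write_table(
        pd.DataFrame(ring_rows),
        os.path.join(out_dir, "rings_true.tsv"),
        key_columns=["sample_id", "spot_id"],
    )
    planted = []
    for ct, genes in truth.marker_genes.items():
        for g in genes:
            planted.append(
                {"kind": "marker", "gene": g, "cell_type": ct, "domain": "", "group": "", "detail": ""}
            )
    for dom, (gene, host) in truth.program_genes.items():
        planted.append(
            {"kind": "program", "gene": gene, "cell_type": host, "domain": dom, "group": "", "detail": ""}
        )
    for eff in truth.group_effects:
        planted.append(
            {
                "kind": "group_effect",
                "gene": eff.gene,
                "cell_type": eff.cell_type,
                "domain": eff.domain,
                "group": eff.group,
                "detail": f"log2_fold={eff.log2_fold}",
            }
        )
    if truth.vessel_gradient is not None:
        grad = truth.vessel_gradient
        planted.append(
            {
                "kind": "vessel_gradient",
                "gene": grad.gene,
                "cell_type": grad.cell_type,
                "domain": "",
                "group": grad.group,
                "detail": "multipliers=" + ",".join(str(m) for m in grad.multipliers),
            }
        )
    write_table(
        pd.DataFrame(planted),
        os.path.join(out_dir, "planted_genes.tsv"),
        key_columns=["kind", "gene"],
    )
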