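"""Distance-aware ligand-receptor communication and vessel-ring analysis.

Communication strength between a sender and receiver group for an LR pair
follows a mass-action scheme: the product of the sender's trimmed-mean
ligand expression and the receiver's receptor activity (geometric mean over
subunits), passed through a Hill saturation raw/(Kh + raw), optionally
scaled by a population factor and — for inter-subregion networks — by an
exponential decay in the centroid distance.  Significance comes from a
label-permutation test with Bonferroni adjustment.

The concentric vessel analysis bins spots into rings around the vascular
(VAS) spots: level 1 within 200 px (~um), level 2 in (200, 400], level 3 in
(400, 600], level 4 beyond; the nearest vessel decides ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist

from .io import LRTable, SpotMatrix
from .psm import PseudoCellMatrix
from .stats import rank_markers

logger = logging.getLogger(__name__)

DEFAULT_RADII = (200.0, 400.0, 600.0)
VAS_LEVEL = "VAS"


@dataclass
class RingAssignment:
    """Per-spot nearest-VAS distance and ring level ('VAS' or '1'..'4')."""

    spot_ids: np.ndarray
    sample_id: str
    distance_px: np.ndarray
    level: np.ndarray
    radii: tuple = DEFAULT_RADII


@dataclass
class CommunicationNetwork:
    entries: pd.DataFrame  # pair_name, pathway, sender, receiver, L, R, raw, strength
    nodes: pd.DataFrame  # node, outgoing, incoming
    params: dict = field(default_factory=dict)

    def pathway_aggregates(self) -> pd.DataFrame:
        agg = (
            self.entries.groupby(["pathway", "sender", "receiver"], as_index=False)[
                "strength"
            ].sum()
        )
        return agg


def ring_levels(spots: SpotMatrix, radii=DEFAULT_RADII) -> RingAssignment:
    """Assign concentric ring levels around a sample's VAS spots.

    ``d`` is the minimum Euclidean distance to any VAS spot of the same
    sample (which realizes the nearest-vessel tie-break); levels follow the
    (0, r1], (r1, r2], (r2, r3], (r3, inf) bins and VAS spots themselves are
    labeled 'VAS'.  A sample without VAS spots gets all level 4 with a
    warning.
    """
    r1, r2, r3 = radii
    if not 0 < r1 < r2 < r3:
        raise ValueError("radii must be strictly increasing and positive")
    is_vas = np.asarray(spots.is_vas, dtype=bool)
    n = spots.n_spots
    xy = np.column_stack([spots.x, spots.y])
    if not is_vas.any():
        warnings.warn(
            f"sample {spots.sample_id}: no VAS spot; all spots assigned level 4",
            stacklevel=2,
        )
        return RingAssignment(
            spot_ids=spots.spot_ids,
            sample_id=spots.sample_id,
            distance_px=np.full(n, np.inf),
            level=np.full(n, "4", dtype=object),
            radii=tuple(radii),
        )
    d = cdist(xy, xy[is_vas]).min(axis=1)
    level = np.empty(n, dtype=object)
    level[(d > 0) & (d <= r1)] = "1"
    level[(d > r1) & (d <= r2)] = "2"
    level[(d > r2) & (d <= r3)] = "3"
    level[d > r3] = "4"
    level[is_vas] = VAS_LEVEL
    d = d.copy()
    d[is_vas] = 0.0
    return RingAssignment(
        spot_ids=spots.spot_ids,
        sample_id=spots.sample_id,
        distance_px=d,
        level=level,
        radii=tuple(radii),
    )


def group_profile(expr, labels, gene_ids=None, trim: float = 0.1, normalized: bool = False) -> pd.DataFrame:
    """Per-group symmetric trimmed-mean expression (groups x genes).

    Expression is 10k-scaled log1p-normalized then de-logged before
    averaging; groups smaller than 1/trim observations fall back to the
    plain mean (logged).
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    expr = np.asarray(expr, dtype=float)
    if not normalized:
        from .domains import normalize_expression

        expr = normalize_expression(expr)
    values = np.expm1(expr)
    labels = np.asarray(labels, dtype=object)
    rows = {}
    for g in sorted(set(labels)):
        sub = values[labels == g]
        if trim > 0 and len(sub) < 1.0 / trim:
            logger.info("group %r smaller than 1/trim; using plain mean", g)
            rows[g] = sub.mean(axis=0)
        elif trim == 0:
            rows[g] = sub.mean(axis=0)
        else:
            rows[g] = sps.trim_mean(sub, trim, axis=0)
    out = pd.DataFrame(rows).T
    if gene_ids is not None:
        out.columns = list(gene_ids)
    return out


def lr_strength(
    sender_profile,
    receiver_profile,
    entry,
    Kh: float = 0.5,
    weight: float = 1.0,
    pop_factor: float = 1.0,
    expr_scale: float = 1.0,
):
    """Mass-action strength of one LR pair between one sender and receiver.

    Returns ``(L, R, raw, strength)`` with strength =
    weight * pop_factor * raw / (Kh + raw).  ``expr_scale`` divides the
    profile values before the mass-action product so that Kh refers to a
    sensible unit (networks built from 10k-scaled profiles pass 100, putting
    L and R in percent-of-library units).  Missing ligand or subunit genes
    yield strength 0 with a warning.
    """
    if Kh <= 0:
        raise ValueError("Kh must be > 0")
    if not 0 < weight <= 1 or not 0 < pop_factor <= 1:
        raise ValueError("weight and pop_factor must lie in (0, 1]")
    genes = [entry.ligand] + list(entry.receptor_subunits)
    missing = [g for g in genes if g not in sender_profile.index]
    if missing:
        warnings.warn(
            f"pair {entry.pair_name}: missing genes {missing}; strength 0",
            stacklevel=2,
        )
        return 0.0, 0.0, 0.0, 0.0
    L = float(sender_profile[entry.ligand]) / expr_scale
    subs = np.asarray(
        [receiver_profile[g] / expr_scale for g in entry.receptor_subunits], float
    )
    R = float(np.exp(np.mean(np.log(np.maximum(subs, 0) + 1e-300)))) if (subs > 0).all() else 0.0
    raw = L * R
    return L, R, raw, weight * pop_factor * raw / (Kh + raw)


def distance_weights(coords, labels, lam=None):
    """Exponential decay weights between group centroids.

    ``w[i, j] = exp(-d_ij / lambda)`` with lambda the median off-diagonal
    centroid distance when not supplied; ``w[i, i] = 1``.
    Returns ``(weights DataFrame, lambda)``.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels, dtype=object)
    groups = sorted(set(labels))
    cents = np.vstack([coords[labels == g].mean(axis=0) for g in groups])
    D = cdist(cents, cents)
    if len(groups) == 1:
        return pd.DataFrame([[1.0]], index=groups, columns=groups), 1.0
    if lam is None:
        off = D[~np.eye(len(groups), dtype=bool)]
        lam = float(np.median(off))
        if lam <= 0:
            lam = 1.0
    W = np.exp(-D / lam)
    np.fill_diagonal(W, 1.0)
    return pd.DataFrame(W, index=groups, columns=groups), float(lam)


def build_network(
    expr,
    labels,
    lr_table: LRTable,
    gene_ids=None,
    coords=None,
    mode: str = "inter_subregion",
    Kh: float = 0.5,
    trim: float = 0.1,
    lam=None,
    use_pop_factor: bool = False,
    normalized: bool = False,
    expr_scale: float = 100.0,
) -> CommunicationNetwork:
    """Score every (pair, sender, receiver) and aggregate node strengths.

    ``mode='inter_subregion'`` applies distance-decay weights from the label
    centroids (``coords`` required); ``mode='cell_cell'`` uses weight 1.
    """
    if len(lr_table) == 0:
        raise ValueError("empty LR table")
    if mode not in ("inter_subregion", "cell_cell"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels, dtype=object)
    groups = sorted(set(labels))
    profiles = group_profile(expr, labels, gene_ids=gene_ids, trim=trim, normalized=normalized)
    if mode == "inter_subregion":
        if coords is None:
            raise ValueError("inter_subregion mode requires coords")
        W, lam_used = distance_weights(coords, labels, lam)
    else:
        W = pd.DataFrame(1.0, index=groups, columns=groups)
        lam_used = None
    freq = {g: (labels == g).mean() for g in groups}
    rows = []
    for e in lr_table.entries:
        for snd in groups:
            for rcv in groups:
                pf = float(np.sqrt(freq[snd] * freq[rcv])) if use_pop_factor else 1.0
                L, R, raw, s = lr_strength(
                    profiles.loc[snd],
                    profiles.loc[rcv],
                    e,
                    Kh=Kh,
                    weight=float(W.loc[snd, rcv]),
                    pop_factor=pf,
                    expr_scale=expr_scale,
                )
                rows.append(
                    {
                        "pair_name": e.pair_name,
                        "pathway": e.pathway,
                        "sender": snd,
                        "receiver": rcv,
                        "L": L,
                        "R": R,
                        "raw": raw,
                        "strength": s,
                    }
                )
    entries = pd.DataFrame(rows)
    nodes = pd.DataFrame(
        {
            "node": groups,
            "outgoing": [
                entries.loc[entries["sender"] == g, "strength"].sum() for g in groups
            ],
            "incoming": [
                entries.loc[entries["receiver"] == g, "strength"].sum() for g in groups
            ],
        }
    )
    params = {
        "Kh": Kh,
        "trim": trim,
        "mode": mode,
        "lambda": lam_used,
        "use_pop_factor": use_pop_factor,
    }
    return CommunicationNetwork(entries=entries, nodes=nodes, params=params)


def permutation_significance(
    expr,
    labels,
    lr_table: LRTable,
    gene_ids=None,
    coords=None,
    mode: str = "cell_cell",
    n_perm: int = 100,
    seed: int = 0,
    sample_ids=None,
    **kwargs,
) -> CommunicationNetwork:
    """Permutation p-values for every network entry, Bonferroni-adjusted.

    Labels are shuffled (within sample when ``sample_ids`` is given) and the
    full network recomputed each time; p_raw = (1 + #{perm >= obs}) /
    (1 + n_perm) and p_adj = min(1, p_raw * n_entries).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    labels = np.asarray(labels, dtype=object)
    observed = build_network(
        expr, labels, lr_table, gene_ids=gene_ids, coords=coords, mode=mode, **kwargs
    )
    obs = observed.entries["strength"].to_numpy()
    exceed = np.zeros(len(obs))
    rng = np.random.default_rng(seed)
    if sample_ids is not None:
        sample_ids = np.asarray(sample_ids)
    key = observed.entries[["pair_name", "sender", "receiver"]]
    for _ in range(n_perm):
        perm = labels.copy()
        if sample_ids is None:
            rng.shuffle(perm)
        else:
            for s in np.unique(sample_ids):
                idx = np.flatnonzero(sample_ids == s)
                perm[idx] = perm[idx[rng.permutation(len(idx))]]
        if set(perm) != set(labels):  # a label vanished: strengths undefined there
            pass
        net = build_network(expr, perm, lr_table, gene_ids=gene_ids, coords=coords, mode=mode, **kwargs)
        aligned = net.entries.set_index(["pair_name", "sender", "receiver"])[
            "strength"
        ].reindex(pd.MultiIndex.from_frame(key)).to_numpy()
        exceed += aligned >= obs
    p_raw = (1.0 + exceed) / (1.0 + n_perm)
    n_tests = len(obs)
    entries = observed.entries.copy()
    entries["p_raw"] = p_raw
    entries["p_adj"] = np.minimum(1.0, p_raw * n_tests)
    observed.entries = entries
    observed.params.update({"n_perm": n_perm, "n_tests": n_tests, "seed": seed})
    return observed


def ring_dge(
    psm: PseudoCellMatrix,
    cell_type: str,
    level_a: str = "1",
    level_b: str = "3",
    use_origin: bool = True,
) -> pd.DataFrame:
    """Proximal-vs-distal DGE for one cell type across ring levels.

    Delegates to :func:`spotcell.stats.rank_markers` with level_a as the
    target stratum.
    """
    if str(level_a) == str(level_b):
        raise ValueError("level_a and level_b must differ")
    col = "type_origin" if use_origin else "type_inferred"
    meta = psm.meta
    lev = meta["level"].astype(str)
    mask = (meta[col] == cell_type) & lev.isin([str(level_a), str(level_b)])
    for lv in (level_a, level_b):
        if ((meta[col] == cell_type) & (lev == str(lv))).sum() < 2:
            raise ValueError(
                f"fewer than 2 {cell_type} pseudo-cells at level {lv}"
            )
    sub = psm.counts[mask.to_numpy()]
    labels = lev[mask].to_numpy(dtype=object)
    return rank_markers(sub, labels, str(level_a), psm.gene_ids)
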