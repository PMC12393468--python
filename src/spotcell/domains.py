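"""Spatially smoothed clustering of spots into hippocampal subregions.

Expression is normalized, reduced to a PCA embedding, and clustered with a
k-means-initialized ICM (iterated conditional modes) scheme that adds a
Potts-style bonus for agreeing with spatial neighbors.  The cluster count is
chosen by BIC; clusters are named by marker scores.

The smoothness objective maximized by the sweeps is

    J = sum_s [ -||e_s - mu_{c_s}||^2 / (2 sigma^2) - (d/2) log sigma^2 ]
        + beta * #{neighbor pairs with equal labels}

over a symmetrized m-nearest-neighbor graph.  Each local update (take the
label maximizing the spot's data score plus beta times the count of its
neighbors currently carrying that label) cannot decrease J, and neither can
the centroid / variance re-estimates between sweeps, so J is non-decreasing
sweep over sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .io import UNASSIGNED, SpotMatrix

logger = logging.getLogger(__name__)


@dataclass
class DomainModel:
    k: int
    beta: float
    centroids: np.ndarray
    sigma2: float
    labels: np.ndarray
    bic: float
    n_sweeps_run: int
    objective_trace: np.ndarray


def normalize_expression(counts) -> np.ndarray:
    """Library-size normalize to 10,000 counts per spot, then log1p."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        bad = list(np.flatnonzero(totals[:, 0] == 0))
        raise ValueError(f"spots with zero total counts: {bad}")
    return np.log1p(counts / totals * 1e4)


def normalize_embed(counts, n_hvg: int = 2000, d: int = 20) -> np.ndarray:
    """Normalize, select highly variable genes, and project to ``d`` PCs.

    HVGs are the top ``n_hvg`` genes by dispersion (variance/mean of the
    normalized values).  The PCA sign convention (largest-magnitude loading
    positive) makes repeated runs bit-identical.
    """
    logn = normalize_expression(counts)
    G = logn.shape[1]
    n_hvg = min(n_hvg, G)
    mean = logn.mean(axis=0)
    var = logn.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-disp, kind="stable")[:n_hvg]
    X = logn[:, np.sort(order)]
    X = X - X.mean(axis=0)
    d = min(d, X.shape[1], X.shape[0])
    # deterministic full SVD; components scaled by singular values
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    emb = U[:, :d] * s[:d]
    for j in range(d):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            emb[:, j] = -emb[:, j]
    return emb


def _neighbor_lists(coords, m_neighbors, sample_ids=None):
    """Symmetrized m-NN adjacency; neighbors never cross sample boundaries."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    adj: list[set] = [set() for _ in range(n)]
    if sample_ids is None:
        groups = [np.arange(n)]
    else:
        sample_ids = np.asarray(sample_ids)
        groups = [np.flatnonzero(sample_ids == s) for s in pd_unique(sample_ids)]
    for idx in groups:
        m = min(m_neighbors, len(idx) - 1)
        if m < 1:
            continue
        nn = NearestNeighbors(n_neighbors=m + 1).fit(coords[idx])
        _, nbrs = nn.kneighbors(coords[idx])
        for row, local in zip(nbrs, idx):
            for other in row[1:]:
                j = idx[other]
                adj[local].add(int(j))
                adj[int(j)].add(int(local))
    return [np.fromiter(s, dtype=int) for s in adj]


def pd_unique(values):
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def _objective(embedding, labels, centroids, sigma2, adj, beta):
    d = embedding.shape[1]
    sq = ((embedding - centroids[labels]) ** 2).sum()
    data = -sq / (2 * sigma2) - len(embedding) * d / 2 * np.log(sigma2)
    same = 0
    for i, nbrs in enumerate(adj):
        same += int((labels[nbrs] == labels[i]).sum())
    return data + beta * same / 2


def cluster_spatial(
    embedding,
    coords,
    k: int,
    beta: float = 1.0,
    m_neighbors: int = 6,
    max_sweeps: int = 20,
    seed: int = 0,
    sample_ids=None,
) -> DomainModel:
    """Cluster an embedding with spatial ICM smoothing.

    With ``beta = 0`` the sweeps reduce to plain k-means refinement from the
    same seeded initialization.
    """
    embedding = np.asarray(embedding, dtype=float)
    n, d = embedding.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of spots ({n})")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    adj = _neighbor_lists(coords, m_neighbors, sample_ids)

    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(embedding)
    labels = km.labels_.astype(int)
    centroids = km.cluster_centers_.copy()
    sigma2 = max(((embedding - centroids[labels]) ** 2).sum() / (n * d), 1e-12)

    trace = [_objective(embedding, labels, centroids, sigma2, adj, beta)]
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        sq = ((embedding[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        data_score = -sq / (2 * sigma2)
        changed = 0
        for s in range(n):
            bonus = np.zeros(k)
            nbr_labels = labels[adj[s]]
            if len(nbr_labels):
                cnt = np.bincount(nbr_labels, minlength=k)
                bonus = beta * cnt
            new = int(np.argmax(data_score[s] + bonus))
            if new != labels[s]:
                labels[s] = new
                changed += 1
        # re-estimate centroids (reseeding empty clusters) and variance
        for c in range(k):
            mask = labels == c
            if mask.any():
                centroids[c] = embedding[mask].mean(axis=0)
            else:
                worst = int(
                    np.argmax(((embedding - centroids[labels]) ** 2).sum(axis=1))
                )
                logger.warning("cluster %d empty after sweep %d; reseeding", c, sweep)
                centroids[c] = embedding[worst]
                labels[worst] = c
        sigma2 = max(((embedding - centroids[labels]) ** 2).sum() / (n * d), 1e-12)
        trace.append(_objective(embedding, labels, centroids, sigma2, adj, beta))
        if changed == 0:
            break

    bic = _bic(embedding, labels, centroids, sigma2, k)
    return DomainModel(
        k=k,
        beta=beta,
        centroids=centroids,
        sigma2=sigma2,
        labels=labels,
        bic=bic,
        n_sweeps_run=sweeps,
        objective_trace=np.asarray(trace),
    )


def _bic(embedding, labels, centroids, sigma2, k) -> float:
    n, d = embedding.shape
    sq = ((embedding - centroids[labels]) ** 2).sum()
    loglik = -n * d / 2 * np.log(2 * np.pi * sigma2) - sq / (2 * sigma2)
    p = k * d + 1
    return float(-2 * loglik + p * np.log(n))


def select_k(
    embedding,
    coords,
    k_range,
    beta: float = 1.0,
    seed: int = 0,
    **kwargs,
):
    """Choose the cluster count by BIC over ``k_range``.

    Returns ``(k_best, curve)`` with ``curve`` a list of dicts carrying the
    BIC for every k plus the elbow (maximum second difference) flag.
    """
    k_range = list(k_range)
    if len(k_range) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if sorted(k_range) != k_range:
        raise ValueError("k_range must be ascending")
    bics = []
    for k in k_range:
        try:
            model = cluster_spatial(embedding, coords, k, beta=beta, seed=seed, **kwargs)
        except Exception as exc:  # propagate with the offending k
            raise RuntimeError(f"clustering failed at k={k}: {exc}") from exc
        bics.append(model.bic)
    bics = np.asarray(bics)
    k_best = int(k_range[int(np.argmin(bics))])
    second_diff = np.full(len(k_range), -np.inf)
    if len(k_range) >= 3:
        second_diff[1:-1] = bics[:-2] - 2 * bics[1:-1] + bics[2:]
    elbow_k = int(k_range[int(np.argmax(second_diff))])
    curve = [
        {
            "k": int(k),
            "bic": float(b),
            "is_min": int(k) == k_best,
            "is_elbow": int(k) == elbow_k,
        }
        for k, b in zip(k_range, bics)
    ]
    return k_best, curve


def annotate_domains(labels, counts, gene_ids, marker_sets) -> tuple[np.ndarray, dict]:
    """Name clusters by their mean z-scored marker expression.

    Each cluster is assigned the domain whose marker genes score highest
    averaged over the cluster's spots; several clusters may share one domain
    name.  A tie within 1e-12 leaves the cluster UNASSIGNED.

    Returns ``(per_spot_domains, cluster_to_domain)``.
    """
    labels = np.asarray(labels)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for dom, genes in marker_sets.items():
        if not genes:
            raise ValueError(f"empty marker set for domain {dom!r}")
        missing = [g for g in genes if g not in gene_index]
        if missing:
            raise ValueError(f"marker genes absent for domain {dom!r}: {missing}")
    logn = normalize_expression(counts)
    mu = logn.mean(axis=0)
    sd = logn.std(axis=0)
    z = (logn - mu) / np.where(sd > 0, sd, 1.0)
    domains = sorted(marker_sets)
    mapping: dict = {}
    for c in np.unique(labels):
        mask = labels == c
        scores = np.array(
            [z[np.ix_(mask, [gene_index[g] for g in marker_sets[dom]])].mean() for dom in domains]
        )
        order = np.argsort(-scores)
        if len(scores) > 1 and scores[order[0]] - scores[order[1]] <= 1e-12:
            logger.warning("cluster %s: marker-score tie, leaving UNASSIGNED", c)
            mapping[int(c)] = UNASSIGNED
        else:
            mapping[int(c)] = domains[order[0]]
    return np.asarray([mapping[int(c)] for c in labels], dtype=object), mapping


def assign_domains(
    spots_list: list[SpotMatrix],
    marker_sets,
    k_range=None,
    beta: float = 1.0,
    n_hvg: int = 2000,
    d: int = 20,
    m_neighbors: int = 6,
    seed: int = 0,
):
    """End-to-end domain assignment across samples (joint embedding).

    Samples are embedded jointly after per-spot library-size normalization;
    the spatial neighbor graph never crosses sample boundaries.  Returns
    ``(domains, model, curve)`` with ``domains`` aligned to the concatenated
    spot order.
    """
    counts = np.vstack([sm.counts for sm in spots_list])
    coords = np.vstack(
        [np.column_stack([sm.x, sm.y]) for sm in spots_list]
    )
    sample_ids = np.concatenate(
        [np.repeat(sm.sample_id, sm.n_spots) for sm in spots_list]
    )
    gene_ids = spots_list[0].gene_ids
    emb = normalize_embed(counts, n_hvg=n_hvg, d=d)
    if k_range is None:
        k_range = range(8, 15, 2)
    k_best, curve = select_k(
        emb, coords, list(k_range), beta=beta, seed=seed,
        m_neighbors=m_neighbors, sample_ids=sample_ids,
    )
    model = cluster_spatial(
        emb, coords, k_best, beta=beta, seed=seed,
        m_neighbors=m_neighbors, sample_ids=sample_ids,
    )
    domains, _ = annotate_domains(model.labels, counts, gene_ids, marker_sets)
    return domains, model, curve
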