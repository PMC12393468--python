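"""Reference-based spot deconvolution and per-spot expression allocation.

Each spot's gene counts are modeled as Multinomial(N_s, sum_k theta_k phi_k):
a mixture of the reference cell-type expression fractions phi with unknown
per-spot proportions theta on the simplex.  theta is estimated by EM
(maximum likelihood), and the observed counts are then re-allocated to cell
types by their conditional expectation,

    Z[k, g] = x[g] * theta_k phi[k, g] / sum_j theta_j phi[j, g],

which conserves counts exactly (sum_k Z[k, g] = x[g]).  A non-negative
least-squares estimator is provided as an internal second method, and a
split-half reference permutation benchmark quantifies the stability of the
allocated expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import ReferencePanel, SpotMatrix, build_reference


@dataclass
class DeconvolutionResult:
    """Per-spot fractions theta (S x K) and allocations Z (S x K x G)."""

    cell_types: list
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    theta: np.ndarray
    allocations: np.ndarray
    loglik_trace: list
    method: str


def align_gene_universe(spots: SpotMatrix, panel: ReferencePanel):
    """Intersect the spot and reference gene universes.

    Returns ``(counts, phi, gene_ids)`` restricted to shared genes (in spot
    order), with phi rows re-normalized to sum to one.
    """
    ref_index = {g: i for i, g in enumerate(panel.gene_ids)}
    keep = [i for i, g in enumerate(spots.gene_ids) if g in ref_index]
    if not keep:
        raise ValueError("no shared genes between spots and reference")
    gene_ids = spots.gene_ids[keep]
    counts = spots.counts[:, keep]
    phi = panel.phi[:, [ref_index[g] for g in gene_ids]]
    phi = phi / phi.sum(axis=1, keepdims=True)
    return counts, phi, gene_ids


def filter_reference_genes(panel: ReferencePanel, max_fraction: float = 0.1) -> ReferencePanel:
    """Drop genes whose expression fraction exceeds ``max_fraction`` in any
    type (mitochondrial/ribosomal-like dominance), re-normalizing phi."""
    keep = (panel.phi <= max_fraction).all(axis=0)
    if not keep.any():
        raise ValueError("reference outlier filter removed every gene")
    phi = panel.phi[:, keep]
    phi = phi / phi.sum(axis=1, keepdims=True)
    return ReferencePanel(
        cell_types=list(panel.cell_types),
        phi=phi,
        gene_ids=panel.gene_ids[keep],
        n_cells_per_type=panel.n_cells_per_type,
        pseudocount=panel.pseudocount,
    )


def em_fractions(x, phi, max_iter: int = 500, tol: float = 1e-6):
    """EM for one spot's cell-type fractions under the multinomial mixture.

    E-step: r[k, g] = theta_k phi[k, g] / sum_j theta_j phi[j, g];
    M-step: theta_k <- sum_g x_g r[k, g] / sum_g x_g.  Initialized uniform,
    stopped at ``max|d theta| < tol``.  Returns ``(theta, loglik_trace)``
    with the trace of l(theta) = sum_g x_g log sum_k theta_k phi[k, g].
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if x.sum() <= 0:
        raise ValueError("spot has zero total counts")
    if np.isnan(phi).any():
        raise ValueError("phi contains NaN")
    theta, trace = _em_batch(x[None, :], phi, max_iter=max_iter, tol=tol)
    return theta[0], [t[0] for t in trace]


def _em_batch(X, phi, max_iter: int = 500, tol: float = 1e-6):
    """Vectorized EM over all spots at once (same updates as em_fractions)."""
    X = np.asarray(X, dtype=float)
    S, G = X.shape
    K = phi.shape[0]
    N = X.sum(axis=1, keepdims=True)
    theta = np.full((S, K), 1.0 / K)
    trace = []
    for _ in range(max_iter):
        mix = theta @ phi  # S x G
        trace.append(np.einsum("sg,sg->s", X, np.log(mix)))
        new_theta = theta * ((X / mix) @ phi.T) / N
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            break
    mix = theta @ phi
    trace.append(np.einsum("sg,sg->s", X, np.log(mix)))
    return theta, trace


def nnls_fractions(x, phi):
    """Fractions by non-negative least squares on the normalized profile.

    Solves min_{theta>=0} ||x/sum(x) - phi^T theta||_2 then renormalizes
    theta to the simplex.  Internal second estimator for cross-method
    comparison.
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if x.sum() <= 0:
        raise ValueError("spot has zero total counts")
    K = phi.shape[0]
    for i in range(K):
        for j in range(i + 1, K):
            if np.allclose(phi[i], phi[j]):
                warnings.warn(
                    f"degenerate reference: phi rows {i} and {j} identical",
                    stacklevel=2,
                )
    theta, _ = optimize.nnls(phi.T, x / x.sum())
    total = theta.sum()
    if total <= 0:
        raise ValueError("NNLS returned the all-zero solution")
    return theta / total


def allocate(x, theta, phi) -> np.ndarray:
    """Conditional-expectation allocation of one spot's counts to types."""
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if abs(theta.sum() - 1.0) > 1e-6 or (theta < -1e-12).any():
        raise ValueError("theta must lie on the simplex")
    num = theta[:, None] * phi  # K x G
    denom = num.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        resp = np.where(denom > 0, num / denom, 0.0)
    return resp * x[None, :]


def deconvolve_all(
    spots: SpotMatrix,
    panel: ReferencePanel,
    method: str = "em",
    max_iter: int = 500,
    tol: float = 1e-6,
) -> DeconvolutionResult:
    """Estimate theta and allocations Z for every spot of a sample.

    Fully deterministic.  Spots with zero total counts over the shared gene
    universe raise with the offending spot ids.
    """
    counts, phi, gene_ids = align_gene_universe(spots, panel)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(spots.spot_ids[totals == 0])
        raise ValueError(f"spots with zero counts on shared genes: {bad}")
    if method == "em":
        theta, trace_arrs = _em_batch(counts, phi, max_iter=max_iter, tol=tol)
        trace = list(np.asarray(trace_arrs).T)
    elif method == "nnls":
        theta = np.vstack([nnls_fractions(x, phi) for x in counts])
        trace = [np.array([]) for _ in range(len(counts))]
    else:
        raise ValueError(f"unknown method {method!r}")
    S, G = counts.shape
    K = phi.shape[0]
    Z = np.empty((S, K, G))
    num = theta[:, :, None] * phi[None, :, :]
    denom = num.sum(axis=1, keepdims=True)
    np.divide(num, denom, out=Z, where=denom > 0)
    Z[np.broadcast_to(denom == 0, Z.shape)] = 0.0
    Z *= counts[:, None, :]
    return DeconvolutionResult(
        cell_types=list(panel.cell_types),
        gene_ids=gene_ids,
        spot_ids=spots.spot_ids,
        theta=theta,
        allocations=Z,
        loglik_trace=trace,
        method=method.upper(),
    )


def split_half_consistency(
    cell_counts,
    cell_labels,
    spots: SpotMatrix,
    gene_ids,
    n_splits: int = 4,
    seed: int = 0,
    pseudocount: float = 0.5,
    method: str = "em",
):
    """Split-half reference permutation benchmark of allocation stability.

    For each split the reference cells of every type are shuffled (seeded)
    and halved; each half yields its own phi, the tissue is deconvolved with
    both, and for each cell type the Pearson correlation between the two
    vectorized allocation blocks (all spots x genes) is recorded.  With odd
    cell counts the first half receives the extra cell.

    Returns ``(per_split, mean_correlation)`` where ``per_split`` is a list
    of dicts ``{cell_type: r}``.
    """
    cell_counts = np.asarray(cell_counts)
    cell_labels = np.asarray(cell_labels, dtype=object)
    types = sorted(set(cell_labels))
    for ct in types:
        if (cell_labels == ct).sum() < 4:
            raise ValueError(f"cell type {ct!r} has fewer than 4 cells")
    rng = np.random.default_rng(seed)
    per_split = []
    for _ in range(n_splits):
        idx_a, idx_b = [], []
        for ct in types:
            idx = np.flatnonzero(cell_labels == ct)
            rng.shuffle(idx)
            half = (len(idx) + 1) // 2
            idx_a.extend(idx[:half])
            idx_b.extend(idx[half:])
        res = {}
        results = []
        for part in (idx_a, idx_b):
            panel = build_reference(
                cell_counts[part], cell_labels[part], gene_ids, pseudocount
            )
            results.append(deconvolve_all(spots, panel, method=method))
        for k, ct in enumerate(results[0].cell_types):
            a = results[0].allocations[:, k, :].ravel()
            b = results[1].allocations[:, k, :].ravel()
            res[ct] = float(stats.pearsonr(a, b)[0])
        per_split.append(res)
    mean_corr = float(np.mean([np.mean(list(d.values())) for d in per_split]))
    return per_split, mean_corr


def compare_proportions(theta_a, theta_b, cell_types):
    """Per-type Spearman correlation of two fraction estimates across spots.

    Returns a list of dicts with rho and two-sided p; constant columns are
    flagged (``defined=False``) rather than propagating NaN.
    """
    theta_a = np.asarray(theta_a, dtype=float)
    theta_b = np.asarray(theta_b, dtype=float)
    if theta_a.shape != theta_b.shape:
        raise ValueError("theta matrices must share spots and types")
    out = []
    for k, ct in enumerate(cell_types):
        a, b = theta_a[:, k], theta_b[:, k]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            out.append({"cell_type": ct, "rho": None, "p": None, "defined": False})
            continue
        rho, p = stats.spearmanr(a, b)
        out.append(
            {"cell_type": ct, "rho": float(rho), "p": float(p), "defined": True}
        )
    return out
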