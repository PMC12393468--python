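"""Rank-based marker/DGE statistics, set logic and composition tests.

The differential-expression machinery is the two-sample Mann-Whitney
rank-sum test (the test scanpy's ``rank_genes_groups`` actually performs)
with Benjamini-Hochberg FDR control at adjusted p < 0.05.  Fold changes are
computed on de-logged means of the 10k-scaled log1p-normalized expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .domains import normalize_expression

logger = logging.getLogger(__name__)

ALPHA = 0.05
_LOG2FC_EPS = 1e-9


def rank_sum_test(a, b, mode: str = "auto"):
    """Two-sample Mann-Whitney rank-sum test; returns ``(U, p_two_sided)``.

    ``mode='auto'`` uses the exact null distribution when both samples have
    at most 10 observations and there are no ties, else the tie-corrected
    normal approximation with continuity correction.  ``U`` is the statistic
    for sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
        mode = "exact" if (max(a.size, b.size) <= 10 and no_ties) else "normal"
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2fc(mean_in, mean_out) -> np.ndarray:
    return np.log2(
        (np.expm1(mean_in) + _LOG2FC_EPS) / (np.expm1(mean_out) + _LOG2FC_EPS)
    )


def rank_markers(
    counts,
    labels,
    target,
    gene_ids,
    normalized: bool = False,
) -> pd.DataFrame:
    """One-vs-rest differential expression for ``target``.

    Counts are 10k-scaled and log1p-transformed unless ``normalized=True``;
    the rank-sum test runs per gene with the tie-corrected normal
    approximation, BH adjustment is applied across genes, and log2FC is
    computed on de-logged means.  Returns a table with one row per gene.
    """
    labels = np.asarray(labels, dtype=object)
    if target not in labels:
        raise ValueError(f"target {target!r} not present in labels")
    mask_in = labels == target
    n_in, n_out = int(mask_in.sum()), int((~mask_in).sum())
    if n_in < 2 or n_out < 2:
        raise ValueError("each group needs at least 2 observations")
    X = np.asarray(counts, dtype=float)
    logn = X if normalized else normalize_expression(X)
    a, b = logn[mask_in], logn[~mask_in]
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    mean_in = a.mean(axis=0)
    mean_out = b.mean(axis=0)
    return pd.DataFrame(
        {
            "gene": np.asarray(gene_ids, dtype=object),
            "group": target,
            "log2FC": _log2fc(mean_in, mean_out),
            "U": np.asarray(res.statistic, dtype=float),
            "p": p,
            "p_adj": bh_adjust(p),
            "mean_in": mean_in,
            "mean_out": mean_out,
            "n_in": n_in,
            "n_out": n_out,
        }
    )


def pick_domain_marker(dge: pd.DataFrame):
    """The marker gene of a contrast: highest log2FC among significant
    positive rows; ties broken by smaller p then lexicographic gene id.
    Returns ``None`` when no row qualifies."""
    if dge.empty:
        raise ValueError("empty DGE table")
    hits = dge[(dge["p_adj"] < ALPHA) & (dge["log2FC"] > 0)]
    if hits.empty:
        logger.warning("no significant positive marker; returning None")
        return None
    hits = hits.sort_values(
        ["log2FC", "p", "gene"], ascending=[False, True, True], kind="stable"
    )
    return hits.iloc[0]["gene"]


def pairwise_group_dge(counts, group_labels, gene_ids, groups=None, normalized=False):
    """All pairwise two-group DGE tables.

    Returns ``{(X, Y): table}`` for ordered pairs X < Y in ``groups`` order;
    each table's log2FC/U is oriented as X versus Y.
    """
    group_labels = np.asarray(group_labels, dtype=object)
    if groups is None:
        groups = sorted(set(group_labels))
    tables = {}
    for i, gx in enumerate(groups):
        for gy in groups[i + 1 :]:
            mask = (group_labels == gx) | (group_labels == gy)
            tables[(gx, gy)] = rank_markers(
                np.asarray(counts)[mask],
                group_labels[mask],
                gx,
                gene_ids,
                normalized=normalized,
            )
    return tables


def unique_up_sets(tables: dict, groups=("AC", "PART", "AD"), alpha: float = ALPHA):
    """Genes uniquely upregulated in each group versus BOTH other groups.

    ``tables`` maps ordered pairs ``(X, Y)`` to two-group DGE tables oriented
    X-vs-Y (as produced by :func:`pairwise_group_dge`).  A gene is uniquely
    up in X iff it is significant (p_adj < alpha) with positive fold change
    against each of the two other groups; the sets are disjoint across
    groups by construction.
    """
    def up_genes(x, y):
        if (x, y) in tables:
            t = tables[(x, y)]
            hits = t[(t["p_adj"] < alpha) & (t["log2FC"] > 0)]
        elif (y, x) in tables:
            t = tables[(y, x)]
            hits = t[(t["p_adj"] < alpha) & (t["log2FC"] < 0)]
        else:
            raise ValueError(f"missing contrast between {x!r} and {y!r}")
        return set(hits["gene"])

    out = {}
    for g in groups:
        others = [h for h in groups if h != g]
        sets = [up_genes(g, h) for h in others]
        out[g] = set.intersection(*sets) if sets else set()
    return out


def composition_test(theta, domains, group_labels, cell_types, groups=None) -> pd.DataFrame:
    """Welch two-sample t-tests on per-spot fractions within each domain.

    One row per (domain, cell type, group contrast); BH adjustment is applied
    jointly across all rows.  Degenerate contrasts (zero variance in both
    groups) are reported as t = 0, p = 1 and flagged.
    """
    theta = np.asarray(theta, dtype=float)
    domains = np.asarray(domains, dtype=object)
    group_labels = np.asarray(group_labels, dtype=object)
    if groups is None:
        groups = sorted(set(group_labels))
    rows = []
    for dom in sorted(set(domains)):
        dmask = domains == dom
        for k, ct in enumerate(cell_types):
            for i, ga in enumerate(groups):
                for gb in groups[i + 1 :]:
                    a = theta[dmask & (group_labels == ga), k]
                    b = theta[dmask & (group_labels == gb), k]
                    if len(a) < 2 or len(b) < 2:
                        raise ValueError(
                            f"domain {dom!r} needs >=2 spots per group "
                            f"({ga}: {len(a)}, {gb}: {len(b)})"
                        )
                    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                        t, p, flag = 0.0, 1.0, True
                    else:
                        t, p = sps.ttest_ind(a, b, equal_var=False)
                        flag = False
                    rows.append(
                        {
                            "domain": dom,
                            "cell_type": ct,
                            "contrast": f"{ga}_vs_{gb}",
                            "t": float(t),
                            "p": float(p),
                            "n_a": len(a),
                            "n_b": len(b),
                            "degenerate": flag,
                        }
                    )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df
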