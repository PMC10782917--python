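"""Domain marker detection: one-vs-rest Wilcoxon rank-sum tests.

For every identified domain each gene is tested for differential expression
between the domain's spots and all remaining spots, with Benjamini–Hochberg
adjustment across the genes of each domain's test family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import DomainLabels
from .io import ExpressionMatrix


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    adj_(i) = min_{j >= i} (p_(j) · m / j), clipped at 1, for the ascending
    order statistics p_(1) <= ... <= p_(m).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _rank_sum_asymptotic(x: np.ndarray, in_group: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized tie-corrected normal approximation over all genes at once.

    Returns (U, z, p) arrays of length n_genes for the two-sided test of the
    ``in_group`` spots against the rest; z > 0 means higher in the group.
    """
    n = x.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = stats.rankdata(x, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    U = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction: sum of (t^3 - t) over tied groups, per gene
    tie_term = np.zeros(x.shape[1])
    for g in range(x.shape[1]):
        _, counts = np.unique(x[:, g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (U - mu) / sigma
    z = np.where(sigma > 0, z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return U, z, np.minimum(p, 1.0)


def wilcoxon_deg(
    norm: ExpressionMatrix,
    labels: DomainLabels,
    min_cells: int = 3,
    family: str = "per_domain",
) -> pd.DataFrame:
    """One-vs-rest rank-sum tests for every (domain, gene) pair.

    Uses the exact null distribution when the pooled sample is small
    (n < 20, no ties) and the tie-corrected normal approximation otherwise.
    The log2 fold change is computed on expm1-backtransformed means of the
    log-normalized values. ``family`` controls the BH adjustment family:
    the genes of one domain's comparison (default) or all tests globally.
    Returns a table sorted within each domain by adjusted p-value.
    """
    if norm.layer != "normalized":
        raise ValueError("wilcoxon_deg expects normalized data")
    if labels.n_spots != norm.n_spots:
        raise ValueError("labels and expression matrix are not aligned")
    x = norm.dense().astype(float)
    n = x.shape[0]
    frames = []
    for d in range(labels.K):
        in_group = labels.labels == d
        n1 = int(in_group.sum())
        if n1 == 0:
            continue
        if n1 < min_cells:
            warnings.warn(f"domain {d} has {n1} < {min_cells} spots; skipped")
            continue
        if n < 20:
            U = np.empty(x.shape[1])
            z = np.empty(x.shape[1])
            p = np.empty(x.shape[1])
            for g in range(x.shape[1]):
                a, b = x[in_group, g], x[~in_group, g]
                has_ties = np.unique(np.concatenate([a, b])).size < n
                method = "asymptotic" if has_ties else "exact"
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
                U[g], p[g] = res.statistic, res.pvalue
                mu, sd = n1 * (n - n1) / 2.0, np.sqrt(n1 * (n - n1) * (n + 1) / 12.0)
                z[g] = (U[g] - mu) / sd if sd > 0 else 0.0
        else:
            U, z, p = _rank_sum_asymptotic(x, in_group)
        mean_in = np.maximum(np.expm1(x[in_group]).mean(axis=0), 0.0)
        mean_out = np.maximum(np.expm1(x[~in_group]).mean(axis=0), 0.0)
        lfc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        frames.append(
            pd.DataFrame(
                {
                    "gene": norm.gene_ids,
                    "domain": d,
                    "log2fc": lfc,
                    "statistic": U,
                    "z": z,
                    "pval": p,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["gene", "domain", "log2fc", "statistic", "z", "pval", "pval_adj"])
    table = pd.concat(frames, ignore_index=True)
    if family == "per_domain":
        table["pval_adj"] = table.groupby("domain")["pval"].transform(lambda s: bh_adjust(s.to_numpy()))
    elif family == "global":
        table["pval_adj"] = bh_adjust(table["pval"].to_numpy())
    else:
        raise ValueError(f"unknown family {family!r}")
    table = table.sort_values(["domain", "pval_adj", "pval", "gene"], kind="stable").reset_index(drop=True)
    return table
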