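"""Exon-intron split analysis (EISA), reimplemented from scratch.

Contrasts exonic (mature mRNA) against intronic (pre-mRNA) count changes
between two conditions to separate transcriptional from post-transcriptional
regulation. Both matrices are TMM-normalized independently; the significance
of the exon-intron interaction comes from a per-gene NB log-linear model

    log mu = b0 + b1*condition + b2*count_type + b3*condition:count_type

with a likelihood-ratio test on the interaction term, dispersion shared
across genes (one common method-of-moments value per count type). Genes with
FDR below the threshold (default 0.001), positive interaction and positive
residual above the Dexon ~ Dintron best-fit line are classed
post-transcriptional.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import NormFactors, bh_fdr, mom_dispersions, tmm_factors

log = logging.getLogger(__name__)

PHI_FLOOR = 1e-6
CLASSES = ("post_transcriptional", "transcriptional", "mixed", "unclassified")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: float) -> np.ndarray:
    from scipy.special import gammaln

    mu = np.clip(mu, 1e-10, None)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    )


def _fit_cells(y: np.ndarray, offs: np.ndarray, cells: list[np.ndarray], phis: np.ndarray,
               n_iter: int = 60) -> np.ndarray:
    """Saturated-cell NB MLE loglik per gene (Fisher scoring per cell)."""
    ll = np.zeros(y.shape[0])
    for idx in cells:
        sub = y[:, idx].astype(float)
        L = np.exp(offs[idx])
        phi = float(phis[idx][0])
        beta = np.log((sub.sum(axis=1) + 0.5) / L.sum())
        for _ in range(n_iter):
            mu = np.exp(beta)[:, None] * L[None, :]
            score = ((sub - mu) / (1.0 + phi * mu)).sum(axis=1)
            info = (mu / (1.0 + phi * mu)).sum(axis=1)
            step = score / np.clip(info, 1e-12, None)
            beta = beta + np.clip(step, -5, 5)
        mu = np.exp(beta)[:, None] * L[None, :]
        ll += _nb_loglik(sub, mu, 1.0 / phi).sum(axis=1)
    return ll


def _fit_glm(y: np.ndarray, X: np.ndarray, offs: np.ndarray, phis: np.ndarray,
             n_iter: int = 60) -> np.ndarray:
    """Vectorized IRLS for an NB log-linear model with known dispersion.

    Returns the maximized log-likelihood per gene. ``phis`` gives the
    dispersion of each observation (column); the likelihood uses each
    observation's own value.
    """
    G, S = y.shape
    p = X.shape[1]
    yf = y.astype(float)
    # moment init: intercept at the offset-adjusted mean
    beta = np.zeros((G, p))
    beta[:, 0] = np.log((yf.sum(axis=1) + 0.5) / np.exp(offs).sum())
    for _ in range(n_iter):
        eta = beta @ X.T + offs[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phis[None, :] * mu)
        z = (eta - offs[None, :]) + (yf - mu) / mu
        A = np.einsum("si,gs,sj->gij", X, w, X)
        b = np.einsum("si,gs,gs->gi", X, w, z)
        A += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(A, b[..., None])[..., 0]
        beta = beta + np.clip(new - beta, -5, 5)
    eta = np.clip(beta @ X.T + offs[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    ll = np.zeros(G)
    for s in range(S):
        ll += _nb_loglik(yf[:, s], mu[:, s], 1.0 / phis[s])
    return ll


def _normalized(counts: pd.DataFrame, factors: NormFactors) -> pd.DataFrame:
    eff = factors.effective_lib_sizes
    scale = float(np.exp(np.mean(np.log(eff))))
    return counts / eff * scale


def eisa(
    exonic: pd.DataFrame,
    intronic: pd.DataFrame,
    condition: pd.Series,
    condition_a: str,
    condition_b: str,
    min_log2_mean: float = 5.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene exon/intron log2 fold changes and interaction significance.

    Returns a frame with gene, d_exon, d_intron (log2FC of ``condition_b``
    over ``condition_a``), d_diff = d_exon - d_intron, p, fdr for the
    interaction, and intron_p/intron_fdr for a condition-only test on the
    intronic counts (used by :func:`classify_regulation`). Genes must pass
    ``min_log2_mean`` (mean log2 normalized count) in both matrices.
    """
    shared = exonic.index.intersection(intronic.index)
    dropped = len(exonic.index.union(intronic.index)) - len(shared)
    if dropped:
        log.info("excluding %d genes missing from one of the matrices", dropped)
    if len(shared) == 0:
        raise ValueError("no shared genes between exonic and intronic matrices")
    ex = exonic.loc[shared]
    it = intronic.loc[shared]

    f_ex = tmm_factors(ex)
    f_it = tmm_factors(it)
    norm_ex = _normalized(ex, f_ex)
    norm_it = _normalized(it, f_it)
    keep = (np.log2(norm_ex + 1).mean(axis=1) >= min_log2_mean) & (
        np.log2(norm_it + 1).mean(axis=1) >= min_log2_mean
    )
    ex, it = ex.loc[keep], it.loc[keep]
    norm_ex, norm_it = norm_ex.loc[keep], norm_it.loc[keep]
    if ex.shape[0] == 0:
        raise ValueError("no genes pass the expression filter")

    cols_a = [c for c in ex.columns if condition[c] == condition_a]
    cols_b = [c for c in ex.columns if condition[c] == condition_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >=2 replicates per condition")

    d_exon = np.log2(
        (norm_ex[cols_b].mean(axis=1) + pseudocount) / (norm_ex[cols_a].mean(axis=1) + pseudocount)
    )
    d_intron = np.log2(
        (norm_it[cols_b].mean(axis=1) + pseudocount) / (norm_it[cols_a].mean(axis=1) + pseudocount)
    )

    # common dispersion per count type, shared across genes
    ia = np.array([ex.columns.get_loc(c) for c in cols_a])
    ib = np.array([ex.columns.get_loc(c) for c in cols_b])
    _, phi_ex = mom_dispersions(norm_ex.values, [ia, ib])
    _, phi_it = mom_dispersions(norm_it.values, [ia, ib])
    phi_ex = max(phi_ex, PHI_FLOOR)
    phi_it = max(phi_it, PHI_FLOOR)

    order = cols_a + cols_b
    y = np.hstack([ex[order].values, it[order].values])
    offs = np.concatenate(
        [np.log(f_ex.effective_lib_sizes[order].values), np.log(f_it.effective_lib_sizes[order].values)]
    )
    n_a, n_b = len(cols_a), len(cols_b)
    cond = np.concatenate([np.repeat([0.0, 1.0], [n_a, n_b])] * 2)
    ctype = np.repeat([0.0, 1.0], [n_a + n_b, n_a + n_b])  # 0 = exon, 1 = intron
    phis = np.where(ctype == 0, phi_ex, phi_it)

    cells = [
        np.nonzero((cond == ci) & (ctype == ti))[0] for ci in (0, 1) for ti in (0, 1)
    ]
    ll_full = _fit_cells(y, offs, cells, phis)
    X_red = np.column_stack([np.ones_like(cond), cond, ctype])
    ll_red = _fit_glm(y, X_red, offs, phis)
    lrt = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    pvals = stats.chi2.sf(lrt, df=1)

    # condition-only test on intronic counts (for the transcriptional class)
    y_it = it[order].values
    offs_it = np.log(f_it.effective_lib_sizes[order].values)
    phis_it = np.full(len(order), phi_it)
    cond_it = np.repeat([0.0, 1.0], [n_a, n_b])
    cells_it = [np.nonzero(cond_it == ci)[0] for ci in (0, 1)]
    ll_it_full = _fit_cells(y_it, offs_it, cells_it, phis_it)
    ll_it_red = _fit_glm(y_it, np.ones((len(order), 1)), offs_it, phis_it)
    p_it = stats.chi2.sf(np.clip(2.0 * (ll_it_full - ll_it_red), 0.0, None), df=1)

    return pd.DataFrame(
        {
            "gene": ex.index,
            "d_exon": d_exon.values,
            "d_intron": d_intron.values,
            "d_diff": (d_exon - d_intron).values,
            "p": pvals,
            "fdr": bh_fdr(pvals),
            "intron_p": p_it,
            "intron_fdr": bh_fdr(p_it),
        }
    ).reset_index(drop=True)


def classify_regulation(
    results: pd.DataFrame, fdr_threshold: float = 0.001
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Class labels plus the Dexon-on-Dintron best-fit line.

    Ordinary least squares over all tested genes; a gene is
    ``post_transcriptional`` when its interaction FDR is below the
    threshold, d_diff > 0 and it lies above the line (positive residual);
    ``transcriptional`` when the intron shift dominates (|d_intron| >
    |d_diff|) and is itself significant; significant leftovers are
    ``mixed``; the rest ``unclassified``.
    """
    if len(results) < 10:
        raise ValueError("need >=10 genes to fit the regression line")
    x = results["d_intron"].values
    yv = results["d_exon"].values
    if np.ptp(x) == 0:
        raise ValueError("degenerate d_intron (all equal); line undefined")
    slope, intercept, *_ = stats.linregress(x, yv)
    residual = yv - (intercept + slope * x)

    out = results.copy()
    out["residual"] = residual
    sig = out["fdr"] < fdr_threshold
    ptx = sig & (out["d_diff"] > 0) & (residual > 0)
    tx = (
        ~ptx
        & (out["d_intron"].abs() > out["d_diff"].abs())
        & (out["intron_fdr"] < fdr_threshold)
    )
    mixed = ~ptx & ~tx & (sig | (out["intron_fdr"] < fdr_threshold))
    out["class"] = "unclassified"
    out.loc[mixed, "class"] = "mixed"
    out.loc[tx, "class"] = "transcriptional"
    out.loc[ptx, "class"] = "post_transcriptional"
    return out, (float(slope), float(intercept))
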