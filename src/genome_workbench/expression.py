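"""Tissue specificity (tau) and NB quasi-likelihood differential expression.

The tau index summarizes how concentrated a gene's expression is in one
tissue: with per-tissue expression x_i rescaled by the maximum tissue,
tau = sum(1 - x_i) / (N - 1) over N tissues; 0 means uniform expression, 1
means a single expressing tissue. Genes with tau >= 0.95 are assigned to
their maximally expressing tissue.

Differential expression between conditions within a tissue uses a
negative-binomial model: tagwise dispersions are estimated by adjusted
profile likelihood, shrunk toward a lowess mean-dispersion trend by
empirical-Bayes weighting, and genes are tested with a quasi-likelihood F
test (deviance drop scaled by a squeezed quasi-dispersion, with residual
plus prior degrees of freedom). This is a deliberately simplified
reimplementation of the standard QL machinery: exact numerical agreement
with any published package is out of scope, calibration is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import f as f_dist
from statsmodels.nonparametric.smoothers_lowess import lowess


# --------------------------------------------------------------------------
# filtering and normalization
# --------------------------------------------------------------------------

def smallest_group_size(meta: pd.DataFrame) -> int:
    """X = the number of replicates in the smallest (tissue, condition) group."""
    return int(meta.groupby(["tissue", "condition"]).size().min())


def filter_counts(counts: pd.DataFrame, meta: pd.DataFrame,
                  gene_lengths: pd.Series, min_gene_length: int = 200,
                  count_floor: int = 10) -> pd.DataFrame:
    """Length filter then low-expression filter; returns a sub-matrix.

    Genes shorter than ``min_gene_length`` (strict <) are removed; then genes
    are kept only if at least X samples have counts >= ``count_floor``, where
    X is the size of the smallest condition group.
    """
    missing = meta.index.difference(counts.columns)
    if len(missing):
        raise ValueError(f"samples missing from counts: {list(missing)}")
    if meta["tissue"].isna().any() or (meta.groupby("tissue").size() == 0).any():
        raise ValueError("every tissue needs at least one sample")
    if counts.empty:
        return counts
    keep_len = gene_lengths.reindex(counts.index) >= min_gene_length
    out = counts.loc[keep_len]
    x = smallest_group_size(meta)
    keep_expr = (out[meta.index] >= count_floor).sum(axis=1) >= x
    return out.loc[keep_expr]


def cpm(counts: pd.DataFrame, log: bool = False,
        prior: float = 0.5) -> pd.DataFrame:
    """Counts per million by library size; optional log2 with a pseudo-count."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    out = counts.div(lib, axis=1) * 1e6
    if log:
        out = np.log2(out + prior)
    return out


# --------------------------------------------------------------------------
# tau
# --------------------------------------------------------------------------

def tau(expr: pd.DataFrame, meta: pd.DataFrame,
        use_log: bool = False, log_prior: float = 0.5) -> pd.DataFrame:
    """Per-gene tau from per-tissue mean expression.

    ``expr`` is an expression matrix (typically CPM) with samples as columns.
    Tissue means are rescaled by the maximum tissue so x_i lies in [0, 1];
    on the log option, log2(CPM + prior) values are floored at 0 first.
    All-zero genes get tau = NaN with ``undefined`` flagged.
    """
    tissues = sorted(meta["tissue"].unique())
    if len(tissues) < 2:
        raise ValueError("tau needs at least 2 tissues")
    means = pd.DataFrame({
        t: expr[meta.index[meta["tissue"] == t]].mean(axis=1) for t in tissues
    })
    if use_log:
        means = np.log2(means + log_prior).clip(lower=0.0)
    mx = means.max(axis=1)
    x = means.div(mx.replace(0.0, np.nan), axis=0)
    n = len(tissues)
    t_val = (1.0 - x).sum(axis=1, skipna=False) / (n - 1)
    out = means.copy()
    out.columns = [f"mean_{t}" for t in tissues]
    out["tau"] = t_val
    out["max_tissue"] = means.idxmax(axis=1)
    ties = means.eq(mx, axis=0).sum(axis=1) > 1
    out["max_tie"] = ties
    out["undefined"] = mx <= 0
    out.loc[out["undefined"], ["tau"]] = np.nan
    out.loc[out["undefined"], ["max_tissue"]] = None
    return out


def assign_specificity(tau_table: pd.DataFrame,
                       threshold: float = 0.95) -> pd.DataFrame:
    """Assign genes with tau >= threshold (inclusive) to their top tissue.

    Argmax ties leave the gene unassigned with the tie flag set.
    """
    out = tau_table.copy()
    qualify = (out["tau"] >= threshold) & ~out["undefined"] & ~out["max_tie"]
    out["assigned_tissue"] = out["max_tissue"].where(qualify, None)
    return out


# --------------------------------------------------------------------------
# NB quasi-likelihood DE
# --------------------------------------------------------------------------

@dataclass
class DEOptions:
    dispersion_prior_df: float = 10.0
    ql_prior_df: float = 10.0
    lowess_frac: float = 0.4
    lfc_prior_count: float = 0.125
    alpha: float = 0.01


def _group_means(y: np.ndarray, s: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    """Per-group abundance q (counts per unit size factor): Sum y / Sum s."""
    return np.stack([y[:, m].sum(axis=1) / s[m].sum() for m in masks], axis=1)


def _size_factors(y: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, robust to composition shifts from DE genes.

    Falls back to library-size factors when too few genes are expressed in
    every sample.
    """
    lib = y.sum(axis=0)
    s = lib / lib.mean()
    pos = (y > 0).all(axis=1)
    if pos.sum() >= 50:
        logs = np.log(y[pos])
        med = np.median(logs - logs.mean(axis=1, keepdims=True), axis=0)
        s = np.exp(med)
        s = s / s.mean()
    return s


def _nb_loglik_cr(y: np.ndarray, mu: np.ndarray, phi: float,
                  masks: list[np.ndarray]) -> np.ndarray:
    """NB log-likelihood with Cox-Reid adjustment, per gene."""
    if phi < 1e-8:
        phi = 1e-8
    r = 1.0 / phi
    ll = (gammaln(y + r) - gammaln(r)
          + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu) + 1e-300)).sum(axis=1)
    w = mu / (1.0 + phi * mu)
    adj = sum(np.log(w[:, m].sum(axis=1) + 1e-300) for m in masks)
    return ll - 0.5 * adj


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Total NB deviance per gene (phi per gene)."""
    r = 1.0 / np.maximum(phi, 1e-8)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = (y + r) * np.log((y + r) / (mu + r))
    return 2.0 * (t1 - t2).sum(axis=1)


def estimate_dispersions(y: np.ndarray, s: np.ndarray, masks: list[np.ndarray],
                         prior_df: float = 10.0, lowess_frac: float = 0.4
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Tagwise NB dispersions shrunk toward a fitted mean-dispersion trend.

    Tagwise estimates maximize the Cox-Reid adjusted profile likelihood on a
    log-spaced grid; the trend is a lowess fit of log-dispersion on log-mean;
    empirical-Bayes shrinkage averages the two in log space with prior
    weight ``prior_df`` against the residual degrees of freedom.
    """
    q = _group_means(y, s, masks)
    mu = np.zeros_like(y, dtype=float)
    for gi, m in enumerate(masks):
        mu[:, m] = q[:, gi][:, None] * s[m][None, :]
    mu = np.maximum(mu, 1e-8)

    grid = np.logspace(-4, 1, 41)
    ll = np.stack([_nb_loglik_cr(y, mu, p, masks) for p in grid], axis=1)
    tag = grid[np.argmax(ll, axis=1)]

    log_mean = np.log(q.mean(axis=1) + 1e-8)
    fit = lowess(np.log(tag), log_mean, frac=lowess_frac, return_sorted=False)
    df_resid = y.shape[1] - len(masks)
    w = prior_df / (prior_df + df_resid)
    shrunk = np.exp(w * fit + (1 - w) * np.log(tag))
    return shrunk, tag


def de_test(counts: pd.DataFrame, meta: pd.DataFrame, tissue: str,
            condition_pair: tuple[str, str] | None = None,
            options: DEOptions | None = None) -> pd.DataFrame:
    """NB quasi-likelihood F test between two conditions within a tissue.

    Returns per-gene log2FC (second condition over first), dispersion, F
    statistic, p-value and the DE flag at p < alpha (default 0.01). Either
    condition having fewer than 2 replicates is an error.
    """
    opt = options or DEOptions()
    sub_meta = meta[meta["tissue"] == tissue]
    if condition_pair is None:
        conds = sorted(sub_meta["condition"].unique())
        if len(conds) != 2:
            raise ValueError("condition_pair required when not exactly 2 conditions")
        condition_pair = (conds[0], conds[1])
    c1, c2 = condition_pair
    sel = sub_meta[sub_meta["condition"].isin(condition_pair)]
    n1 = (sel["condition"] == c1).sum()
    n2 = (sel["condition"] == c2).sum()
    if n1 < 2 or n2 < 2:
        raise ValueError("each condition needs at least 2 replicates")

    y = counts[sel.index].to_numpy(dtype=float)
    s = _size_factors(y)
    m1 = (sel["condition"] == c1).to_numpy()
    m2 = (sel["condition"] == c2).to_numpy()
    masks = [m1, m2]

    disp, _ = estimate_dispersions(y, s, masks, prior_df=opt.dispersion_prior_df,
                                   lowess_frac=opt.lowess_frac)

    q = _group_means(y, s, masks)
    mu_full = np.zeros_like(y)
    mu_full[:, m1] = q[:, 0][:, None] * s[m1][None, :]
    mu_full[:, m2] = q[:, 1][:, None] * s[m2][None, :]
    q0 = y.sum(axis=1) / s.sum()
    mu_null = q0[:, None] * s[None, :]

    dev_full = _nb_deviance(y, np.maximum(mu_full, 1e-8), disp)
    dev_null = _nb_deviance(y, np.maximum(mu_null, 1e-8), disp)

    df_resid = y.shape[1] - 2
    s2 = np.maximum(dev_full, 0.0) / df_resid
    log_mean = np.log(q.mean(axis=1) + 1e-8)
    s2_trend = np.maximum(
        lowess(s2, log_mean, frac=opt.lowess_frac, return_sorted=False), 1e-8)
    df_prior = opt.ql_prior_df
    s2_post = (df_prior * s2_trend + df_resid * s2) / (df_prior + df_resid)

    F = np.maximum(dev_null - dev_full, 0.0) / np.maximum(s2_post, 1e-8)
    df_total = df_resid + df_prior
    pvals = f_dist.sf(F, 1, df_total)

    p = opt.lfc_prior_count
    log2fc = np.log2((q[:, 1] + p) / (q[:, 0] + p))

    return pd.DataFrame({
        "log2fc": log2fc, "dispersion": disp, "F": F, "pvalue": pvals,
        "de": pvals < opt.alpha, "mean_count": q.mean(axis=1),
    }, index=counts.index)


# --------------------------------------------------------------------------
# overlap and heatmap export
# --------------------------------------------------------------------------

def overlap_summary(specific: pd.DataFrame, de_genes: set[str]) -> pd.DataFrame:
    """Per-tissue overlap between tau-specific genes and DE genes.

    ``specific`` is the assign_specificity output; genes with an assigned
    tissue define the specific sets.
    """
    rows = []
    assigned = specific[specific["assigned_tissue"].notna()]
    for t, grp in assigned.groupby("assigned_tissue"):
        genes = set(grp.index)
        inter = genes & de_genes
        rows.append(dict(tissue=t, n_specific=len(genes), n_de=len(de_genes),
                         n_overlap=len(inter),
                         overlap_fraction=len(inter) / len(genes) if genes else 0.0))
    total = set(assigned.index)
    rows.append(dict(tissue="all", n_specific=len(total), n_de=len(de_genes),
                     n_overlap=len(total & de_genes),
                     overlap_fraction=(len(total & de_genes) / len(total)
                                       if total else 0.0)))
    return pd.DataFrame(rows)


def zscore_matrix(log_cpm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Z-scores of log-CPM across samples, for heatmap export."""
    mu = log_cpm.mean(axis=1)
    sd = log_cpm.std(axis=1).replace(0.0, np.nan)
    return log_cpm.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
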