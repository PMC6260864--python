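"""Negative-binomial differential expression engine.

Implements the standard count-based workflow: median-of-ratios size
factors, per-gene NB2 dispersion estimation with shrinkage toward a
mean-dispersion trend, a gene-wise negative-binomial log-link GLM fitted by
iteratively reweighted least squares (vectorised across genes), Wald tests
per contrast, and Benjamini-Hochberg adjustment over the tested genes.
Also provides the comparative-CT (ddCT) closed form for qPCR data.

The model is NB2: ``var = mu + alpha * mu**2`` with gene-wise dispersion
``alpha``, sample size factors entering as offsets on the log scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ContrastSpec,
    CountMatrix,
    DdctTable,
    SampleDesign,
    ValidationError,
    empty_contrast_result,
)

DISPERSION_MIN = 1e-8
DISPERSION_MAX = 10.0
_IRLS_TOL = 1e-10
_IRLS_MAXITER = 100


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: CountMatrix, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each zero-free gene, counts are divided by the gene's geometric mean
    across samples; a sample's size factor is the median of these ratios.
    Genes containing any zero are excluded from the reference set. If no
    gene is zero-free, set ``allow_pseudo_reference=True`` to compute the
    geometric mean over positive counts only.
    """
    if counts.scale != "raw":
        raise ValidationError("size factors are estimated from raw counts")
    values = counts.data.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(values)
    zero_free = np.all(values > 0, axis=1)
    if zero_free.any():
        log_geomean = logs[zero_free].mean(axis=1)
        log_ratios = logs[zero_free] - log_geomean[:, None]
    elif allow_pseudo_reference:
        pos = values > 0
        with np.errstate(invalid="ignore"):
            log_geomean = np.where(pos, logs, 0.0).sum(axis=1) / np.maximum(pos.sum(axis=1), 1)
        usable = pos.any(axis=1)
        log_ratios = np.where(pos, logs - log_geomean[:, None], np.nan)[usable]
    else:
        raise ValidationError(
            "no gene has positive counts in every sample; "
            "rerun with allow_pseudo_reference=True"
        )
    sf = np.exp(np.nanmedian(log_ratios, axis=0))
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def normalize(counts: CountMatrix, size_factors: pd.Series) -> CountMatrix:
    """Divide each sample's counts by its size factor."""
    if counts.scale != "raw":
        raise ValidationError("normalize expects raw counts")
    sf = size_factors.reindex(counts.sample_ids)
    if sf.isna().any() or len(size_factors) != counts.n_samples:
        raise ValidationError("size factors do not match the matrix samples")
    if (sf <= 0).any():
        raise ValidationError("size factors must be positive")
    return CountMatrix(counts.data / sf, scale="normalized")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersions(
    counts: CountMatrix,
    design: SampleDesign,
    size_factors: pd.Series,
) -> pd.Series:
    """Per-gene NB2 dispersion estimates.

    Method-of-moments on normalized counts pooled within design cells
    (one cell per combination of factor levels), shrunk 50/50 in log space
    toward a log-linear mean-dispersion trend fitted across genes, and
    clamped to ``[1e-8, 10]``.
    """
    norm = (counts.data / size_factors.reindex(counts.sample_ids)).to_numpy(dtype=float)
    groups = design.group_labels().reindex(counts.sample_ids)
    cells = [np.flatnonzero((groups == g).to_numpy()) for g in groups.unique()]
    if max(len(c) for c in cells) < 2:
        raise ValidationError(
            "dispersion is unidentifiable: no design cell has >= 2 replicates"
        )
    num = np.zeros(counts.n_genes)
    den = np.zeros(counts.n_genes)
    for cell in cells:
        if len(cell) < 2:
            continue
        sub = norm[:, cell]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(cell) - 1
        num += w * (v - m)
        den += w * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    clamped = np.clip(raw, DISPERSION_MIN, DISPERSION_MAX)

    # log-linear trend in the gene-wise mean, fitted on informative genes
    base_mean = norm.mean(axis=1)
    ok = (raw > 10 * DISPERSION_MIN) & (base_mean > 0)
    if ok.sum() >= 10:
        x = np.log(base_mean[ok])
        y = np.log(clamped[ok])
        slope, intercept = np.polyfit(x, y, 1)
        with np.errstate(divide="ignore"):
            log_trend = np.where(base_mean > 0, slope * np.log(np.maximum(base_mean, 1e-300)) + intercept, np.log(DISPERSION_MIN))
    else:
        log_trend = np.full(counts.n_genes, np.log(np.median(clamped)))
    log_trend = np.clip(log_trend, np.log(DISPERSION_MIN), np.log(DISPERSION_MAX))
    shrunk = np.exp(0.5 * np.log(clamped) + 0.5 * log_trend)
    shrunk = np.clip(shrunk, DISPERSION_MIN, DISPERSION_MAX)
    return pd.Series(shrunk, index=counts.gene_ids, name="dispersion")


# ---------------------------------------------------------------------------
# NB GLM (vectorised IRLS)
# ---------------------------------------------------------------------------

def nb_glm_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    tol: float = _IRLS_TOL,
    maxiter: int = _IRLS_MAXITER,
):
    """Fit gene-wise NB log-link GLMs by Fisher-scoring IRLS, all genes at once.

    Parameters
    ----------
    y : (G, n) counts
    X : (n, p) design matrix, shared across genes
    offset : (n,) log size factors
    alpha : (G,) dispersions

    Returns
    -------
    beta : (G, p) coefficients (natural-log scale)
    se : (G, p) Wald standard errors from the Fisher information ``X'WX``
    converged : (G,) bool
    """
    G, n = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("design matrix is singular (collinear columns)")
    alpha = np.asarray(alpha, dtype=float)[:, None]  # (G,1)

    mu = np.maximum(y + 0.5, 0.5)
    eta = np.log(mu)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    for _ in range(maxiter):
        W = mu / (1.0 + alpha * mu)  # (G, n) Fisher weights for log link
        z = (eta - offset) + (y - mu) / mu
        A = np.einsum("nj,gn,nk->gjk", X, W, X)
        b = np.einsum("nj,gn,gn->gj", X, W, z)
        try:
            new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # regularise near-singular per-gene systems minimally
            A = A + 1e-10 * np.eye(p)[None, :, :]
            new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        step = np.abs(new_beta - beta).max(axis=1)
        converged = step < tol * (1.0 + np.abs(new_beta).max(axis=1))
        beta = new_beta
        eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        if converged.all():
            break
    W = mu / (1.0 + alpha * mu)
    A = np.einsum("nj,gn,nk->gjk", X, W, X)
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se, converged


# ---------------------------------------------------------------------------
# contrast testing
# ---------------------------------------------------------------------------

def fit_contrast(
    counts: CountMatrix,
    design: SampleDesign,
    spec: ContrastSpec,
    dispersions: pd.Series,
    size_factors: pd.Series,
    base_mean_min: float = 0.0,
) -> pd.DataFrame:
    """Wald test for one two-level contrast.

    Per gene a negative-binomial log-link GLM is fitted on the samples in
    the contrast (after stratum filtering), with ``log(size factor)``
    offsets and optional per-sample covariates. ``log2fc`` is the
    numerator-vs-denominator coefficient divided by ``ln 2``; the Wald
    statistic is the coefficient over its standard error, referred to a
    standard normal. Genes failing the tested filter (``base_mean`` at or
    below ``base_mean_min`` computed over *all* samples, or lacking a
    nonzero count on either contrast side, or non-convergent) carry missing
    statistics and are excluded from the BH family.
    """
    table = design.with_group_column()
    table = table.reindex(counts.sample_ids)
    mask = pd.Series(True, index=table.index)
    for factor, level in spec.stratum.items():
        if factor not in table.columns:
            raise ValidationError(f"stratum factor {factor!r} not in design")
        mask &= table[factor] == level
    if spec.factor not in table.columns:
        raise ValidationError(f"contrast factor {spec.factor!r} not in design")
    levels = table[spec.factor]
    for lev in (spec.numerator, spec.denominator):
        if not ((levels == lev) & mask).any():
            raise ValidationError(
                f"contrast level {lev!r} of factor {spec.factor!r} has no samples "
                f"after stratum filtering"
            )
    keep = mask & levels.isin([spec.numerator, spec.denominator])
    samples = table.index[keep]

    sf_all = size_factors.reindex(counts.sample_ids)
    base_mean = (counts.data / sf_all).mean(axis=1) if counts.scale == "raw" else counts.data.mean(axis=1)

    y = counts.data.loc[:, samples].to_numpy(dtype=float)
    sf = sf_all.loc[samples].to_numpy(dtype=float)
    indicator = (levels.loc[samples] == spec.numerator).to_numpy(dtype=float)

    cols = [np.ones(len(samples)), indicator]
    names = ["intercept", "condition"]
    for cov in spec.covariates:
        if design.covariates is None or cov not in design.covariates.columns:
            raise ValidationError(f"covariate {cov!r} not present in design")
        cols.append(design.covariates.loc[samples, cov].to_numpy(dtype=float))
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"singular design: collinear columns among {names}")

    num_side = indicator == 1
    has_signal = (y[:, num_side].sum(axis=1) > 0) & (y[:, ~num_side].sum(axis=1) > 0)
    tested = (base_mean.to_numpy() > max(base_mean_min, 0.0)) & has_signal

    result = empty_contrast_result(counts.gene_ids)
    result["base_mean"] = base_mean.to_numpy()
    if tested.any():
        alpha = dispersions.reindex(counts.gene_ids).to_numpy(dtype=float)[tested]
        beta, se, converged = nb_glm_fit(y[tested], X, np.log(sf), alpha)
        coef = beta[:, 1]
        coef_se = se[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(coef_se > 0, coef / coef_se, 0.0)
        pval = 2.0 * stats.norm.sf(np.abs(stat))
        ok = converged & (coef_se > 0)
        idx = np.flatnonzero(tested)[ok]
        result.iloc[idx, result.columns.get_loc("log2fc")] = coef[ok] / np.log(2.0)
        result.iloc[idx, result.columns.get_loc("lfc_se")] = coef_se[ok] / np.log(2.0)
        result.iloc[idx, result.columns.get_loc("stat")] = stat[ok]
        result.iloc[idx, result.columns.get_loc("pvalue")] = pval[ok]
        result.iloc[idx, result.columns.get_loc("tested")] = True
    result["padj"] = adjust_bh(result["pvalue"])
    return result


def adjust_bh(pvalues) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing entries pass through.

    ``padj`` at rank ``k`` (ascending) is ``min(1, min_{j >= k} p_(j) * m / j)``
    over the ``m`` non-missing entries, computed by sorting once and taking
    a reverse cumulative minimum.
    """
    arr = np.asarray(pvalues, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if ((arr[mask] < 0) | (arr[mask] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if mask.any():
        p = arr[mask]
        m = p.size
        order = np.argsort(p, kind="stable")
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
        restored = np.empty(m)
        restored[order] = adj
        out[mask] = restored
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index, name="padj")
    return out


# ---------------------------------------------------------------------------
# comparative CT
# ---------------------------------------------------------------------------

def ddct_fold_change(table: DdctTable, control_group: str) -> pd.Series:
    """Comparative-CT fold changes relative to a control group.

    ``dCT_i = CT_target_i - CT_reference_i``; ``ddCT_i = dCT_i - mean(dCT)``
    over the control group; fold change ``2**(-ddCT_i)``. The arithmetic mean
    of the control-group dCT is used, so the mean log2 fold change within the
    control group is exactly zero.
    """
    df = table.table
    in_control = df["group"] == control_group
    if not in_control.any():
        raise ValidationError(f"control group {control_group!r} has no samples")
    dct = df["ct_target"].astype(float) - df["ct_reference"].astype(float)
    ddct = dct - dct[in_control].mean()
    fc = np.power(2.0, -ddct)
    return pd.Series(fc.to_numpy(), index=df["sample_id"], name="fold_change")
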