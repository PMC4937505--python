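"""RNA-seq quantification and differential expression.

Expression is quantified as RPKM; differential expression uses
precision-weighted linear models: log-CPM with mean-variance trend weights
(the voom construction), gene-wise weighted least squares, and empirical
Bayes moderation of the residual variances toward a pooled prior before
computing moderated t-statistics.  Multiple testing is controlled with
Benjamini-Hochberg.  Sample structure is summarized by Ward clustering on a
variance-stabilized matrix restricted to the most variable genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``library_sizes`` defaults to the column sums of ``counts``.
    """
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = library_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


# ---------------------------------------------------------------------------
# Precision weights (voom construction)
# ---------------------------------------------------------------------------

@dataclass
class WeightedExpression:
    """log2-CPM matrix with per-observation precision weights."""

    logexpr: pd.DataFrame  # genes x samples
    weights: np.ndarray  # same shape
    library_sizes: pd.Series


def effective_library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Composition-corrected library sizes (median-of-ratios scaling).

    Per sample, the median ratio of its counts to the gene-wise geometric
    mean (over genes expressed everywhere) gives a size factor robust to a
    minority of strongly regulated genes; raw library sizes are rescaled so
    their total is preserved.  This is the standard guard against
    compositional bias when many genes move in one direction.
    """
    pos = counts.loc[(counts > 0).all(axis=1)]
    if pos.empty:
        return counts.sum(axis=0).astype(float)
    logs = np.log(pos.to_numpy(dtype=float))
    geomean = logs.mean(axis=1)
    sf = np.exp(np.median(logs - geomean[:, None], axis=0))
    lib = counts.sum(axis=0).astype(float)
    eff = sf / sf.mean() * lib.mean()
    return pd.Series(eff, index=counts.columns)


def precision_weights(
    counts: pd.DataFrame,
    design: np.ndarray,
    span: float = 0.5,
    weight_bounds: tuple[float, float] = (1e-6, 1e6),
    normalize: str = "median_ratio",
) -> WeightedExpression:
    """Estimate per-observation precision weights from the mean-variance trend.

    Genes with zero counts in every sample are excluded first.  Counts are
    converted to log2 counts-per-million with a 0.5 offset; an unweighted
    linear-model fit provides gene-wise residual standard deviations, whose
    square roots are smoothed against average log2 count by lowess.  Each
    observation's weight is the inverse predicted variance (trend value to
    the fourth power, inverted) at its fitted count scale, clipped to
    ``weight_bounds``.

    ``normalize='median_ratio'`` (default) uses composition-corrected
    effective library sizes for the CPM scaling; ``'none'`` uses raw column
    sums.
    """
    counts = counts.loc[counts.sum(axis=1) > 0]
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    if n != counts.shape[1]:
        raise ValueError("design rows must match sample count")
    if n - p < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    if normalize == "median_ratio":
        lib = effective_library_sizes(counts)
    elif normalize == "none":
        lib = counts.sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown normalization: {normalize!r}")
    y = np.log2((counts.to_numpy(dtype=float) + 0.5) / (lib.to_numpy() + 1.0)[None, :] * 1e6)
    pinv = np.linalg.pinv(design)
    beta = y @ pinv.T  # genes x p
    fitted = beta @ design.T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
    # mean-variance trend: sqrt(sd) vs average log2 count
    mean_logcount = y.mean(axis=1) + np.mean(np.log2(lib.to_numpy() + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(sigma)
    sm = lowess(sqrt_sd, mean_logcount, frac=span, it=3, return_sorted=True)
    xs, ys = sm[:, 0], np.maximum(sm[:, 1], 1e-4)  # floor against a zero trend
    # fitted log2-count per observation
    fitted_count = fitted + (np.log2(lib.to_numpy() + 1.0) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_count, xs, ys)
    w = np.clip(pred_sqrt_sd**-4.0, *weight_bounds)
    return WeightedExpression(
        pd.DataFrame(y, index=counts.index, columns=counts.columns), w, lib
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated statistics
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed gene variances.

    Returns (d0, s02): prior degrees of freedom and prior variance such that
    s2 ~ s02 * F(df, d0).  d0 = inf when gene variances are underdispersed
    relative to pure chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def moderated_fit(
    we: WeightedExpression,
    design: np.ndarray,
    contrast: np.ndarray,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Gene-wise weighted least squares with moderated t-statistics.

    Per gene: WLS fit of log-expression on ``design`` with the voom weights;
    the contrast estimate b = contrast' beta and its unscaled variance
    u = contrast' (X'WX)^-1 contrast.  Residual variances s2 (df = n - p) are
    shrunk toward the fitted prior, s2_post = (d0 s0^2 + df s2)/(d0 + df),
    and t = b / sqrt(s2_post u) is referred to a t distribution with
    d0 + df degrees of freedom.  ``d0_override`` forces the prior df (0
    recovers the ordinary t; inf the pooled-variance limit).

    Returns a DataFrame with log2 fold change, moderated t, p and BH-adjusted
    p per gene.
    """
    design = np.asarray(design, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    n, p = design.shape
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("design matrix is rank deficient")
    if contrast.shape != (p,):
        raise ValueError("contrast length must match design columns")
    df_resid = n - p
    y = we.logexpr.to_numpy(dtype=float)
    W = we.weights
    G = y.shape[0]
    b = np.empty(G)
    u = np.empty(G)
    s2 = np.empty(G)
    for g in range(G):
        w = W[g]
        sw = np.sqrt(w)
        Xw = design * sw[:, None]
        yw = y[g] * sw
        XtX = Xw.T @ Xw
        XtXi = np.linalg.inv(XtX)
        beta = XtXi @ (Xw.T @ yw)
        resid = yw - Xw @ beta
        b[g] = contrast @ beta
        u[g] = contrast @ XtXi @ contrast
        s2[g] = (resid**2).sum() / df_resid
    if d0_override is not None:
        d0 = d0_override
        _, s02 = fit_f_dist(s2, df_resid)
    else:
        d0, s02 = fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    t = b / np.sqrt(s2_post * u)
    if np.isinf(df_total):
        pvals = 2 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "gene": we.logexpr.index,
            "log2_fc": b,
            "t": t,
            "p": pvals,
            "adj_p": bh_adjust(pvals),
        }
    ).set_index("gene")
    out.attrs["d0"] = d0
    out.attrs["s02"] = s02
    out.attrs["df_resid"] = df_resid
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significant_genes(
    de: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 2.0
) -> pd.DataFrame:
    """Genes with adjusted p strictly below ``p_cut`` and linear-scale fold
    change strictly above ``fc_cut`` (|log2FC| > log2(fc_cut)).

    Returns the surviving rows with a ``direction`` column; counts per
    direction are in ``.attrs['n_up']`` / ``.attrs['n_down']``.
    """
    keep = (de["adj_p"] < p_cut) & (de["log2_fc"].abs() > np.log2(fc_cut))
    out = de.loc[keep].copy()
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    out.attrs["n_up"] = int((out["direction"] == "up").sum())
    out.attrs["n_down"] = int((out["direction"] == "down").sum())
    return out


# ---------------------------------------------------------------------------
# Sample clustering
# ---------------------------------------------------------------------------

def variance_stabilize(counts: pd.DataFrame, method: str = "log", pseudo: float = 1.0) -> pd.DataFrame:
    """Variance-stabilizing transform of a count matrix.

    ``log``: log2(count + pseudo) on library-size-scaled counts (default);
    ``anscombe``: 2*sqrt(count + 3/8), a closed-form Poisson VST.
    """
    if method == "log":
        lib = counts.sum(axis=0).astype(float)
        scaled = counts / (lib / lib.mean())
        return np.log2(scaled + pseudo)
    if method == "anscombe":
        return 2.0 * np.sqrt(counts + 3.0 / 8.0)
    raise ValueError(f"unknown VST method: {method!r}")


def sample_cluster(
    counts: pd.DataFrame, top_n: int = 500, vst: str = "log"
) -> tuple[np.ndarray, list[str], str]:
    """Ward clustering of samples on the most variable genes.

    Applies the VST, selects the ``top_n`` genes by variance and runs Ward
    linkage on Euclidean sample distances.  Returns (linkage matrix, sample
    order, newick string).
    """
    if counts.shape[1] < 3:
        raise ValueError("at least 3 samples required")
    vs = variance_stabilize(counts, vst)
    variances = vs.var(axis=1)
    if top_n > len(variances):
        warnings.warn("top_n exceeds gene count; using all genes")
        top_n = len(variances)
    top = variances.sort_values(ascending=False, kind="stable").index[:top_n]
    X = vs.loc[top].to_numpy(dtype=float).T
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    labels = list(counts.columns)
    return Z, labels, _to_newick(Z, labels)


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return walk(tree) + ";"
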