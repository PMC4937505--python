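"""Target-decoy confidence estimation.

A Fisher linear discriminant is trained on PSM score features with decoys as
the negative class; PSMs are then thresholded to a requested false discovery
rate (decoy-based estimate), and proteins are filtered at a stricter level
using each protein's best surviving peptide score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FEATURES = ["score", "delta_score", "abs_ppm_error", "missed_cleavages", "charge"]


@dataclass
class FDRResult:
    """Outcome of decoy-based FDR thresholding."""

    threshold: float
    n_targets_kept: int
    n_decoys_kept: int
    estimated_fdr: float
    level: float


def _feature_matrix(psms: pd.DataFrame, features: list[str]) -> np.ndarray:
    cols = {}
    for f in features:
        if f == "abs_ppm_error":
            cols[f] = psms["ppm_error"].abs()
        else:
            cols[f] = psms[f]
    return pd.DataFrame(cols).to_numpy(dtype=float)


def fit_discriminant(
    psms: pd.DataFrame,
    features: list[str] | None = None,
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Score PSMs with a Fisher linear discriminant (targets vs decoys).

    The projection direction is Sw^-1 (mu_target - mu_decoy) where Sw is the
    pooled within-class scatter; a singular Sw is ridge-regularized with a
    warning.  The sign is fixed so that targets score higher on average.
    Returns a copy of the table with a ``discriminant_score`` column.
    """
    features = features or DEFAULT_FEATURES
    decoy = psms["decoy"].to_numpy(dtype=bool)
    if decoy.all() or not decoy.any():
        raise ValueError("both target and decoy PSMs are required")
    X = _feature_matrix(psms, features)
    Xt, Xd = X[~decoy], X[decoy]
    mu_t, mu_d = Xt.mean(axis=0), Xd.mean(axis=0)
    Sw = np.cov(Xt, rowvar=False) * (len(Xt) - 1) + np.cov(Xd, rowvar=False) * (
        len(Xd) - 1
    )
    Sw = np.atleast_2d(Sw)
    try:
        w = np.linalg.solve(Sw, mu_t - mu_d)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; ridge-regularizing")
        w = np.linalg.solve(Sw + ridge * np.trace(Sw) * np.eye(len(Sw)), mu_t - mu_d)
    scores = X @ w
    if scores[~decoy].mean() < scores[decoy].mean():  # orientation convention
        scores = -scores
    out = psms.copy()
    out["discriminant_score"] = scores
    return out


def _decoy_threshold(
    scores: np.ndarray, decoy: np.ndarray, level: float
) -> tuple[float, int, int, float]:
    """Most permissive score threshold with decoys/targets <= level.

    Scans unique scores in descending order; ties at the threshold are kept.
    Returns (threshold, n_targets, n_decoys, fdr_at_threshold); threshold is
    +inf when no cut attains the level.
    """
    order = np.argsort(-scores, kind="stable")
    s, d = scores[order], decoy[order]
    n_dec = np.cumsum(d)
    n_tar = np.cumsum(~d)
    # only evaluate at the last index of each tied score block
    last_of_block = np.r_[s[1:] != s[:-1], True]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_tar > 0, n_dec / np.maximum(n_tar, 1), np.where(n_dec > 0, np.inf, 0.0))
    ok = last_of_block & (fdr <= level)
    if not ok.any():
        return np.inf, 0, 0, np.nan
    k = np.flatnonzero(ok)[-1]
    return float(s[k]), int(n_tar[k]), int(n_dec[k]), float(fdr[k])


def threshold_at_fdr(
    scored: pd.DataFrame, level: float = 0.05, score_col: str = "discriminant_score"
) -> tuple[FDRResult, pd.DataFrame]:
    """Threshold scored PSMs at a decoy-estimated FDR level.

    The estimator is decoys_kept / targets_kept (concatenated target-decoy
    convention).  Survivors are the target PSMs at or above the most
    permissive threshold whose estimate does not exceed ``level``; decoys are
    excluded from the survivor set.
    """
    if not 0 < level < 1 and level != 1.0:
        raise ValueError("level must be in (0, 1]")
    scores = scored[score_col].to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    decoy = scored["decoy"].to_numpy(dtype=bool)
    thr, n_t, n_d, fdr = _decoy_threshold(scores, decoy, level)
    if not np.isfinite(thr):
        warnings.warn("no threshold attains the requested FDR level")
        survivors = scored.iloc[0:0].copy()
        return FDRResult(np.inf, 0, 0, np.nan, level), survivors
    survivors = scored.loc[(scores >= thr) & ~decoy].copy()
    return FDRResult(thr, n_t, n_d, fdr, level), survivors


def protein_level_fdr(
    scored: pd.DataFrame,
    level: float = 0.02,
    score_col: str = "discriminant_score",
) -> tuple[FDRResult, pd.DataFrame]:
    """Protein-level filtering by best-peptide score.

    Each accession is scored by its best PSM/peptide score; accessions whose
    best evidence is a decoy peptide form the decoy protein population.  The
    same decoy-counting threshold rule is then applied at protein
    granularity.  Returns the FDR summary and the surviving target-protein
    table (accession, best score).
    """
    rows = []
    for _, r in scored.iterrows():
        for acc in str(r["proteins"]).split(";"):
            rows.append((acc, float(r[score_col]), bool(r["decoy"])))
    long = pd.DataFrame(rows, columns=["accession", score_col, "decoy"])
    best = (
        long.sort_values([score_col, "accession"], ascending=[False, True])
        .groupby("accession", sort=True)
        .first()
        .reset_index()
    )
    res, survivors = threshold_at_fdr(best, level=level, score_col=score_col)
    return res, survivors


def peptide_level_fdr_estimate(scored: pd.DataFrame, score_col: str = "discriminant_score",
                               threshold: float = -np.inf) -> float:
    """Decoy-based FDR estimate at unique-peptide granularity.

    Collapses PSMs above ``threshold`` to unique peptides (best score per
    peptide) and reports decoys/targets — the post-hoc peptide-level estimate
    companion to the PSM-level control.
    """
    kept = scored.loc[scored[score_col] >= threshold]
    best = kept.sort_values(score_col, ascending=False).groupby("peptide").first()
    n_dec = int(best["decoy"].sum())
    n_tar = int((~best["decoy"].astype(bool)).sum())
    return n_dec / n_tar if n_tar else np.nan
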