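"""Trajectory standardization, fuzzy c-means clustering and layer overlay.

Trajectories (one row per peptide/protein/transcript, one column per time
point) are z-scored row-wise so each feature has mean 0 and SD 1 across the
time course, then clustered with fuzzy c-means (Bezdek alternating
optimization, Euclidean distance, fuzzifier m = 1.5 by default).  Cluster
counts follow the study layers: 5 for cleavage peptides (CSP), 6 for global
protein profiles (GPP), 9 for transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class FuzzyClustering:
    """Result of one fuzzy c-means run (best of ``n_starts``)."""

    c: int
    m: float
    centers: np.ndarray  # c x T
    membership: np.ndarray  # n x c, rows sum to 1
    objective: float
    objective_history: list[float]
    n_iter: int
    seed: int | None


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores: each trajectory gets mean 0 and SD 1.

    Rows with zero variance cannot be standardized and are dropped with a
    warning.  Idempotent on already-standardized input.
    """
    vals = X.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} constant trajectories")
    vals = vals[keep]
    out = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(out, index=X.index[keep], columns=X.columns)


def _fcm_once(
    X: np.ndarray, c: int, m: float, rng: np.random.Generator,
    tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float], int]:
    n = X.shape[0]
    U = rng.dirichlet(np.ones(c), size=n)
    history: list[float] = []
    J = np.inf
    exponent = -1.0 / (m - 1.0)
    for it in range(1, max_iter + 1):
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = cdist(X, centers, "sqeuclidean")
        J_new = float((Um * d2).sum())
        history.append(J_new)
        # membership update; points coinciding with a center take the
        # limit convention: full membership in (the first) zero-distance
        # cluster.
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2**exponent
            U = inv / inv.sum(axis=1, keepdims=True)
        zrows = zero.any(axis=1)
        if zrows.any():
            U[zrows] = 0.0
            first = np.argmax(zero[zrows], axis=1)
            U[np.flatnonzero(zrows), first] = 1.0
        if np.isfinite(J) and abs(J - J_new) < tol:
            J = J_new
            break
        J = J_new
    return centers, U, J, history, len(history)


def fuzzy_cmeans(
    X: pd.DataFrame | np.ndarray,
    c: int,
    m: float = 1.5,
    seed: int | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
    n_starts: int = 10,
) -> FuzzyClustering:
    """Fuzzy c-means with multi-start best-objective selection.

    Alternates the Bezdek updates — centers v_i = sum_j u_ij^m x_j /
    sum_j u_ij^m and memberships u_ij = 1 / sum_k (d_ij/d_kj)^(2/(m-1)) with
    Euclidean d — until the objective J = sum_ij u_ij^m d_ij^2 changes by
    less than ``tol`` or ``max_iter`` is reached.  Initialization is a random
    membership matrix per start; the run with the lowest final J wins.
    """
    vals = np.asarray(X, dtype=float)
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if vals.shape[0] < c:
        raise ValueError("need at least c rows")
    ss = np.random.SeedSequence(seed)
    best: FuzzyClustering | None = None
    for child in ss.spawn(n_starts):
        rng = np.random.default_rng(child)
        centers, U, J, history, n_iter = _fcm_once(vals, c, m, rng, tol, max_iter)
        if best is None or J < best.objective:
            best = FuzzyClustering(c, m, centers, U, J, history, n_iter, seed)
    assert best is not None
    return best


def assign_clusters(U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels from a membership matrix.

    Argmax per row; ties break to the lowest cluster index.  Returns
    (labels, max-membership values).
    """
    U = np.asarray(U, dtype=float)
    labels = U.argmax(axis=1)
    return labels, U[np.arange(len(U)), labels]


def cluster_report(
    features: pd.Index | list[str], layer: str, result: FuzzyClustering
) -> pd.DataFrame:
    labels, memb = assign_clusters(result.membership)
    return pd.DataFrame(
        {
            "feature": list(features),
            "layer": layer,
            "cluster": labels + 1,  # 1-based cluster ids in reports
            "max_membership": memb,
        }
    )


def cluster_trends(result: FuzzyClustering) -> np.ndarray:
    """Pearson r of each cluster center against time-point rank.

    Used to designate down-regulated protein clusters (negative trend) for
    the overlay restriction.
    """
    T = result.centers.shape[1]
    rank = np.arange(T, dtype=float)
    rank = (rank - rank.mean()) / rank.std()
    z = (result.centers - result.centers.mean(axis=1, keepdims=True))
    sd = z.std(axis=1)
    out = np.zeros(len(z))
    nz = sd > 0
    out[nz] = (z[nz] * rank).mean(axis=1) / sd[nz]
    return out


def overlay(
    csp: pd.DataFrame,
    gpp: pd.DataFrame,
    rna: pd.DataFrame,
    csp_labels: pd.Series,
    gpp_labels: pd.Series,
    id_map: pd.DataFrame,
    restrict_gpp_clusters: list[int] | None = None,
) -> pd.DataFrame:
    """Join the three standardized trajectory layers per cleavage feature.

    ``csp``/``gpp``/``rna`` are standardized trajectory matrices indexed by
    peptide, protein accession and gene id respectively; ``id_map`` has
    columns peptide, accession, gene resolving each CSP feature to at most
    one protein and gene.  When ``restrict_gpp_clusters`` is given, triads
    whose protein is not in one of the designated (down-regulated) GPP
    clusters are excluded; features with missing protein or transcript layers
    are retained with NaN layers and counted in the ``complete`` flag.

    Returns a long table: one row per (peptide, time point) with cleavage,
    protein and transcript values plus cluster annotations.
    """
    time_cols = list(csp.columns)
    rows = []
    for _, link in id_map.iterrows():
        pep, acc, gene = link["peptide"], link["accession"], link["gene"]
        if pep not in csp.index:
            continue
        c_traj = csp.loc[pep]
        p_traj = gpp.loc[acc] if acc in gpp.index else None
        g_traj = rna.loc[gene] if gene in rna.index else None
        gpp_cluster = int(gpp_labels.loc[acc]) if acc in gpp_labels.index else None
        if restrict_gpp_clusters is not None:
            if gpp_cluster is None or gpp_cluster not in restrict_gpp_clusters:
                continue
        for j, t in enumerate(time_cols):
            rows.append(
                {
                    "peptide": pep,
                    "accession": acc,
                    "gene": gene,
                    "csp_cluster": int(csp_labels.loc[pep]),
                    "gpp_cluster": gpp_cluster,
                    "time": t,
                    "cleavage": float(c_traj.iloc[j]),
                    "protein": float(p_traj.iloc[j]) if p_traj is not None else np.nan,
                    "transcript": float(g_traj.iloc[j]) if g_traj is not None else np.nan,
                    "complete": p_traj is not None and g_traj is not None,
                }
            )
    return pd.DataFrame(rows)
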