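"""Regulatory-mode classification from cleavage/protein/transcript triads.

For each caspase-substrate gene the three standardized 6-point trajectories
are compared: pairwise Pearson correlations plus a per-layer monotone trend
(Pearson r of the trajectory against time-point rank).  A small decision
table then assigns one of four regulatory modes, mirroring the exemplar
patterns MAGED2 (transcript up, protein down, cleaved: caspase-mediated
degradation), SQSTM1 (transcript and protein up together), MAP3K7 (protein
down with flat transcript: direct caspase effect) and UHRF1 (transcript and
protein down together: transcription-coupled loss); anything else is
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MODES = (
    "caspase_degradation",
    "co_upregulated",
    "direct_caspase",
    "transcription_coupled",
    "ambiguous",
)


@dataclass
class TriadProfile:
    """One gene's three-layer kinetic profile (standardized trajectories)."""

    gene: str
    cleavage: np.ndarray | None
    protein: np.ndarray | None
    transcript: np.ndarray | None


@dataclass
class RegulatoryCall:
    gene: str
    mode: str
    r_pt: float  # protein vs transcript
    r_pc: float  # protein vs cleavage
    r_tc: float  # transcript vs cleavage
    trend_transcript: float
    trend_protein: float
    trend_cleavage: float


def _pearson(a: np.ndarray | None, b: np.ndarray | None) -> float:
    """Pearson r, NaN-flagged when a layer is missing or degenerate."""
    if a is None or b is None:
        return np.nan
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def trend(traj: np.ndarray | None) -> float:
    """Monotone-trend statistic: Pearson r of trajectory vs time-point rank.

    Rank rather than raw hours is used because sampling is strongly
    non-uniform (0-72 h).  A constant (or missing) trajectory has no trend
    and returns 0.
    """
    if traj is None:
        return 0.0
    traj = np.asarray(traj, dtype=float)
    if traj.std() == 0:
        return 0.0
    return _pearson(traj, np.arange(len(traj), dtype=float))


def correlate_layers(triad: TriadProfile) -> dict[str, float]:
    """Pairwise Pearson correlations among the three layers.

    Missing layers yield NaN for the correlations involving them.
    """
    return {
        "r_pt": _pearson(triad.protein, triad.transcript),
        "r_pc": _pearson(triad.protein, triad.cleavage),
        "r_tc": _pearson(triad.transcript, triad.cleavage),
    }


def classify_mode(
    triad: TriadProfile, trend_cut: float = 0.5, r_cut: float = 0.5
) -> RegulatoryCall:
    """Assign a regulatory mode from per-layer trends.

    Trend calls: up if r > trend_cut, down if r < -trend_cut, flat
    otherwise.  Decision table, first match wins:

    ==================  ============  ===========  ======================
    transcript          protein       cleavage     mode
    ==================  ============  ===========  ======================
    up                  down          up           caspase_degradation
    up                  up            (any)        co_upregulated
    flat                down          (any)        direct_caspase
    down                down          (any)        transcription_coupled
    (otherwise)                                    ambiguous
    ==================  ============  ===========  ======================
    """
    t_t = trend(triad.transcript)
    t_p = trend(triad.protein)
    t_c = trend(triad.cleavage)

    def call(x: float) -> str:
        if x > trend_cut:
            return "up"
        if x < -trend_cut:
            return "down"
        return "flat"

    ct, cp, cc = call(t_t), call(t_p), call(t_c)
    if ct == "up" and cp == "down" and cc == "up":
        mode = "caspase_degradation"
    elif ct == "up" and cp == "up":
        mode = "co_upregulated"
    elif ct == "flat" and cp == "down":
        mode = "direct_caspase"
    elif ct == "down" and cp == "down":
        mode = "transcription_coupled"
    else:
        mode = "ambiguous"
    corr = correlate_layers(triad)
    return RegulatoryCall(triad.gene, mode, corr["r_pt"], corr["r_pc"],
                          corr["r_tc"], t_t, t_p, t_c)


def classify_table(
    triads: list[TriadProfile], trend_cut: float = 0.5, r_cut: float = 0.5
) -> pd.DataFrame:
    calls = [classify_mode(t, trend_cut, r_cut) for t in triads]
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "mode": [c.mode for c in calls],
            "r_pt": [c.r_pt for c in calls],
            "r_pc": [c.r_pc for c in calls],
            "r_tc": [c.r_tc for c in calls],
            "trend_transcript": [c.trend_transcript for c in calls],
            "trend_protein": [c.trend_protein for c in calls],
            "trend_cleavage": [c.trend_cleavage for c in calls],
        }
    )


def triads_from_overlay(overlay: pd.DataFrame) -> list[TriadProfile]:
    """Build per-gene triads from the long overlay table."""
    out = []
    for (pep, acc, gene), grp in overlay.groupby(["peptide", "accession", "gene"], sort=True):
        grp = grp.sort_index()
        prot = grp["protein"].to_numpy()
        trans = grp["transcript"].to_numpy()
        out.append(
            TriadProfile(
                gene=str(gene),
                cleavage=grp["cleavage"].to_numpy(),
                protein=None if np.isnan(prot).any() else prot,
                transcript=None if np.isnan(trans).any() else trans,
            )
        )
    return out


def substrate_regression(
    protein: pd.DataFrame, transcript: pd.DataFrame
) -> dict[str, float]:
    """Pooled protein-vs-transcript correlation across substrates and times.

    Both layers must be standardized trajectory matrices sharing an index
    (genes) and column count (time points).  All gene x time observations
    are pooled; returns Pearson r with its p-value and the least-squares
    slope/intercept of protein on transcript.
    """
    common = protein.index.intersection(transcript.index)
    x = transcript.loc[common].to_numpy(dtype=float).ravel()
    y = protein.loc[common].to_numpy(dtype=float).ravel()
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("at least 3 paired observations required")
    fit = stats.linregress(x, y)
    return {
        "r": float(fit.rvalue),
        "p": float(fit.pvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(x.size),
    }
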