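"""TMT6plex reporter-ion quantification and peptide/protein rollup.

Reporter extraction takes, per channel, the highest peak intensity within a
20 ppm window around the theoretical reporter m/z.  PSMs whose six reporter
intensities sum to 2000 or less are discarded.  Peptide-level quantification
sums PSM-level intensities per channel and is carried downstream as relative
abundance to the maximal channel; protein-level quantification is the
unweighted mean of the peptide relative-abundance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics.mass import nist_mass

from .design import DEFAULT_DESIGN, StudyDesign

__all__ = [
    "TMT6_REPORTER_MZ",
    "ReporterSpectrum",
    "extract_reporters",
    "attach_reporters",
    "combined_intensity",
    "filter_min_intensity",
    "rollup_peptides",
    "rollup_proteins",
]

# ---------------------------------------------------------------------------
# Theoretical TMT6plex reporter ion m/z, computed from NIST isotope masses.
# The reporter cation is C8H16N+ (mass of the neutral composition minus one
# electron); heavier channels substitute 13C and/or 15N: the 126/127 pair
# differs by one 15N, 128/129 add two 13C, 130/131 add four 13C.
# ---------------------------------------------------------------------------
_C12 = nist_mass["C"][12][0]
_C13 = nist_mass["C"][13][0]
_H1 = nist_mass["H"][1][0]
_N14 = nist_mass["N"][14][0]
_N15 = nist_mass["N"][15][0]
_ELECTRON = nist_mass["e*"][0][0]

_BASE = 8 * _C12 + 16 * _H1 + _N14 - _ELECTRON
_D13C = _C13 - _C12
_D15N = _N15 - _N14

TMT6_REPORTER_MZ: dict[str, float] = {
    "126": _BASE,
    "127": _BASE + _D15N,
    "128": _BASE + 2 * _D13C,
    "129": _BASE + 2 * _D13C + _D15N,
    "130": _BASE + 4 * _D13C,
    "131": _BASE + 4 * _D13C + _D15N,
}


@dataclass
class ReporterSpectrum:
    """Reporter-region peak list of one MS2/MS3 spectrum."""

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size and (self.mz <= 0).any():
            raise ValueError("m/z values must be positive")
        if self.intensity.size and (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")


def extract_reporters(
    spectrum: ReporterSpectrum,
    theoretical_mz: dict[str, float] | None = None,
    tol_ppm: float = 20.0,
) -> np.ndarray:
    """Extract the six reporter intensities from one peak list.

    Per channel, the highest peak intensity among peaks within ``tol_ppm``
    parts per million of the theoretical reporter m/z (window computed on the
    theoretical mass).  Channels with no peak in window get 0; an empty peak
    list yields an all-zero vector.
    """
    if tol_ppm < 0:
        raise ValueError("tolerance must be non-negative")
    if theoretical_mz is None:
        theoretical_mz = TMT6_REPORTER_MZ
    out = np.zeros(len(theoretical_mz))
    if spectrum.mz.size == 0:
        return out
    for i, mz0 in enumerate(theoretical_mz.values()):
        window = np.abs(spectrum.mz - mz0) / mz0 * 1e6 <= tol_ppm
        if window.any():
            out[i] = spectrum.intensity[window].max()
    return out


def attach_reporters(
    psms: pd.DataFrame,
    spectra: dict[str, ReporterSpectrum],
    design: StudyDesign = DEFAULT_DESIGN,
    tol_ppm: float = 20.0,
) -> pd.DataFrame:
    """Fill the reporter_* columns of a PSM table from raw peak lists.

    PSM rows whose spectrum_id has no peak list get all-zero reporters.
    """
    cols = design.channel_columns()
    theo = {c: TMT6_REPORTER_MZ[c] for c in design.channels}
    out = psms.copy()
    rows = []
    for sid in out["spectrum_id"]:
        spec = spectra.get(sid)
        if spec is None:
            rows.append(np.zeros(len(cols)))
        else:
            rows.append(extract_reporters(spec, theo, tol_ppm))
    out[cols] = np.asarray(rows)
    return out


def combined_intensity(
    psms: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN
) -> pd.Series:
    """Sum of the six reporter intensities per PSM."""
    return psms[design.channel_columns()].sum(axis=1)


def filter_min_intensity(
    psms: pd.DataFrame,
    min_total: float = 2000.0,
    design: StudyDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Keep PSMs with combined reporter intensity strictly greater than
    ``min_total``.  Row order is preserved; the filter is idempotent."""
    keep = combined_intensity(psms, design) > min_total
    return psms.loc[keep].copy()


def rollup_peptides(
    psms: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    """Aggregate PSMs to peptide level.

    One row per (peptide, protein-set) key with channel-wise intensity sums
    and the relative abundance to the maximal channel.  Peptides whose summed
    channels are all zero get an all-zero relative abundance and are flagged
    in the ``all_zero`` column.
    """
    cols = design.channel_columns()
    grouped = (
        psms.groupby(["peptide", "proteins"], sort=True)[cols]
        .sum()
        .reset_index()
    )
    sums = grouped[cols].to_numpy(dtype=float)
    maxes = sums.max(axis=1)
    rel = np.zeros_like(sums)
    nz = maxes > 0
    rel[nz] = sums[nz] / maxes[nz, None]
    rel_cols = [f"rel_{c}" for c in design.channels]
    grouped[rel_cols] = rel
    grouped["n_psms"] = (
        psms.groupby(["peptide", "proteins"], sort=True)
        .size()
        .reset_index(drop=True)
    )
    grouped["all_zero"] = ~nz
    return grouped


def rollup_proteins(
    peptides: pd.DataFrame,
    design: StudyDesign = DEFAULT_DESIGN,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Aggregate peptide relative abundances to protein level.

    Per accession, the unweighted mean of the peptide relative-abundance
    vectors.  Peptides shared across accessions contribute to every matching
    accession unless ``unique_only`` is set, in which case shared peptides
    are dropped.
    """
    rel_cols = [f"rel_{c}" for c in design.channels]
    records = []
    for _, row in peptides.iterrows():
        accs = str(row["proteins"]).split(";")
        if unique_only and len(accs) > 1:
            continue
        for acc in accs:
            records.append((acc, *row[rel_cols].tolist()))
    long = pd.DataFrame(records, columns=["accession", *rel_cols])
    out = long.groupby("accession", sort=True).mean().reset_index()
    out["n_peptides"] = (
        long.groupby("accession", sort=True).size().reset_index(drop=True)
    )
    return out


def normalize_channels(
    psms: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    """Optional loading normalization: equalize channel column sums.

    Off by default in the pipeline; provided because whether the study
    normalized channel loadings is not stated.
    """
    cols = design.channel_columns()
    out = psms.copy()
    totals = out[cols].sum(axis=0).to_numpy(dtype=float)
    target = totals[totals > 0].mean() if (totals > 0).any() else 0.0
    factors = np.where(totals > 0, target / np.where(totals > 0, totals, 1), 1.0)
    out[cols] = out[cols].to_numpy(dtype=float) * factors
    return out
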