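"""Study design constants and kinetic archetype templates.

The experimental design being modelled: HeLa cells under tunicamycin-induced
ER stress sampled at 0, 4, 8, 24, 48 and 72 h, with each time point labelled
with one TMT6plex channel (reporter series 126-131).  The RNA-seq arm of the
design samples 0, 8, 24 and 72 h in a stress-only ("TM") and a
stress-plus-pan-caspase-inhibitor ("TMZ", z-VAD-FMK) condition with three
biological replicates per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: TMT6plex channel labels in reporter-mass order.
TMT6_CHANNELS: tuple[str, ...] = ("126", "127", "128", "129", "130", "131")


@dataclass(frozen=True)
class StudyDesign:
    """Time-course design shared by the proteomics and transcriptomics layers.

    Parameters
    ----------
    time_points_h:
        Proteomics sampling times in hours, strictly increasing.  One TMT
        channel per time point.
    channels:
        TMT6plex channel labels aligned to ``time_points_h``.
    rna_time_points_h:
        Sampling times of the inhibitor-contrast RNA-seq experiment.
    rna_replicates:
        Biological replicates per RNA-seq condition (>= 2).
    treatments:
        Treatment arm labels: stress-only first, stress+inhibitor second.
    """

    time_points_h: tuple[float, ...] = (0, 4, 8, 24, 48, 72)
    channels: tuple[str, ...] = TMT6_CHANNELS
    rna_time_points_h: tuple[float, ...] = (0, 8, 24, 72)
    rna_replicates: int = 3
    treatments: tuple[str, str] = ("TM", "TMZ")

    def __post_init__(self) -> None:
        if list(self.time_points_h) != sorted(set(self.time_points_h)):
            raise ValueError("time points must be strictly increasing")
        if len(self.channels) != 6:
            raise ValueError("TMT6plex design requires exactly 6 channels")
        if len(self.channels) != len(self.time_points_h):
            raise ValueError("one channel per time point required")
        if self.rna_replicates < 2:
            raise ValueError("at least 2 RNA replicates per condition")

    @property
    def n_time_points(self) -> int:
        return len(self.time_points_h)

    def channel_columns(self) -> list[str]:
        """Reporter-intensity column names used in PSM tables."""
        return [f"reporter_{c}" for c in self.channels]


DEFAULT_DESIGN = StudyDesign()

# ---------------------------------------------------------------------------
# Kinetic archetypes.
#
# Piecewise-linear 6-point templates on a relative-abundance scale.  The five
# cleavage (CSP) shapes mirror the observed substrate kinetics classes:
# cleaved early (before 24 h), accumulating after 24 h, accumulating by 72 h,
# and two bimodal populations with a trough at 48 h.  The six protein (GPP)
# shapes include the two down-regulated classes used for the overlay
# restriction.  Exact values are free generator parameters.
# ---------------------------------------------------------------------------

CSP_ARCHETYPES: dict[str, np.ndarray] = {
    "early": np.array([0.05, 0.55, 1.00, 0.90, 0.55, 0.75]),
    "post24": np.array([0.05, 0.05, 0.15, 0.80, 0.90, 1.00]),
    "post72": np.array([0.05, 0.05, 0.05, 0.10, 0.35, 1.00]),
    "bimodal_early": np.array([0.05, 0.90, 1.00, 0.35, 0.15, 0.85]),
    "bimodal_mid": np.array([0.05, 0.10, 0.55, 1.00, 0.30, 0.90]),
}

GPP_ARCHETYPES: dict[str, np.ndarray] = {
    "up_early": np.array([0.10, 0.60, 1.00, 0.95, 0.85, 0.90]),
    "up_late": np.array([0.10, 0.10, 0.20, 0.50, 0.80, 1.00]),
    "transient": np.array([0.20, 0.90, 1.00, 0.50, 0.25, 0.20]),
    "mid_wave": np.array([0.50, 0.40, 0.60, 1.00, 0.80, 0.45]),
    "down_early": np.array([1.00, 0.55, 0.30, 0.15, 0.10, 0.05]),
    "down_late": np.array([1.00, 0.95, 0.85, 0.60, 0.30, 0.10]),
}

#: GPP archetype names treated as "down-regulated" for the overlay restriction.
GPP_DOWN_ARCHETYPES: tuple[str, str] = ("down_early", "down_late")

RNA_ARCHETYPES: dict[str, np.ndarray] = {
    "up_fast": np.array([0.10, 0.70, 1.00, 0.95, 0.90, 0.90]),
    "up_mid": np.array([0.10, 0.20, 0.45, 1.00, 0.95, 0.90]),
    "up_late": np.array([0.10, 0.10, 0.15, 0.30, 0.60, 1.00]),
    "transient_early": np.array([0.20, 1.00, 0.80, 0.35, 0.25, 0.20]),
    "transient_mid": np.array([0.15, 0.30, 0.90, 1.00, 0.40, 0.20]),
    "flat_wave": np.array([0.55, 0.45, 0.60, 0.50, 0.65, 0.50]),
    "down_fast": np.array([1.00, 0.45, 0.25, 0.15, 0.10, 0.10]),
    "down_mid": np.array([1.00, 0.90, 0.70, 0.35, 0.20, 0.15]),
    "down_late": np.array([1.00, 0.95, 0.90, 0.80, 0.50, 0.15]),
}
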