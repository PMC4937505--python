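"""Run configuration: one schema-validated YAML document drives a run.

Unknown keys are rejected (pydantic ``extra='forbid'``); all randomness in
a run derives from the single root ``seed``.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticConfig(_Strict):
    n_proteins: int = 300
    length_range: tuple[int, int] = (60, 400)
    n_psms: int = 1200
    n_peptides: int = 300
    noise_sd: float = 0.2
    decoy_fraction: float = 0.3
    false_target_fraction: float = 0.05
    base_intensity: float = 2e5
    n_genes: int = 1500
    dispersion: float = 0.02
    n_tf_sets: int = 20
    tf_set_size: int = 30
    n_dual_tfs: int = 5
    target_up_fc: float = 4.0
    rna_time_amplitude: float = 0.8
    n_gpp_proteins: int = 600
    gpp_noise_sd: float = 0.3


class QuantifyConfig(_Strict):
    min_intensity: float = 2000.0
    tol_ppm: float = 20.0
    normalize_channels: bool = False
    unique_peptides_only: bool = False


class FdrConfig(_Strict):
    psm_level: float = 0.05
    protein_level: float = 0.02
    features: list[str] = Field(
        default_factory=lambda: ["score", "delta_score", "abs_ppm_error",
                                 "missed_cleavages", "charge"]
    )


class ClusteringConfig(_Strict):
    csp_c: int = 5
    gpp_c: int = 6
    rna_c: int = 9
    m: float = 1.5
    tol: float = 1e-9
    max_iter: int = 1000
    n_starts: int = 10
    restrict_overlay_to_down: bool = True


class ClassifyConfig(_Strict):
    trend_cut: float = 0.5
    r_cut: float = 0.5


class DeConfig(_Strict):
    p_cut: float = 0.05
    fc_cut: float = 2.0
    contrast_time_h: float = 72.0


class EnrichmentConfig(_Strict):
    rho: float = 0.01
    min_size: int = 5
    p_cut: float = 0.05
    fc_flat: float = 2.0
    highlight_p: float = 1e-4
    highlight_fc: float = 2.0


class SampleClusterConfig(_Strict):
    top_n: int = 500
    vst: str = "log"


class UserDataConfig(_Strict):
    psm_table: str | None = None
    fasta: str | None = None
    counts: str | None = None
    gene_lengths: str | None = None
    sample_table: str | None = None
    gene_sets_gmt: str | None = None
    tf_map: str | None = None
    known_sites: dict[str, str] = Field(default_factory=dict)


class RunConfig(_Strict):
    """Top-level configuration for a pipeline run."""

    seed: int = 0
    mode: str = "synthetic"  # synthetic | user-data
    outdir: str = "caspkit_run"
    synthetic: SyntheticConfig = SyntheticConfig()
    user_data: UserDataConfig = UserDataConfig()
    quantify: QuantifyConfig = QuantifyConfig()
    fdr: FdrConfig = FdrConfig()
    clustering: ClusteringConfig = ClusteringConfig()
    classify: ClassifyConfig = ClassifyConfig()
    de: DeConfig = DeConfig()
    enrichment: EnrichmentConfig = EnrichmentConfig()
    sample_cluster: SampleClusterConfig = SampleClusterConfig()

    @field_validator("mode")
    @classmethod
    def _mode_ok(cls, v: str) -> str:
        if v not in ("synthetic", "user-data"):
            raise ValueError("mode must be 'synthetic' or 'user-data'")
        return v

    def validate_inputs(self) -> None:
        """In user-data mode, required input paths must exist."""
        if self.mode != "user-data":
            return
        required = {
            "user_data.psm_table": self.user_data.psm_table,
            "user_data.fasta": self.user_data.fasta,
            "user_data.counts": self.user_data.counts,
            "user_data.gene_lengths": self.user_data.gene_lengths,
            "user_data.sample_table": self.user_data.sample_table,
        }
        for key, path in required.items():
            if path is None:
                raise FileNotFoundError(f"config key {key} is required in user-data mode")
            if not Path(path).exists():
                raise FileNotFoundError(f"config key {key}: file not found: {path}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=True)
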