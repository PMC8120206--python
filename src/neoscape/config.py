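"""Configuration objects for the synthetic cohort generator and the pipeline.

Both configs are pydantic models: unknown keys are rejected, every threshold
is range-checked, and a fixed seed makes every downstream step reproducible.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class SyntheticCohortConfig(BaseModel):
    """Parameters of the synthetic metastatic-cohort generator.

    Defaults emulate a 26-patient nasopharyngeal-carcinoma-like cohort with
    paired primary / regional-lymph-node / distant-metastasis samples:
    ~65 nonsilent mutations per sample, 57% of nonsilent mutations yielding
    at least one called neoantigen, and epitope yields of roughly 4.5 per
    missense and 9 per frameshift mutation.

    ``theta_cnv`` and ``theta_txn`` are the *true* odds multipliers with which
    neoantigenic mutations fall into copy-loss regions / remain expressed,
    i.e. the planted DNA-level and transcriptional depletion odds ratios.
    ``beta_reduction`` biases the drop-out odds of strong/medium-affinity or
    high-stability neoantigens in metastatic samples (0 = no bias).
    """

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(26, ge=1)
    # patient id -> list of site labels such as "PRIMARY:1", "LYMPH:1",
    # "DISTANT:1"; None selects the built-in 29/16/12 site layout.
    sites_per_patient: Optional[dict[str, list[str]]] = None

    n_mutations_mean: float = Field(100.0, gt=0)
    missense_fraction: float = Field(0.55, ge=0, le=1)
    frameshift_fraction: float = Field(0.04, ge=0, le=1)
    other_nonsilent_fraction: float = Field(0.06, ge=0, le=1)
    # silent fraction is the remainder

    neoantigenic_fraction: float = Field(0.57, ge=0, le=1)
    epitopes_per_mutation: float = Field(7.0, gt=0)
    frameshift_epitope_factor: float = Field(2.0, gt=0)

    affinity_lognorm_params: tuple[float, float] = (5.0, 1.2)
    fpkm_lognorm_params: tuple[float, float] = (1.0, 1.5)
    stability_lognorm_params: tuple[float, float] = (0.5, 1.0)

    theta_cnv: float = Field(1.5, ge=0)
    theta_txn: float = Field(0.7, ge=0)
    p_copy_loss_base: float = Field(0.15, gt=0, lt=1)
    p_expressed_base: float = Field(0.6, gt=0, lt=1)

    beta_reduction: float = Field(2.0, ge=0)
    p_drop_met: float = Field(0.12, gt=0, lt=1)
    gain_fraction_met: float = Field(0.15, ge=0)
    p_clonal: float = Field(0.65, ge=0, le=1)
    p_clonality_flip: float = Field(0.15, ge=0, le=1)

    depth: int = Field(100, ge=10)

    subtype_effect: float = Field(1.5, ge=0)
    n_signature_genes: int = Field(50, ge=1)
    n_background_genes: int = Field(200, ge=0)
    subtype_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    cell_fraction_dirichlet: dict[str, float] = Field(
        default_factory=lambda: {
            "T_cells_CD8": 2.0,
            "T_cells_CD4": 2.0,
            "Tregs": 1.0,
            "B_cells": 1.0,
            "NK_cells": 1.0,
            "Macrophages_M0": 1.0,
            "Macrophages_M1": 1.0,
            "Macrophages_M2": 1.0,
            "Dendritic_cells": 1.0,
            "Other": 4.0,
        }
    )

    tcr_powerlaw_exponent: float = Field(2.5, gt=1)
    n_tcr_clones: int = Field(300, ge=1)

    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check_fractions(self) -> "SyntheticCohortConfig":
        total = (
            self.missense_fraction
            + self.frameshift_fraction
            + self.other_nonsilent_fraction
        )
        if total > 1 + 1e-12:
            raise ValueError(
                "missense_fraction + frameshift_fraction + other_nonsilent_fraction "
                f"must be <= 1, got {total}"
            )
        if abs(sum(self.subtype_proportions) - 1) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        for mu_sigma_name in (
            "affinity_lognorm_params",
            "fpkm_lognorm_params",
            "stability_lognorm_params",
        ):
            _, sigma = getattr(self, mu_sigma_name)
            if sigma <= 0:
                raise ValueError(f"{mu_sigma_name}: sigma must be > 0")
        return self


class PipelineConfig(BaseModel):
    """Fixed thresholds and mode switches of the analysis pipeline."""

    model_config = ConfigDict(extra="forbid")

    # neoantigen calling gates
    affinity_gate_nm: float = Field(500.0, gt=0)
    strong_affinity_nm: float = Field(50.0, gt=0)
    medium_affinity_nm: float = Field(150.0, gt=0)
    stability_cut_h: float = Field(2.0, gt=0)
    fpkm_gate: float = Field(1.0, gt=0)

    # variant QC
    min_alt_reads: int = Field(5, ge=0)
    alpha: float = Field(0.05, gt=0, lt=1)

    # instability / heterogeneity
    cin_wgii_cut: float = Field(0.2, gt=0)

    # subtype model
    probability_gate: float = Field(0.4, gt=0, lt=1)
    train_fraction: float = Field(2 / 3, gt=0, lt=1)
    resampling_iterations: int = Field(100, ge=1)

    # mode switches
    depletion_significance_gate: bool = False
    zscore_population_sd: bool = True
    log_transform_neoantigen_load: bool = True
    tcr_clonal_frequency: float = Field(0.01, gt=0, lt=1)

    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check_order(self) -> "PipelineConfig":
        if not (
            self.strong_affinity_nm < self.medium_affinity_nm < self.affinity_gate_nm
        ):
            raise ValueError(
                "affinity class cuts must satisfy strong < medium < gate"
            )
        return self
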