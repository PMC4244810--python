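"""Validated analysis configuration shared by every pipeline stage.

All thresholds live here so that a run is fully described by one document;
there is no hidden global state and every stochastic step takes an explicit
seed.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator


class SegmentationConfig(BaseModel):
    """Brightfield foreground extraction controls.

    ``fixed_threshold`` (intensity depth below the background median)
    overrides the default Otsu threshold when set.  ``min_depth_sigmas``
    guards against thresholding pure noise: the chosen threshold must exceed
    this many robust (MAD-based) background SDs, otherwise the frame is
    declared empty.
    """

    fixed_threshold: float | None = Field(default=None, gt=0)
    min_depth_sigmas: float = Field(default=6.0, gt=0)
    min_object_size: int = Field(default=5, gt=0)


class FitConfig(BaseModel):
    """Bounds and gates for the growth-model fit."""

    min_points: int = Field(default=5, ge=3)
    rmse_cap: float = Field(default=0.5, gt=0)  # ln pixels
    min_mu_fittable: float = Field(default=0.01, gt=0)  # ln px / h
    mu_upper: float = Field(default=10.0, gt=0)
    h0_upper: float = Field(default=300.0, gt=0)


class StatsConfig(BaseModel):
    mc_replicates: int = Field(default=199, gt=0)
    permutation_replicates: int = Field(default=999, gt=0)
    spatial_min_dead: int = Field(default=5, gt=0)
    min_fittable_for_medians: int = Field(default=10, gt=0)


class AnalysisConfig(BaseModel):
    """Top-level configuration for segment → track → fit → summarize."""

    segmentation: SegmentationConfig = SegmentationConfig()
    fit: FitConfig = FitConfig()
    stats: StatsConfig = StatsConfig()

    #: mean PI over an object must exceed background median + k * MAD
    pi_k: float = Field(default=6.0, gt=0)
    #: final/initial area ratio at or above which a founder divided
    dividing_ratio: float = Field(default=4.0, gt=0)
    #: count PI-positive-at-t0 founders in the survival denominator
    count_pi_positive_t0: bool = True
    #: default frame interval (h) when the input carries no time base
    frame_interval: float = Field(default=1.0, gt=0)
    seed: int = Field(ge=0, lt=2**31)

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if self.fit.min_mu_fittable >= self.fit.mu_upper:
            raise ValueError("min_mu_fittable must be below mu_upper")
        return self
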